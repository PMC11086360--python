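import numpy as np
import pytest

from grfest import ekf
from grfest.ekf import (CalibrationError, EKFParams, EKFState, IMUTrial,
                        centripetal_tangential, init_from_calibration,
                        observation, omega_matrix, predict, run_pair_ekf,
                        update)
from grfest.quat import (euler_xyz, quat_conj, quat_from_euler_xyz,
                         quat_multiply, quat_normalize)


def hinge_trial(T=10.0, rate=1000.0, A=np.deg2rad(45), f=0.5,
                l2=np.array([0.0, 0.03, -0.15]),
                noise_acc=0.0, noise_gyr=0.0, seed=0):
    """Two-link hinge: link a static, link b oscillating about the shared
    joint's X axis.  Signals are analytic (closed-form rotating-frame
    kinematics), independent of the simulation kernels."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, T, 1.0 / rate)
    th = A * np.sin(2 * np.pi * f * t)
    thd = A * 2 * np.pi * f * np.cos(2 * np.pi * f * t)
    thdd = -A * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
    N = t.size
    acc = np.zeros((N, 2, 3))
    gyr = np.zeros((N, 2, 3))
    g = np.array([0.0, 0.0, 9.81])
    for k in range(N):
        acc[k, 0] = g
        c, s = np.cos(th[k]), np.sin(th[k])
        R2 = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        w2 = np.array([thd[k], 0, 0])
        wd2 = np.array([thdd[k], 0, 0])
        acc[k, 1] = centripetal_tangential(w2, wd2, l2) + R2.T @ g
        gyr[k, 1] = w2
    acc += noise_acc * rng.standard_normal(acc.shape)
    gyr += noise_gyr * rng.standard_normal(gyr.shape)
    trial = IMUTrial(t=t, sensors=["a", "b"], accel=acc, gyro=gyr, rate=rate)
    return trial, th


def rel_flexion_rms(Qs, Qc, th):
    errs = np.empty(len(th))
    for k in range(len(th)):
        qr = quat_multiply(quat_conj(Qs[k]), Qc[k])
        errs[k] = euler_xyz(qr)[0] - th[k]
    return float(np.sqrt(np.mean(errs ** 2)))


L1 = np.array([0.0, 0.05, 0.12])
L2 = np.array([0.0, 0.03, -0.15])


class TestPrimitives:
    def test_omega_matrix_zero(self):
        assert np.allclose(omega_matrix(np.zeros(3)), 0.0)

    def test_omega_matrix_antisymmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            O = omega_matrix(rng.standard_normal(3))
            assert np.allclose(O, -O.T)

    def test_omega_matrix_quaternion_kinematics_oracle(self):
        """Omega(w) q equals the quaternion product q x (0, w)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = rng.standard_normal(3)
            q = quat_normalize(rng.standard_normal(4))
            lhs = omega_matrix(w) @ q
            rhs = quat_multiply(q, np.concatenate([[0.0], w]))
            assert np.allclose(lhs, rhs, atol=1e-12)

    @pytest.mark.parametrize("w,wd,ls,expected", [
        (np.zeros(3), np.zeros(3), L1, np.zeros(3)),
        (np.array([0, 0, 10.0]), np.zeros(3), np.array([0.1, 0, 0]),
         np.array([-10.0, 0, 0])),
        (np.zeros(3), np.array([0, 0, 5.0]), np.array([0.1, 0, 0]),
         np.array([0, 0.5, 0])),
    ])
    def test_centripetal_tangential(self, w, wd, ls, expected):
        assert np.allclose(centripetal_tangential(w, wd, ls), expected, atol=1e-12)


class TestPredict:
    def test_zero_rate_state_unchanged_covariance_grows(self):
        p = EKFParams(dt=1e-3)
        st = EKFState(x=np.array([1.0, 0, 0, 0, 1.0, 0, 0, 0]),
                      P=np.eye(8) * 1e-4)
        st2 = predict(st, np.zeros(3), np.zeros(3), p)
        assert np.allclose(st2.x, st.x)
        assert np.trace(st2.P) > np.trace(st.P)

    def test_constant_rate_matches_quaternion_exponential(self):
        p = EKFParams(dt=1e-3)
        st = EKFState(x=np.array([1.0, 0, 0, 0, 1.0, 0, 0, 0]), P=p.P0.copy())
        w = np.array([0.0, 0.0, np.pi])
        for _ in range(500):
            st = predict(st, w, w, p)
        yaw = euler_xyz(st.x[:4])[2]
        assert yaw == pytest.approx(np.pi / 2, abs=1e-3)

    def test_quaternions_unit_norm(self):
        p = EKFParams(dt=1e-3)
        rng = np.random.default_rng(2)
        st = EKFState(x=np.array([1.0, 0, 0, 0, 1.0, 0, 0, 0]), P=p.P0.copy())
        for _ in range(50):
            st = predict(st, rng.standard_normal(3), rng.standard_normal(3), p)
            assert np.linalg.norm(st.x[:4]) == pytest.approx(1.0, abs=1e-14)
            assert np.linalg.norm(st.x[4:]) == pytest.approx(1.0, abs=1e-14)


class TestObservation:
    def test_jacobian_matches_finite_differences(self):
        """Analytic H equals finite differences of the homogeneous rotation
        form, projected to the unit-quaternion tangent space."""
        def Rv(q, v):
            w, u = q[0], q[1:]
            return v * (w * w - u @ u) + 2 * w * np.cross(u, v) + 2 * u * (u @ v)

        def h_hom(x, b_s, b_c):
            qs, qc = x[:4], x[4:]
            n_s, n_c = qs @ qs, qc @ qc
            out = np.empty(6)
            out[:3] = Rv(quat_conj(qs), Rv(qc, b_c) / n_c) / n_s
            out[3:] = Rv(quat_conj(qc), Rv(qs, b_s) / n_s) / n_c
            return out

        rng = np.random.default_rng(3)
        for _ in range(5):
            x = np.concatenate([quat_normalize(rng.standard_normal(4)),
                                quat_normalize(rng.standard_normal(4))])
            b_s = rng.standard_normal(3)
            b_c = rng.standard_normal(3)
            h, H = observation(x, b_s, b_c)
            assert np.allclose(h, h_hom(x, b_s, b_c), atol=1e-12)
            eps = 1e-7
            Hfd = np.zeros((6, 8))
            for j in range(8):
                xp = x.copy()
                xp[j] += eps
                Hfd[:, j] = (h_hom(xp, b_s, b_c) - h) / eps
            assert np.allclose(H, Hfd, atol=1e-5)

    def test_inverse_rotation_property(self):
        from grfest.quat import quat_to_matrix
        rng = np.random.default_rng(4)
        qs = quat_normalize(rng.standard_normal(4))
        qc = quat_normalize(rng.standard_normal(4))
        R1 = quat_to_matrix(qs).T @ quat_to_matrix(qc)
        R2 = quat_to_matrix(qc).T @ quat_to_matrix(qs)
        assert np.allclose(R1 @ R2, np.eye(3), atol=1e-12)

    def test_static_truth_zero_innovation(self):
        g = np.array([0.0, 0.0, 9.81])
        qs = quat_from_euler_xyz([0.2, -0.1, 0.3])
        qc = quat_from_euler_xyz([-0.4, 0.2, 0.1])
        from grfest.quat import quat_to_matrix
        b_s = quat_to_matrix(qs).T @ g
        b_c = quat_to_matrix(qc).T @ g
        x = np.concatenate([qs, qc])
        h, _ = observation(x, b_s, b_c)
        assert np.allclose(h, np.concatenate([b_s, b_c]), atol=1e-12)

    def test_common_yaw_offset_leaves_innovation_unchanged(self):
        """Only relative orientation is observable: a shared heading offset
        applied to both links does not change the predicted observation."""
        rng = np.random.default_rng(5)
        qs = quat_normalize(rng.standard_normal(4))
        qc = quat_normalize(rng.standard_normal(4))
        b_s = rng.standard_normal(3)
        b_c = rng.standard_normal(3)
        h0, _ = observation(np.concatenate([qs, qc]), b_s, b_c)
        for yaw in (0.3, 1.2, -2.0):
            qz = quat_from_euler_xyz([0.0, 0.0, yaw])
            h1, _ = observation(np.concatenate([quat_multiply(qz, qs),
                                                quat_multiply(qz, qc)]),
                                b_s, b_c)
            assert np.allclose(h0, h1, atol=1e-12)


class TestUpdate:
    def test_static_truth_state_unchanged(self):
        g = np.array([0.0, 0.0, 9.81])
        from grfest.quat import quat_to_matrix
        qs = quat_from_euler_xyz([0.1, 0.0, 0.0])
        qc = quat_from_euler_xyz([0.5, 0.0, 0.0])
        p = EKFParams(dt=1e-3)
        st = EKFState(x=np.concatenate([qs, qc]), P=np.eye(8) * 1e-4)
        a_s = quat_to_matrix(qs).T @ g
        a_c = quat_to_matrix(qc).T @ g
        st2 = update(st, a_s, a_c, np.zeros(3), np.zeros(3), p)
        assert np.allclose(st2.x, st.x, atol=1e-12)

    def test_perturbed_state_contracts_toward_truth(self):
        g = np.array([0.0, 0.0, 9.81])
        from grfest.quat import quat_to_matrix
        qs = quat_from_euler_xyz([0.0, 0.0, 0.0])
        qc_true = quat_from_euler_xyz([0.5, 0.0, 0.0])
        qc_pert = quat_from_euler_xyz([0.5 + np.deg2rad(5), 0.0, 0.0])
        p = EKFParams(dt=1e-3)
        st = EKFState(x=np.concatenate([qs, qc_pert]), P=np.eye(8) * 1e-2)
        a_s = quat_to_matrix(qs).T @ g
        a_c = quat_to_matrix(qc_true).T @ g
        st2 = update(st, a_s, a_c, np.zeros(3), np.zeros(3), p)

        def rel_err(x):
            d = quat_multiply(quat_conj(quat_multiply(quat_conj(qs), qc_true)),
                              quat_multiply(quat_conj(x[:4]), x[4:]))
            return 2 * np.arccos(np.clip(abs(d[0]), -1, 1))

        assert rel_err(st2.x) < rel_err(st.x)

    def test_covariance_symmetric_psd_over_run(self):
        trial, _ = hinge_trial(T=0.5, noise_acc=0.05, noise_gyr=0.005, seed=6)
        p = EKFParams()
        st = EKFState(x=np.array([1.0, 0, 0, 0, 1.0, 0, 0, 0]), P=p.P0.copy())
        params = EKFParams(dt=1.0 / trial.rate)
        for k in range(1, 200):
            st = predict(st, trial.gyro[k - 1, 0], trial.gyro[k - 1, 1], params)
            st = update(st, trial.accel[k, 0], trial.accel[k, 1],
                        np.zeros(3), np.zeros(3), params)
            assert np.allclose(st.P, st.P.T, atol=1e-10)
            assert np.linalg.eigvalsh(st.P).min() > -1e-10


class TestPairEKF:
    def test_noise_free_exact_init_recovery(self):
        trial, th = hinge_trial(T=10.0)
        Qs, Qc = run_pair_ekf(trial, ("a", "b"), EKFParams(), L1, L2)
        assert np.rad2deg(rel_flexion_rms(Qs, Qc, th)) < 0.1

    def test_noisy_hinge_recovery_under_2_degrees(self):
        trial, th = hinge_trial(T=10.0, noise_acc=0.05, noise_gyr=0.005, seed=1)
        Qs, Qc = run_pair_ekf(trial, ("a", "b"), EKFParams(), L1, L2)
        assert np.rad2deg(rel_flexion_rms(Qs, Qc, th)) < 2.0

    def test_static_noisy_under_1_degree(self):
        trial, th = hinge_trial(T=10.0, A=0.0, noise_acc=0.05,
                                noise_gyr=0.005, seed=2)
        Qs, Qc = run_pair_ekf(trial, ("a", "b"), EKFParams(), L1, L2)
        assert np.rad2deg(rel_flexion_rms(Qs, Qc, th)) < 1.0

    def test_error_decreases_with_observation_noise(self):
        errs = []
        for sigma in (0.2, 0.05, 0.0125):
            trial, th = hinge_trial(T=4.0, noise_acc=sigma, noise_gyr=0.005,
                                    seed=7)
            Qs, Qc = run_pair_ekf(trial, ("a", "b"), EKFParams(), L1, L2)
            errs.append(rel_flexion_rms(Qs, Qc, th))
        assert errs[0] > errs[2]

    def test_missing_samples_rejected(self):
        trial, _ = hinge_trial(T=0.2)
        trial.accel[10, 0, 0] = np.nan
        with pytest.raises(ValueError):
            run_pair_ekf(trial, ("a", "b"), EKFParams(), L1, L2)


class TestChainOrientations:
    def test_whole_body_chain_on_synthetic_trial(self, hop_trial, model):
        """Per-segment orientation error stays bounded (well under the
        joint-angle errors the method itself reports on real data) through a
        jump with contact impacts."""
        from grfest.body import SEGMENTS
        from grfest.ekf import chain_orientations
        from grfest.quat import quat_from_matrix
        init = {s: quat_from_matrix(hop_trial.truth.seg_R[0, i])
                for i, s in enumerate(SEGMENTS)}
        est = chain_orientations(hop_trial.trial, model,
                                 EKFParams(dt=1e-3), init_quats=init)
        qT = hop_trial.truth.seg_quat()
        for i, s in enumerate(SEGMENTS):
            qE = est.quat[est.idx(s)]
            angs = []
            for k in range(0, est.t.size, 40):
                d = quat_multiply(quat_conj(qT[i][k]), qE[k])
                angs.append(2 * np.arccos(np.clip(abs(d[0]), -1, 1)))
            rms = np.rad2deg(np.sqrt(np.mean(np.array(angs) ** 2)))
            assert rms < 12.0, f"{s}: {rms:.1f} deg"

    def test_composition_consistency(self, hop_trial, model):
        """pelvis->thigh->shank composition equals the direct pelvis->shank
        relative rotation (the chain is built exactly that way)."""
        from grfest.body import SEGMENTS
        from grfest.ekf import chain_orientations
        from grfest.quat import quat_from_matrix, quat_to_matrix
        init = {s: quat_from_matrix(hop_trial.truth.seg_R[0, i])
                for i, s in enumerate(SEGMENTS)}
        est = chain_orientations(hop_trial.trial, model,
                                 EKFParams(dt=1e-3), init_quats=init)
        qp = est.quat[est.idx("pelvis")]
        qs = est.quat[est.idx("shank_r")]
        qt = est.quat[est.idx("thigh_r")]
        for k in range(0, est.t.size, 200):
            direct = quat_to_matrix(qp[k]).T @ quat_to_matrix(qs[k])
            via = (quat_to_matrix(qp[k]).T @ quat_to_matrix(qt[k])) @ \
                (quat_to_matrix(qt[k]).T @ quat_to_matrix(qs[k]))
            assert np.allclose(direct, via, atol=1e-10)

    def test_disconnected_graph_rejected(self, hop_trial, model):
        from grfest.body import ConfigurationError
        from grfest.ekf import chain_orientations
        t = hop_trial.trial
        keep = [s for s in t.sensors if s not in ("thigh_l",)]
        idx = [t.sensors.index(s) for s in keep]
        reduced = IMUTrial(t=t.t, sensors=keep, accel=t.accel[:, idx],
                           gyro=t.gyro[:, idx], rate=t.rate)
        with pytest.raises(ConfigurationError):
            chain_orientations(reduced, model, EKFParams(dt=1e-3))


class TestCalibration:
    def _static_trial(self, accel_rows, gyro_std=0.0, seed=0, T=200):
        rng = np.random.default_rng(seed)
        S = len(accel_rows)
        acc = np.tile(np.asarray(accel_rows, dtype=float), (T, 1, 1))
        gyr = gyro_std * rng.standard_normal((T, S, 3))
        t = np.arange(T) / 1000.0
        return IMUTrial(t=t, sensors=[f"s{i}" for i in range(S)],
                        accel=acc, gyro=gyr, rate=1000.0)

    def test_gravity_aligned_identity(self):
        trial = self._static_trial([[0, 0, 9.81]])
        init, _ = init_from_calibration(trial)
        assert np.allclose(init["s0"], [1, 0, 0, 0], atol=1e-12)

    def test_30_degree_roll_recovered(self):
        phi = np.deg2rad(30)
        from grfest.quat import quat_to_matrix
        q = quat_from_euler_xyz([phi, 0, 0])
        a = quat_to_matrix(q).T @ np.array([0, 0, 9.81])
        init, _ = init_from_calibration(self._static_trial([a]))
        assert euler_xyz(init["s0"])[0] == pytest.approx(phi, abs=1e-6)

    def test_noisy_window_tilt_within_half_degree(self):
        rng = np.random.default_rng(11)
        phi, theta = 0.25, -0.4
        from grfest.quat import quat_to_matrix
        q = quat_from_euler_xyz([phi, theta, 0.0])
        a = quat_to_matrix(q).T @ np.array([0, 0, 9.81])
        T = 2000
        acc = a[None, None, :] + 0.1 * rng.standard_normal((T, 1, 3))
        trial = IMUTrial(t=np.arange(T) / 1000.0, sensors=["s0"], accel=acc,
                         gyro=np.zeros((T, 1, 3)), rate=1000.0)
        init, _ = init_from_calibration(trial)
        ang = euler_xyz(init["s0"])
        assert abs(ang[0] - phi) < np.deg2rad(0.5)
        assert abs(ang[1] - theta) < np.deg2rad(0.5)

    def test_non_static_window_rejected(self):
        trial = self._static_trial([[0, 0, 9.81]], gyro_std=2.0, seed=3)
        with pytest.raises(CalibrationError):
            init_from_calibration(trial)
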