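import numpy as np
import pytest

from grfest.body import SEGMENTS, neutral_pose
from grfest.dynamics import SolverOptions, newton_residual, simulate
from grfest.reference import constant_reference
from grfest.synth import (NoiseModel, SyntheticTrial, add_noise, imu_from_sim,
                          make_fixture, synth_motion, synthesize)


class TestSynthMotion:
    def test_calibration_pose_constant_neutral(self, model):
        traj = synth_motion(model, "calibration-pose", 1.0, seed=0)
        assert all(np.allclose(v, 0.0) for v in traj.node_values)

    def test_same_seed_identical_nodes(self, model):
        a = synth_motion(model, "single-leg-hop", 1.5, seed=9)
        b = synth_motion(model, "single-leg-hop", 1.5, seed=9)
        for va, vb in zip(a.node_values, b.node_values):
            assert np.array_equal(va, vb)

    def test_different_seed_different_amplitude(self, model):
        a = synth_motion(model, "squat-jump", 1.5, seed=1)
        b = synth_motion(model, "squat-jump", 1.5, seed=2)
        k = a.dof_names.index("knee_l_x")
        assert not np.allclose(a.node_values[k], b.node_values[k])

    def test_unknown_scenario_rejected(self, model):
        with pytest.raises(ValueError):
            synth_motion(model, "backflip", 1.0, 0)

    def test_squat_jump_grf_signature(self):
        """Unloading dip below body weight, propulsion peak above it, then a
        flight phase."""
        st = synthesize("squat-jump", seed=0)
        bw = 63.3 * 9.81
        gz = st.truth.grf[:, 2]
        airborne = np.flatnonzero(gz < 0.01 * bw)
        airborne = airborne[airborne > 300]
        assert airborne.size > 0, "no flight phase"
        i_flight = airborne[0]
        i_peak = int(gz[:i_flight].argmax())
        assert gz[i_peak] > bw
        assert gz[150:i_peak].min() < 0.8 * bw


class TestIMUFromSim:
    def test_static_standing_reads_gravity(self, model):
        ref = constant_reference(model, np.zeros(21), (0.0, 2.0))
        sim = simulate(model, ref, solver_opts=SolverOptions(output_rate=100))
        trial = imu_from_sim(sim, model)
        # late samples: settled
        acc = trial.accel[-1]
        assert np.allclose(np.linalg.norm(acc, axis=1), 9.81, atol=0.05)
        # the PD-held stance creeps slowly (friction regularization); the
        # gyros read the residual drift, well below any real motion
        assert np.abs(trial.gyro[-1]).max() < 0.05

    def test_pure_hinge_rotation_closed_form(self, model):
        """A sensor on a hinge rotating at constant rate reads the
        centripetal term plus the rotating gravity projection."""
        from grfest import _core
        from grfest.dynamics import _arrays
        arr = _arrays(model)
        names = model.dof_names()
        i_elbow = arr.pub2int[names.index("elbow_r_x")]
        w0 = 3.0
        T = 200
        tgrid = np.arange(T) / 1000.0
        Q = np.zeros((T, 27))
        Qd = np.zeros((T, 27))
        Qdd = np.zeros((T, 27))
        Q[:, i_elbow] = w0 * tgrid
        Qd[:, i_elbow] = w0
        mount = next(m_ for m_ in model.mountings if m_.segment == "forearm_r")
        body = arr.seg_body[SEGMENTS.index("forearm_r")]
        acc, gyr = _core.sensor_series(Q, Qd, Qdd, arr.parent, arr.jtype,
                                       arr.axis, arr.p_off,
                                       np.array([body]),
                                       mount.lever_arm[None, :],
                                       np.eye(3)[None, :, :], 9.81)
        ls = mount.lever_arm
        for k in (0, 50, 150):
            th = w0 * tgrid[k]
            c, s = np.cos(th), np.sin(th)
            R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
            w_vec = np.array([w0, 0.0, 0.0])
            expected = np.cross(w_vec, np.cross(w_vec, ls)) \
                + R.T @ np.array([0, 0, 9.81])
            assert np.allclose(acc[k, 0], expected, atol=1e-9)
            assert np.allclose(gyr[k, 0], w_vec, atol=1e-12)

    def test_round_trip_noise_free_ekf_recovery(self, hop_trial_clean, model):
        """Feeding noise-free synthetic signals to the paired EKF with exact
        initialization recovers the relative orientations to a fraction of a
        degree (no low-pass: the signals carry no noise to remove)."""
        from grfest.ekf import EKFParams, run_pair_ekf, _pair_levers
        from grfest.quat import quat_from_matrix, quat_multiply, quat_conj
        sim = hop_trial_clean.truth
        trial = hop_trial_clean.trial
        qT = sim.seg_quat()
        ps, cs, lev_p, lev_c = _pair_levers(model, "knee_r")
        i_p, i_c = SEGMENTS.index(ps), SEGMENTS.index(cs)
        x0 = np.concatenate([quat_from_matrix(sim.seg_R[0, i_p]),
                             quat_from_matrix(sim.seg_R[0, i_c])])
        Qs, Qc = run_pair_ekf(trial, (ps, cs), EKFParams(), lev_p, lev_c,
                              x0=x0, accel_cutoff=None, gyro_cutoff=None)
        angs = []
        for k in range(0, trial.t.size, 25):
            d = quat_multiply(
                quat_conj(quat_multiply(quat_conj(qT[i_p][k]), qT[i_c][k])),
                quat_multiply(quat_conj(Qs[k]), Qc[k]))
            angs.append(2 * np.arccos(np.clip(abs(d[0]), -1, 1)))
        assert np.rad2deg(np.sqrt(np.mean(np.array(angs) ** 2))) < 1.0


class TestAddNoise:
    def test_zero_stds_identity(self, calib_trial):
        clean = imu_from_sim(calib_trial.truth, calib_trial.truth.model)
        noisy = add_noise(clean, NoiseModel(0.0, 0.0, 0.0, 0))
        assert np.array_equal(noisy.accel, clean.accel)
        assert np.array_equal(noisy.gyro, clean.gyro)

    def test_noise_variance_matches_configuration(self):
        from grfest.ekf import IMUTrial
        T = 100000
        base = IMUTrial(t=np.arange(T) / 1000.0, sensors=["a"],
                        accel=np.zeros((T, 1, 3)), gyro=np.zeros((T, 1, 3)),
                        rate=1000.0)
        nm = NoiseModel(accel_std=0.05, gyro_std=0.0, bias_walk_std=0.0, seed=1)
        noisy = add_noise(base, nm)
        var = noisy.accel.var()
        assert var == pytest.approx(0.05 ** 2, rel=0.05)

    def test_same_seed_identical(self, calib_trial):
        clean = imu_from_sim(calib_trial.truth, calib_trial.truth.model)
        n1 = add_noise(clean, NoiseModel(seed=7))
        n2 = add_noise(clean, NoiseModel(seed=7))
        assert np.array_equal(n1.accel, n2.accel)
        assert np.array_equal(n1.gyro, n2.gyro)


class TestFixture:
    def test_round_trip_and_cross_module_invariants(self, tmp_path, model):
        from grfest import io as gio
        st = make_fixture("single-leg-hop", 1.69, 63.3,
                          NoiseModel(seed=2), seed=1, outdir=tmp_path)
        assert (tmp_path / "trial.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "meta.yaml").exists()
        back = gio.read_trial_csv(tmp_path / "trial.csv")
        assert back.sensors == st.trial.sensors
        assert np.allclose(back.accel, st.trial.accel, atol=1e-7)
        # truth satisfies the whole-body Newton check
        assert newton_residual(st.truth, st.truth.model).max() < 1.0

    def test_calibration_fixture_passes_static_init(self, calib_trial, model):
        from grfest.ekf import init_from_calibration
        init, neutral = init_from_calibration(
            calib_trial.trial.window(0.5, 1.0), model)
        assert set(init) == set(SEGMENTS)
        # standing posture: all sensors near their mounted orientation
        from grfest.quat import euler_xyz
        for s in SEGMENTS:
            ang = np.rad2deg(euler_xyz(init[s]))
            assert np.abs(ang[:2]).max() < 5.0
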