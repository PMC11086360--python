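import numpy as np
import pytest

from grfest.body import ModelState, neutral_pose
from grfest.dynamics import (ControlGains, GroundParams, SolverOptions,
                             active_torque, assemble_and_solve, angular_momentum,
                             contact_force_law, contact_forces, eom_terms,
                             newton_residual, passive_torque, simulate,
                             virtual_torque, grm_about_ankle)
from grfest.reference import constant_reference


class TestTorqueLaws:
    def test_active_torque_zero_error(self):
        q = np.zeros(21)
        assert np.allclose(active_torque(q, q, q, q, ControlGains()), 0.0)

    def test_active_torque_proportional_term(self):
        g = ControlGains()
        q = np.zeros(21)
        qr = q.copy()
        qr[4] = 0.1
        tau = active_torque(qr, q, q, q, g)
        assert tau[4] == pytest.approx(100.0)
        assert np.count_nonzero(tau) == 1

    def test_active_torque_derivative_term(self):
        g = ControlGains()
        q = np.zeros(21)
        qdr = q.copy()
        qdr[7] = 1.0
        assert active_torque(q, qdr, q, q, g)[7] == pytest.approx(10.0)

    def test_active_torque_dimension_mismatch(self):
        with pytest.raises(ValueError):
            active_torque(np.zeros(20), np.zeros(21), np.zeros(21), np.zeros(21),
                          ControlGains())

    def test_passive_dormant_midrange(self, model):
        j = model.joints["knee_l"]
        mid = 0.5 * (j.q_min + j.q_max)
        assert np.all(np.abs(passive_torque(mid, np.zeros(1), j)) < 0.1)

    def test_passive_restoring_and_monotone_beyond_limit(self, model):
        j = model.joints["knee_l"]
        t_at = passive_torque(j.q_max, np.zeros(1), j)[0]
        t_beyond = passive_torque(j.q_max + 0.1, np.zeros(1), j)[0]
        assert t_beyond < 0 and abs(t_beyond) > abs(t_at)
        t_under = passive_torque(j.q_min - 0.1, np.zeros(1), j)[0]
        assert t_under > 0

    def test_passive_matches_double_exponential_form(self, model):
        j = model.joints["hip_l"]
        a, b, c = j.passive_params[0]
        qs = np.linspace(j.q_min[0] - 0.2, j.q_max[0] + 0.2, 25)
        for q in qs:
            expected = a * (np.exp(b * (j.q_min[0] - q)) - np.exp(b * (q - j.q_max[0])))
            got = passive_torque(np.array([q, 0, 0]), np.zeros(3), j)[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_virtual_torque(self):
        g = ControlGains()
        assert np.allclose(virtual_torque(np.zeros(3), np.zeros(3), g), 0.0)
        # yaw gain is zero: pure yaw produces no torque
        assert np.allclose(virtual_torque([0, 0, 0.4], np.zeros(3), g), 0.0)
        assert virtual_torque([0.1, 0, 0], np.zeros(3), g)[0] == pytest.approx(-40.0)


class TestContactLaw:
    def test_no_force_above_ground(self):
        F = contact_force_law([[0, 0, 0.01]], [[0, 0, 0]], GroundParams())
        assert np.allclose(F, 0.0)

    def test_elastic_spot_check(self):
        F = contact_force_law([[0, 0, -0.01]], [[0, 0, 0]], GroundParams())
        assert F[0, 2] == pytest.approx(10.0, abs=1e-9)

    def test_viscoelastic_spot_check(self):
        F = contact_force_law([[0, 0, -0.01]], [[0, 0, -0.5]], GroundParams())
        assert F[0, 2] == pytest.approx(5010.0, abs=1e-9)

    def test_no_ground_suction(self):
        # fast upward motion inside penetration: force floored at zero
        F = contact_force_law([[0, 0, -0.001]], [[0, 0, +1.0]], GroundParams())
        assert F[0, 2] == 0.0

    def test_friction_invariants_random_states(self):
        rng = np.random.default_rng(42)
        gp = GroundParams()
        pos = rng.uniform(-0.05, 0.05, size=(500, 3))
        vel = rng.uniform(-2, 2, size=(500, 3))
        F = contact_force_law(pos, vel, gp)
        assert np.all(F[:, 2] >= 0)
        Fh = np.hypot(F[:, 0], F[:, 1])
        assert np.all(Fh <= gp.mu_s * F[:, 2] + 1e-9)
        # friction opposes the horizontal velocity
        dot = F[:, 0] * vel[:, 0] + F[:, 1] * vel[:, 1]
        assert np.all(dot <= 1e-12)

    def test_high_speed_friction_tends_to_dynamic(self):
        gp = GroundParams()
        F = contact_force_law([[0, 0, -0.01]], [[5.0, 0, 0]], gp)
        assert abs(F[0, 0]) == pytest.approx(gp.mu_d * F[0, 2], rel=1e-3)


class TestEquationsOfMotion:
    def test_free_fall(self, model):
        st = neutral_pose(model)
        st.q[23] += 1.0
        qdd = assemble_and_solve(model, st, np.zeros(21))
        assert np.allclose(qdd[:21], 0.0, atol=1e-9)
        assert qdd[23] == pytest.approx(-9.81, abs=1e-12)
        assert np.allclose(qdd[[21, 22, 24, 25, 26]], 0.0, atol=1e-9)

    def test_locked_chain_pendulum(self, model):
        names = model.dof_names()
        i = names.index("elbow_l_x")
        locked = np.ones(27, bool)
        locked[i] = False
        st = neutral_pose(model)
        st.q[23] += 1.0
        st.q[i] = -0.7
        qdd = assemble_and_solve(model, st, np.zeros(21), locked=locked)
        s = model.segments["forearm_l"]
        lc = abs(s.com_offset[2])
        inertia = s.inertia[0, 0] + s.mass * lc ** 2
        expected = -(s.mass * 9.81 * lc / inertia) * np.sin(-0.7)
        assert qdd[i] == pytest.approx(expected, rel=1e-10)

    def test_mass_matrix_symmetric_pd(self, model):
        rng = np.random.default_rng(7)
        st = neutral_pose(model)
        st.q = st.q + 0.3 * rng.standard_normal(27)
        M, _ = eom_terms(model, st)
        assert np.allclose(M, M.T, atol=1e-9)
        assert np.linalg.eigvalsh(M).min() > 0

    def test_fast_kernel_matches_reference_kernels(self, model):
        """The fused allocation-free kernel and the clear-reference kernels
        are independent implementations of the same dynamics."""
        from grfest import _core, _fast
        from grfest.dynamics import _arrays, _kernel_args, _to_internal
        from grfest.reference import constant_reference
        arr = _arrays(model)
        ref = constant_reference(model, np.zeros(21), (0.0, 1.0))
        args = _kernel_args(arr, ref, ControlGains(), GroundParams(), 9.81)
        clear_args = (arr.parent, arr.jtype, arr.axis, arr.p_off, arr.mass,
                      arr.com, arr.inertia, arr.pub2int[:21], *ref.packed(),
                      1000.0, 10.0, arr.q_min, arr.q_max, arr.passive,
                      np.array([400.0, 400.0, 0.0]), np.array([40.0, 40.0, 0.0]),
                      1e3, 1e4, 0.7, 0.5, 0.0, 0.01, arr.cp_body, arr.cp_pos, 9.81)
        rng = np.random.default_rng(3)
        st = neutral_pose(model)
        Fb = np.empty((44, 3))
        Pb = np.empty((44, 3))
        for _ in range(10):
            qi, qdi = _to_internal(arr, st.q + 0.25 * rng.standard_normal(27),
                                   0.8 * rng.standard_normal(27))
            y = np.concatenate([qi, qdi])
            t = rng.uniform(0, 1)
            qdd1, fp1, _, ta1 = _core.dyn_eval(t, y, *clear_args)
            qdd2, ta2 = _fast.dyn_fast(t, y, *args, Fb, Pb)
            assert np.allclose(qdd1, qdd2, rtol=1e-10, atol=1e-8)
            assert np.allclose(fp1, Fb, rtol=1e-10, atol=1e-8)
            assert np.allclose(ta1, ta2, rtol=1e-12, atol=1e-10)


class TestSimulate:
    def test_standing_settles_to_body_weight(self, model):
        ref = constant_reference(model, np.zeros(21), (0.0, 2.0))
        sim = simulate(model, ref)
        weight = model.total_mass * 9.81
        assert sim.grf[-1, 2] == pytest.approx(weight, rel=0.01)

    def test_newton_check_throughout_stance(self, model):
        ref = constant_reference(model, np.zeros(21), (0.0, 2.0))
        sim = simulate(model, ref)
        assert newton_residual(sim, model).max() < 1.0

    def test_zero_gravity_zero_torque_state_constant(self):
        # passive-free model so every torque really is zero
        from grfest.body import build_model
        model = build_model(1.69, 63.3,
                            joints_table={"passive_defaults":
                                          {"a": 0.0, "b": 20.0, "c": 0.0}})
        gains = ControlGains(K_PD=0.0, D_PD=0.0,
                             K_virtual=np.zeros(3), D_virtual=np.zeros(3))
        st = neutral_pose(model)
        st.q[23] += 1.0
        ref = constant_reference(model, np.zeros(21), (0.0, 0.3))
        sim = simulate(model, ref, gains=gains, t_span=(0.0, 0.3),
                       initial_state=st, gravity=False)
        assert np.allclose(sim.q[-1], sim.q[0], atol=1e-9)
        assert np.allclose(sim.q_dot[-1], 0.0, atol=1e-9)

    def test_airborne_angular_momentum_conserved(self, model):
        st = neutral_pose(model)
        st.q[23] += 1.5
        st.q_dot[24] = 1.0          # tumbling
        st.q_dot[26] = 2.0          # twisting
        gains = ControlGains(K_virtual=np.zeros(3), D_virtual=np.zeros(3))
        ref = constant_reference(model, np.zeros(21), (0.0, 0.4))
        sim = simulate(model, ref, gains=gains, t_span=(0.0, 0.4),
                       initial_state=st)
        assert np.all(sim.grf == 0.0)
        L = angular_momentum(sim, model)
        drift = np.abs(L - L[0]).max()
        assert drift < 1e-3 * max(1.0, np.abs(L[0]).max())

    def test_deterministic_reruns(self, model):
        ref = constant_reference(model, np.zeros(21), (0.0, 0.5))
        s1 = simulate(model, ref)
        s2 = simulate(model, ref)
        assert np.array_equal(s1.q, s2.q)
        assert np.array_equal(s1.grf, s2.grf)

    def test_total_grf_equals_point_sum(self, model):
        ref = constant_reference(model, np.zeros(21), (0.0, 0.5))
        sim = simulate(model, ref)
        assert np.allclose(sim.grf, sim.point_forces.sum(axis=1))

    def test_contact_invariants_during_motion(self, hop_trial):
        sim = hop_trial.truth
        gp = GroundParams()
        Fv = sim.point_forces[:, :, 2]
        assert np.all(Fv >= 0)
        Fh = np.hypot(sim.point_forces[:, :, 0], sim.point_forces[:, :, 1])
        assert np.all(Fh <= gp.mu_s * Fv + 1e-9)


class TestGRM:
    def _single_point_sim(self, model, offset, force):
        """Minimal SimResult stand-in with one loaded contact point."""
        from grfest.dynamics import SimResult
        T = 3
        pf = np.zeros((T, 44, 3))
        pp = np.zeros((T, 44, 3))
        segp = np.zeros((T, 12, 3))
        segR = np.tile(np.eye(3), (T, 12, 1, 1))
        ankle = np.array([0.3, 0.2, 0.06])
        from grfest.body import SEGMENTS
        segp[:, SEGMENTS.index("foot_l")] = ankle
        pp[:, 0] = ankle + offset
        pf[:, 0] = force
        t = np.linspace(0, 1, T)
        z = np.zeros((T, 27))
        return SimResult(t=t, q=z, q_dot=z, q_ddot=z, grf=pf.sum(1),
                         point_forces=pf, point_positions=pp,
                         tau_a=np.zeros((T, 21)), pelvis_acc=np.zeros((T, 3)),
                         seg_R=segR, seg_p=segp, model=None)

    def test_zero_lever_zero_moment(self, model):
        sim = self._single_point_sim(model, np.array([0, 0, -0.06]),
                                     np.array([0, 0, 100.0]))
        grm = grm_about_ankle(sim, model, "l")
        assert np.allclose(grm, 0.0, atol=1e-12)

    def test_anterior_offset_sagittal_moment(self, model):
        # 0.1 m anterior (-y), 100 N vertical -> 10 N m about the lateral axis
        sim = self._single_point_sim(model, np.array([0, -0.1, -0.06]),
                                     np.array([0, 0, 100.0]))
        grm = grm_about_ankle(sim, model, "l")
        assert abs(grm[0, 0]) == pytest.approx(10.0, abs=1e-9)

    def test_origin_translation_invariance(self, model):
        offs = np.array([0.05, -0.08, -0.06])
        F = np.array([3.0, -2.0, 80.0])
        sim1 = self._single_point_sim(model, offs, F)
        grm1 = grm_about_ankle(sim1, model, "l")
        sim2 = self._single_point_sim(model, offs, F)
        sim2.point_positions += np.array([1.0, -2.0, 0.0])
        sim2.seg_p += np.array([1.0, -2.0, 0.0])
        grm2 = grm_about_ankle(sim2, model, "l")
        assert np.allclose(grm1, grm2, atol=1e-9)
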