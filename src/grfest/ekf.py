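"""Paired-IMU orientation estimation with an extended Kalman filter.

Two IMUs on adjacent segments share a joint.  After subtracting each
sensor's own centripetal and tangential acceleration about that joint
(``omega x (omega x l) + omega_dot x l``), both sensors measure the same
gravitational-plus-translational acceleration of the joint point, expressed
in their own frames.  That equality is the EKF observation; the state is the
stacked pair of scalar-first quaternions propagated by first-order gyro
integration.  The construction never needs to isolate the gravity vector, so
it stays accurate under the large dynamic accelerations of sports movements,
and it needs no magnetometer -- the price is that only the *relative*
orientation across the joint is observable, and absolute heading rests on
gyro integration from the calibration posture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .body import BodyModel, SEGMENTS, JOINTS, joint_offsets, ConfigurationError
from .quat import (quat_to_matrix, quat_multiply, quat_conj,
                   quat_normalize, euler_xyz, quat_from_euler_xyz)


class CalibrationError(ValueError):
    """Raised when a calibration window is not quasi-static."""


@dataclass
class EKFParams:
    w: np.ndarray = field(default_factory=lambda: np.full(8, 1e-3))
    v: np.ndarray = field(default_factory=lambda: np.full(6, 1e-1))   # m/s^2
    P0: np.ndarray = field(default_factory=lambda: np.eye(8) * 1e2)
    dt: float = 1e-3

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.P0 = np.asarray(self.P0, dtype=float)
        if np.any(self.w <= 0) or np.any(self.v <= 0):
            raise ValueError("noise scales must be positive")
        if np.any(np.linalg.eigvalsh(self.P0) <= 0):
            raise ValueError("P0 must be positive-definite")


@dataclass
class EKFState:
    x: np.ndarray                   # (8,) stacked quaternions (Q_s, Q_s+1)
    P: np.ndarray                   # (8, 8)


@dataclass
class IMUTrial:
    """Multi-sensor IMU recording: specific force (m/s^2) and angular
    velocity (rad/s) per sensor, uniformly sampled."""

    t: np.ndarray                   # (T,)
    sensors: list[str]              # segment names
    accel: np.ndarray               # (T, S, 3) sensor frame
    gyro: np.ndarray                # (T, S, 3) sensor frame
    rate: float

    def __post_init__(self):
        if self.accel.shape != self.gyro.shape or self.accel.shape[0] != self.t.size:
            raise ValueError("accel/gyro/time shapes disagree")
        dts = np.diff(self.t)
        if dts.size and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")

    def idx(self, segment: str) -> int:
        try:
            return self.sensors.index(segment)
        except ValueError as exc:
            raise ConfigurationError(f"no sensor on segment {segment!r}") from exc

    def window(self, t0: float, t1: float) -> "IMUTrial":
        m = (self.t >= t0) & (self.t <= t1)
        return IMUTrial(self.t[m], self.sensors, self.accel[m], self.gyro[m],
                        self.rate)


@dataclass
class OrientationEstimate:
    segments: list[str]
    t: np.ndarray
    quat: np.ndarray                # (S, T, 4) scalar-first, global frame

    def euler(self) -> np.ndarray:
        """(S, T, 3) intrinsic X-Y-Z Euler angles."""
        out = np.empty(self.quat.shape[:2] + (3,))
        for s in range(len(self.segments)):
            out[s] = _euler_series(self.quat[s])
        return out

    def idx(self, segment: str) -> int:
        return self.segments.index(segment)


def _euler_series(quats: np.ndarray) -> np.ndarray:
    from .quat import to_scipy
    return to_scipy(quats).as_euler("XYZ")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def omega_matrix(omega) -> np.ndarray:
    """4x4 quaternion-rate matrix: q_dot = 1/2 Omega(omega) q for body-frame
    angular velocity and scalar-first quaternions."""
    wx, wy, wz = omega
    return np.array([
        [0.0, -wx, -wy, -wz],
        [wx, 0.0, wz, -wy],
        [wy, -wz, 0.0, wx],
        [wz, wy, -wx, 0.0],
    ])


def centripetal_tangential(omega, omega_dot, ls) -> np.ndarray:
    """Sensor-frame centripetal + tangential acceleration about the joint:
    omega x (omega x ls) + omega_dot x ls."""
    omega = np.asarray(omega)
    ls = np.asarray(ls)
    return np.cross(omega, np.cross(omega, ls)) + np.cross(np.asarray(omega_dot), ls)


def predict(state: EKFState, omega_s, omega_c, params: EKFParams) -> EKFState:
    """First-order gyro propagation of both quaternions, renormalized, with
    additive process noise on the covariance."""
    dt = params.dt
    F = np.zeros((8, 8))
    F[:4, :4] = np.eye(4) + 0.5 * dt * omega_matrix(omega_s)
    F[4:, 4:] = np.eye(4) + 0.5 * dt * omega_matrix(omega_c)
    x = F @ state.x
    x[:4] = quat_normalize(x[:4])
    x[4:] = quat_normalize(x[4:])
    P = F @ state.P @ F.T + np.diag(params.w ** 2)
    return EKFState(x=x, P=_condition(P))


def _condition(P: np.ndarray, vmax: float = 1.0) -> np.ndarray:
    """Symmetrize and cap the covariance eigenvalues at ``vmax``.

    Unit-quaternion components are bounded by 1, so variances above 1 carry
    no information; leaving them (e.g. from the deliberately vague P0)
    amplifies noise through weakly observable directions."""
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    if w[-1] <= vmax:
        return P
    return (V * np.clip(w, 0.0, vmax)) @ V.T


def _skew(v):
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def _dRv_dq(q, v):
    """3x4 Jacobian of R(q) v with respect to the (unnormalized) quaternion."""
    w, u = q[0], q[1:]
    col0 = 2.0 * (w * v + np.cross(u, v))
    B = 2.0 * ((u @ v) * np.eye(3) + np.outer(u, v) - np.outer(v, u) - w * _skew(v))
    return np.column_stack([col0, B])


_CONJ = np.diag([1.0, -1.0, -1.0, -1.0])


def observation(x: np.ndarray, b_s: np.ndarray, b_c: np.ndarray):
    """Predicted observation and its 6x8 Jacobian.

    h = [ R(q_s)^T R(q_c) b_c ;  R(q_c)^T R(q_s) b_s ]  (each sensor's
    gravity+translation acceleration mapped into the other's frame).
    """
    qs, qc = x[:4], x[4:]
    Rs = quat_to_matrix(qs)
    Rc = quat_to_matrix(qc)
    u_c = Rc @ b_c
    u_s = Rs @ b_s
    h = np.empty(6)
    h[:3] = Rs.T @ u_c
    h[3:] = Rc.T @ u_s
    H = np.zeros((6, 8))
    H[:3, :4] = _dRv_dq(quat_conj(qs), u_c) @ _CONJ
    H[:3, 4:] = Rs.T @ _dRv_dq(qc, b_c)
    H[3:, :4] = Rc.T @ _dRv_dq(qs, b_s)
    H[3:, 4:] = _dRv_dq(quat_conj(qc), u_s) @ _CONJ
    # project out the radial (norm) direction of each quaternion: the state is
    # renormalized anyway, and radial leakage would let magnitude mismatches
    # between the two accelerometers masquerade as rotations
    Ps = np.eye(4) - np.outer(qs, qs) / (qs @ qs)
    Pc = np.eye(4) - np.outer(qc, qc) / (qc @ qc)
    H[:, :4] = H[:, :4] @ Ps
    H[:, 4:] = H[:, 4:] @ Pc
    return h, H


def update(state: EKFState, a_s, a_c, a_ct_s, a_ct_c,
           params: EKFParams) -> EKFState:
    """Measurement update from compensated accelerations of the pair."""
    b_s = np.asarray(a_s) - np.asarray(a_ct_s)
    b_c = np.asarray(a_c) - np.asarray(a_ct_c)
    z = np.concatenate([b_s, b_c])
    h, H = observation(state.x, b_s, b_c)
    S = H @ state.P @ H.T + np.diag(params.v ** 2)
    try:
        K = state.P @ H.T @ np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("innovation covariance singular; regularizing")
        K = state.P @ H.T @ np.linalg.inv(S + 1e-9 * np.eye(6))
    x = state.x + K @ (z - h)
    x[:4] = quat_normalize(x[:4])
    x[4:] = quat_normalize(x[4:])
    P = (np.eye(8) - K @ H) @ state.P
    return EKFState(x=x, P=_condition(P))


# ---------------------------------------------------------------------------
# trial-level estimation
# ---------------------------------------------------------------------------

def _lowpass(x, rate, cutoff=18.0, order=4):
    if rate <= 2.0 * cutoff:
        return x
    b, a = butter(order, cutoff, fs=rate)
    return filtfilt(b, a, x, axis=0)


def gyro_rates_and_derivatives(trial: IMUTrial, idx: int,
                               cutoff: float | None = 18.0):
    """Low-passed gyro signal and its central-difference derivative for one
    sensor (raw differentiation would amplify noise); ``cutoff=None`` skips
    the filter."""
    w = trial.gyro[:, idx, :]
    if cutoff:
        w = _lowpass(w, trial.rate, cutoff)
    wd = np.gradient(w, 1.0 / trial.rate, axis=0)
    return w, wd


def run_pair_ekf(trial: IMUTrial, pair: tuple[str, str], params: EKFParams,
                 lever_s, lever_c, x0: np.ndarray | None = None,
                 accel_cutoff: float | None = 18.0,
                 gyro_cutoff: float | None = 18.0):
    """Run the paired EKF over a full trial.

    ``lever_s``/``lever_c`` are the sensor positions relative to the shared
    joint, in each sensor's frame.  Returns (T, 4) quaternion series for both
    sensors (global frame; common-mode heading is only as good as the gyro
    integration it rests on).
    """
    seg_s, seg_c = pair
    i_s, i_c = trial.idx(seg_s), trial.idx(seg_c)
    if np.any(~np.isfinite(trial.accel[:, [i_s, i_c]])) or \
       np.any(~np.isfinite(trial.gyro[:, [i_s, i_c]])):
        raise ValueError("missing samples in the pair's signals")
    T = trial.t.size
    w_s, wd_s = gyro_rates_and_derivatives(trial, i_s, gyro_cutoff)
    w_c, wd_c = gyro_rates_and_derivatives(trial, i_c, gyro_cutoff)
    # the accelerometers see the same low-pass as the gyros so the
    # centripetal/tangential compensation stays consistent through impacts
    a_s_all = trial.accel[:, i_s, :]
    a_c_all = trial.accel[:, i_c, :]
    if accel_cutoff:
        a_s_all = _lowpass(a_s_all, trial.rate, accel_cutoff)
        a_c_all = _lowpass(a_c_all, trial.rate, accel_cutoff)
    if x0 is None:
        x0 = np.array([1.0, 0, 0, 0, 1.0, 0, 0, 0])
    params = EKFParams(w=params.w, v=params.v, P0=params.P0, dt=1.0 / trial.rate)
    st = EKFState(x=x0.copy(), P=params.P0.copy())
    Qs = np.empty((T, 4))
    Qc = np.empty((T, 4))
    Qs[0], Qc[0] = st.x[:4], st.x[4:]
    lever_s = np.asarray(lever_s)
    lever_c = np.asarray(lever_c)
    for k in range(1, T):
        st = predict(st, w_s[k - 1], w_c[k - 1], params)
        act_s = centripetal_tangential(w_s[k], wd_s[k], lever_s)
        act_c = centripetal_tangential(w_c[k], wd_c[k], lever_c)
        st = update(st, a_s_all[k], a_c_all[k], act_s, act_c, params)
        Qs[k], Qc[k] = st.x[:4], st.x[4:]
    return Qs, Qc


def _pair_levers(model: BodyModel, jname: str):
    """Sensor levers about a joint, in each mounting's sensor frame."""
    _, _, pseg, cseg, _ = next(j for j in JOINTS if j[0] == jname)
    mount = {m.segment: m for m in model.mountings}
    off = joint_offsets(model)[jname]
    lev_p_seg = mount[pseg].lever_arm - off          # parent segment frame
    lev_c_seg = mount[cseg].lever_arm                # child segment frame
    Rp = quat_to_matrix(mount[pseg].mount_rotation)
    Rc = quat_to_matrix(mount[cseg].mount_rotation)
    return pseg, cseg, Rp.T @ lev_p_seg, Rc.T @ lev_c_seg


def strapdown(t, gyro, q0) -> np.ndarray:
    """Plain renormalized first-order gyro integration (used for the pelvis
    root, whose absolute orientation has no pairwise correction)."""
    T = t.size
    Q = np.empty((T, 4))
    Q[0] = quat_normalize(np.asarray(q0, dtype=float))
    dt = t[1] - t[0]
    for k in range(1, T):
        F = np.eye(4) + 0.5 * dt * omega_matrix(gyro[k - 1])
        Q[k] = quat_normalize(F @ Q[k - 1])
    return Q


def chain_orientations(trial: IMUTrial, model: BodyModel, params: EKFParams,
                       init_quats: dict[str, np.ndarray] | None = None,
                       calibration: IMUTrial | None = None,
                       refine_init_t: float | None = None) -> OrientationEstimate:
    """Global segment orientations by composing pairwise EKF estimates
    outward from the pelvis along the kinematic tree.

    Segments without a sensor are skipped (reduced-sensor mode); the sensor
    graph must stay connected from the pelvis through instrumented segments.

    ``refine_init_t`` enables a two-pass run for trials whose opening is only
    approximately static: after a first pass, the converged estimate at that
    time is backcast to t0 through each sensor's integrated gyro delta and
    the chain is re-run from the refined initial attitudes.
    """
    if init_quats is None:
        if calibration is not None:
            init_quats, _ = init_from_calibration(calibration, model)
        else:
            init_quats = {s: np.array([1.0, 0, 0, 0]) for s in trial.sensors}

    if refine_init_t is not None:
        first = chain_orientations(trial, model, params, init_quats=init_quats)
        k_ref = int(np.searchsorted(trial.t, trial.t[0] + refine_init_t))
        k_ref = min(k_ref, trial.t.size - 1)
        refined = {}
        for seg in first.segments:
            w, _ = gyro_rates_and_derivatives(trial, trial.idx(seg))
            delta = strapdown(trial.t[:k_ref + 1], w[:k_ref + 1],
                              np.array([1.0, 0, 0, 0]))[-1]
            refined[seg] = quat_normalize(
                quat_multiply(first.quat[first.idx(seg)][k_ref],
                              quat_conj(delta)))
        return chain_orientations(trial, model, params, init_quats=refined)
    if "pelvis" not in trial.sensors:
        raise ConfigurationError("pelvis sensor is required as the chain root")

    T = trial.t.size
    est: dict[str, np.ndarray] = {}
    i_p = trial.idx("pelvis")
    w_p, _ = gyro_rates_and_derivatives(trial, i_p)
    est["pelvis"] = strapdown(trial.t, w_p, init_quats["pelvis"])

    # walk joints in tree order so parents are estimated first
    for jname, _base, pseg, cseg, _nd in JOINTS:
        if cseg not in trial.sensors:
            continue
        if pseg not in est:
            raise ConfigurationError(
                f"sensor graph disconnected: {cseg} reachable only through "
                f"missing segment {pseg}")
        ps, cs, lev_p, lev_c = _pair_levers(model, jname)
        x0 = np.concatenate([init_quats[pseg], init_quats[cseg]])
        Qs, Qc = run_pair_ekf(trial, (ps, cs), params, lev_p, lev_c, x0=x0)
        child = np.empty((T, 4))
        for k in range(T):
            q_rel = quat_multiply(quat_conj(Qs[k]), Qc[k])
            child[k] = quat_normalize(quat_multiply(est[pseg][k], q_rel))
        est[cseg] = child

    segs = [s for s in SEGMENTS if s in est]
    quat = np.stack([est[s] for s in segs])
    return OrientationEstimate(segments=segs, t=trial.t, quat=quat)


def init_from_calibration(window: IMUTrial, model: BodyModel | None = None,
                          gyro_threshold: float = 0.2):
    """Initial per-sensor quaternions and neutral joint angles from a
    quasi-static calibration window.

    Roll and pitch come from the gravity direction of the time-averaged
    accelerometer signal; yaw is defined as zero in the calibration heading.
    Returns (init_quats, neutral_joint_angles).
    """
    gnorm = np.linalg.norm(window.gyro, axis=2).mean()
    if gnorm > gyro_threshold:
        raise CalibrationError(
            f"calibration window not static (mean |gyro| = {gnorm:.3f} rad/s)")
    init = {}
    for s, seg in enumerate(window.sensors):
        amean = window.accel[:, s, :].mean(axis=0)
        n = amean / np.linalg.norm(amean)
        # with R = Rx(phi) Ry(theta) Rz(0):  R^T e_z = (-sin th cos phi, sin phi, cos th cos phi)
        phi = np.arctan2(n[1], np.hypot(n[0], n[2]))
        theta = np.arctan2(-n[0], n[2])
        init[seg] = quat_from_euler_xyz([phi, theta, 0.0])
    neutral = {}
    if model is not None:
        for jname, _base, pseg, cseg, _nd in JOINTS:
            if pseg in init and cseg in init:
                q_rel = quat_multiply(quat_conj(init[pseg]), init[cseg])
                ang = euler_xyz(q_rel)
                for ax, val in zip(model.joints[jname].dof_axes, ang):
                    neutral[f"{jname}_{ax}"] = float(val)
    return init, neutral
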