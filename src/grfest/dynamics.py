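"""Forward dynamics of the articulated model.

Integrates ``M(q) q'' + Gamma(q, q', Fv, Fh, tau_virtual) = tau`` where tau
stacks active PD torques toward the reference joint angles, passive
limit-range torques, the virtual balance torque on the root Euler DOFs, and
the foot-ground contact forces entering through the point Jacobians.

The default integrator is LSODA (variable-step, stiff-capable): the contact
model's viscous term (D_G = 1e4 N/(m/s) per point) places fast real
eigenvalues in the foot dynamics during stance that make explicit
Runge-Kutta pairs take prohibitively small steps.  An explicit RK45 mode is
available through ``SolverOptions(method="rk45")``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint, solve_ivp

from . import _core, _fast
from .body import BodyModel, JointSpec, ModelState, ModelArrays, model_arrays
from .reference import ReferenceTrajectory

GRAVITY_VEC = np.array([0.0, 0.0, -_core.G])

#: penetration depth (m) over which the contact damping ramps in
DAMPING_RAMP_DEPTH = 1e-3


class SimulationError(RuntimeError):
    """Integration failure or state blow-up; carries the last valid time."""

    def __init__(self, msg, t_last=None):
        super().__init__(msg)
        self.t_last = t_last


@dataclass
class ControlGains:
    K_PD: float = 1000.0            # N m/rad
    D_PD: float = 10.0              # N m/(rad/s)
    K_virtual: np.ndarray = field(default_factory=lambda: np.array([400.0, 400.0, 0.0]))
    D_virtual: np.ndarray = field(default_factory=lambda: np.array([40.0, 40.0, 0.0]))

    def __post_init__(self):
        self.K_virtual = np.asarray(self.K_virtual, dtype=float)
        self.D_virtual = np.asarray(self.D_virtual, dtype=float)
        if self.K_PD < 0 or self.D_PD < 0 or np.any(self.K_virtual < 0) \
                or np.any(self.D_virtual < 0):
            raise ValueError("gains must be non-negative")


@dataclass
class GroundParams:
    K_G: float = 1.0e3              # N/m
    D_G: float = 1.0e4              # N/(m/s)
    mu_s: float = 0.7
    mu_d: float = 0.5
    rz0: float = 0.0                # ground height, m
    friction_reg_speed: float = 0.01  # m/s

    def __post_init__(self):
        if self.K_G <= 0 or self.D_G <= 0:
            raise ValueError("K_G and D_G must be positive")
        if not (self.mu_s >= self.mu_d >= 0):
            raise ValueError("require mu_s >= mu_d >= 0")


@dataclass
class SolverOptions:
    method: str = "lsoda"           # "lsoda" | "rk45" | "semi_implicit"
    rtol: float = 1e-6
    atol: float = 1e-8
    output_rate: float = 1000.0     # Hz
    mxstep: int = 10000             # LSODA internal-step cap per output interval
    dt: float = 1e-4                # fixed step of the semi-implicit method


@dataclass
class ContactForces:
    point_forces: np.ndarray        # (44, 3) world frame, N
    point_positions: np.ndarray     # (44, 3) world frame, m
    tau_virtual: np.ndarray         # (3,) N m on the root Euler DOFs

    @property
    def total_F(self) -> np.ndarray:
        return self.point_forces.sum(axis=0)

    @property
    def Fv(self) -> np.ndarray:
        return self.point_forces[:, 2]

    @property
    def Fh(self) -> np.ndarray:
        return self.point_forces[:, :2]


@dataclass
class SimResult:
    """Forward-dynamics output on a uniform time grid (public DOF order)."""

    t: np.ndarray                   # (T,)
    q: np.ndarray                   # (T, 27)
    q_dot: np.ndarray               # (T, 27)
    q_ddot: np.ndarray              # (T, 27)
    grf: np.ndarray                 # (T, 3) total ground reaction force, world
    point_forces: np.ndarray        # (T, 44, 3); points 0..21 left foot
    point_positions: np.ndarray     # (T, 44, 3)
    tau_a: np.ndarray               # (T, 21) active joint torques
    pelvis_acc: np.ndarray          # (T, 3) specific force, pelvis sensor frame
    seg_R: np.ndarray               # (T, 12, 3, 3) segment world rotations
    seg_p: np.ndarray               # (T, 12, 3) segment origins (proximal joints)
    model: BodyModel = None

    @property
    def rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def seg_quat(self) -> np.ndarray:
        """(12, T, 4) scalar-first unit quaternions of segment orientations."""
        from .quat import quat_from_matrix
        T = self.t.size
        out = np.empty((12, T, 4))
        for s in range(12):
            out[s] = quat_from_matrix(self.seg_R[:, s])
        return out

    def seg_euler(self) -> np.ndarray:
        """(12, T, 3) intrinsic X-Y-Z Euler angles of segment orientations."""
        from scipy.spatial.transform import Rotation
        T = self.t.size
        out = np.empty((12, T, 3))
        for s in range(12):
            out[s] = Rotation.from_matrix(self.seg_R[:, s]).as_euler("XYZ")
        return out


# ---------------------------------------------------------------------------
# elementary torque/force laws (spec-level operations; also used by the
# kernels in their numba form)
# ---------------------------------------------------------------------------

def active_torque(q_r, qd_r, q, qd, gains: ControlGains) -> np.ndarray:
    """PD control torque per controlled DOF."""
    q_r, qd_r, q, qd = map(np.asarray, (q_r, qd_r, q, qd))
    if not (q_r.shape == qd_r.shape == q.shape == qd.shape):
        raise ValueError("active_torque: dimension mismatch")
    return gains.K_PD * (q_r - q) + gains.D_PD * (qd_r - qd)


def passive_torque(q, qd, joint_spec: JointSpec) -> np.ndarray:
    """Double-exponential limit-range torque plus light viscous damping:
    near-zero in mid-range, restoring beyond the anatomical limits."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    qd = np.atleast_1d(np.asarray(qd, dtype=float))
    a = joint_spec.passive_params[:, 0]
    b = joint_spec.passive_params[:, 1]
    c = joint_spec.passive_params[:, 2]
    return (a * (np.exp(b * (joint_spec.q_min - q)) - np.exp(b * (q - joint_spec.q_max)))
            - c * qd)


def virtual_torque(q_virtual, qd_virtual, gains: ControlGains) -> np.ndarray:
    """Balance torque on the root Euler DOFs: -K q - D q'."""
    q_virtual = np.asarray(q_virtual, dtype=float)
    qd_virtual = np.asarray(qd_virtual, dtype=float)
    return -gains.K_virtual * q_virtual - gains.D_virtual * qd_virtual


def contact_force_law(point_positions, point_velocities,
                      ground: GroundParams) -> np.ndarray:
    """Per-point contact forces from world positions/velocities (vectorized
    mirror of the integration kernel; identical formulas)."""
    pos = np.atleast_2d(np.asarray(point_positions, dtype=float))
    vel = np.atleast_2d(np.asarray(point_velocities, dtype=float))
    F = np.zeros_like(pos)
    pen = pos[:, 2] < ground.rz0
    depth = ground.rz0 - pos[:, 2]
    # damping engages over the first millimetre of penetration so the normal
    # force is continuous at touchdown (keeps the stiff solver step size up)
    ramp_d = np.clip(depth / DAMPING_RAMP_DEPTH, 0.0, 1.0)
    Fv = np.where(pen, ground.K_G * depth - ground.D_G * vel[:, 2] * ramp_d, 0.0)
    Fv = np.maximum(Fv, 0.0)
    vh = np.hypot(vel[:, 0], vel[:, 1])
    mu = ground.mu_d + (ground.mu_s - ground.mu_d) * np.exp(-vh / ground.friction_reg_speed)
    ramp = np.minimum(vh / ground.friction_reg_speed, 1.0)
    Fh_mag = mu * Fv * ramp
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(vh > 1e-12, Fh_mag / np.where(vh > 0, vh, 1.0), 0.0)
    F[:, 0] = -scale * vel[:, 0]
    F[:, 1] = -scale * vel[:, 1]
    F[:, 2] = Fv
    return F


def contact_forces(model: BodyModel, state: ModelState,
                   ground: GroundParams | None = None,
                   gains: ControlGains | None = None) -> ContactForces:
    """Contact forces and virtual torque at a model state."""
    ground = ground or GroundParams()
    gains = gains or ControlGains()
    arr = _arrays(model)
    qi, qdi = _to_internal(arr, state.q, state.q_dot)
    Rw, pw, v, a, Es, rs = _core.kin_pass(qi, qdi, np.zeros(27), arr.parent,
                                          arr.jtype, arr.axis, arr.p_off, 0.0)
    Fpts, Ppts, _ = _core.contact_forces(Rw, pw, v, arr.cp_body, arr.cp_pos,
                                         ground.K_G, ground.D_G, ground.mu_s,
                                         ground.mu_d, ground.rz0,
                                         ground.friction_reg_speed)
    tv = virtual_torque(state.q[24:27], state.q_dot[24:27], gains)
    return ContactForces(point_forces=Fpts, point_positions=Ppts, tau_virtual=tv)


# ---------------------------------------------------------------------------
# equations of motion
# ---------------------------------------------------------------------------

_ARRAYS_CACHE: dict[int, ModelArrays] = {}


def _arrays(model: BodyModel) -> ModelArrays:
    key = id(model)
    if key not in _ARRAYS_CACHE:
        _ARRAYS_CACHE[key] = model_arrays(model)
    return _ARRAYS_CACHE[key]


def _to_internal(arr: ModelArrays, q_pub, qd_pub):
    return np.asarray(q_pub)[arr.int2pub], np.asarray(qd_pub)[arr.int2pub]


def eom_terms(model: BodyModel, state: ModelState,
              contact: ContactForces | None = None):
    """Inertia matrix M (27x27) and bias vector Gamma (27,) in public DOF
    order.  Gamma contains Coriolis/centrifugal, gravity, and (minus) the
    generalized contact and virtual-torque forces."""
    arr = _arrays(model)
    qi, qdi = _to_internal(arr, state.q, state.q_dot)
    Rw, pw, v, a, Es, rs = _core.kin_pass(qi, qdi, np.zeros(27), arr.parent,
                                          arr.jtype, arr.axis, arr.p_off, _core.G)
    fext = np.zeros((27, 6))
    if contact is not None:
        for k in range(arr.cp_body.size):
            b = arr.cp_body[k]
            F = contact.point_forces[k]
            fext[b, 3:] += F
            fext[b, :3] += np.cross(contact.point_positions[k] - pw[b], F)
    Gam_i = _core.rnea_from_pass(v, a, Rw, Es, rs, arr.parent, arr.jtype,
                                 arr.axis, arr.mass, arr.com, arr.inertia, fext)
    M_i = _core.crba(Es, rs, arr.parent, arr.jtype, arr.axis, arr.mass,
                     arr.com, arr.inertia)
    if contact is not None:
        Gam_i[3:6] -= contact.tau_virtual
    # permute to public order
    P = arr.int2pub
    M = np.empty((27, 27))
    M[np.ix_(P, P)] = M_i
    Gam = np.empty(27)
    Gam[P] = Gam_i
    return M, Gam


def assemble_and_solve(model: BodyModel, state: ModelState, tau: np.ndarray,
                       contact: ContactForces | None = None,
                       locked: np.ndarray | None = None) -> np.ndarray:
    """Generalized accelerations M^-1 (tau_full - Gamma), public DOF order.

    ``tau`` is the 21-vector of joint torques (root DOFs receive no
    actuation beyond contact/virtual contributions).  ``locked`` optionally
    marks DOFs held at zero acceleration; the reduced system is solved on
    the free DOFs.
    """
    tau_full = np.zeros(27)
    tau_full[:21] = np.asarray(tau, dtype=float)
    M, Gam = eom_terms(model, state, contact)
    b = tau_full - Gam
    qdd = np.zeros(27)
    if locked is None:
        free = np.arange(27)
    else:
        free = np.flatnonzero(~np.asarray(locked, dtype=bool))
    try:
        qdd[free] = np.linalg.solve(M[np.ix_(free, free)], b[free])
    except np.linalg.LinAlgError as exc:
        raise SimulationError(f"singular inertia matrix at state q={state.q}") from exc
    return qdd


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _kernel_args(arr: ModelArrays, traj: ReferenceTrajectory,
                 gains: ControlGains, ground: GroundParams, grav: float):
    """Argument tuple for the fused kernel (`grfest._fast`)."""
    breaks, coefs, nseg = traj.packed()
    jointdof_int = arr.pub2int[:21]
    aid = np.argmax(np.abs(arr.axis), axis=1).astype(np.int64)
    pscal = np.array([gains.K_PD, gains.D_PD, ground.K_G, ground.D_G,
                      ground.mu_s, ground.mu_d, ground.rz0,
                      ground.friction_reg_speed, grav])
    return (arr.parent, arr.jtype, aid, arr.p_off, arr.mass, arr.com,
            arr.inertia, jointdof_int, breaks, coefs, nseg,
            gains.K_virtual, gains.D_virtual, arr.q_min, arr.q_max,
            arr.passive, arr.cp_body, arr.cp_pos, pscal)


def simulate(model: BodyModel, reference: ReferenceTrajectory,
             gains: ControlGains | None = None,
             ground: GroundParams | None = None,
             t_span: tuple[float, float] | None = None,
             solver_opts: SolverOptions | None = None,
             initial_state: ModelState | None = None,
             gravity: bool = True) -> SimResult:
    """Integrate the forward dynamics under a reference trajectory."""
    from .body import neutral_pose

    gains = gains or ControlGains()
    ground = ground or GroundParams()
    opts = solver_opts or SolverOptions()
    t_span = t_span or reference.t_span
    # before its first node the reference holds the starting value (static
    # lead-in); it may not end before the simulation does
    if t_span[1] > reference.t_span[1] + 1e-12:
        raise ValueError("reference ends before the simulation span")
    state0 = initial_state or neutral_pose(model)
    arr = _arrays(model)
    grav = _core.G if gravity else 0.0
    args = _kernel_args(arr, reference, gains, ground, grav)
    return _simulate_core(model, arr, args, state0, t_span, opts, grav)


def _simulate_core(model, arr, args, state0, t_span, opts, grav):
    # the kernels bake gravity in via _core.G; zero-gravity runs patch masses'
    # weight out by integrating with gravity-free kinematics (see rhs_nog)
    qi, qdi = _to_internal(arr, state0.q, state0.q_dot)
    y0 = np.concatenate([qi, qdi])
    nout = max(2, int(round((t_span[1] - t_span[0]) * opts.output_rate)) + 1)
    tgrid = np.linspace(t_span[0], t_span[1], nout)
    targs = tuple(args)
    Fbuf = np.empty((44, 3))
    Pbuf = np.empty((44, 3))

    def fun(t, y):
        return _fast.rhs_fast(t, y, *targs, Fbuf, Pbuf)

    if opts.method == "lsoda":
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            Y, info = odeint(fun, y0, tgrid, rtol=opts.rtol, atol=opts.atol,
                             tfirst=True, full_output=True, mxstep=opts.mxstep)
        if info["message"] != "Integration successful.":
            raise SimulationError(f"integration failed: {info['message']}",
                                  float(info["tcur"][-1]) if len(info.get("tcur", [])) else None)
    elif opts.method == "semi_implicit":
        # fixed-step, contact damping treated implicitly (the stiff part);
        # used for the many candidate evaluations inside the optimizer
        stride = max(1, int(round(1.0 / (opts.output_rate * opts.dt))))
        dt = 1.0 / (opts.output_rate * stride)
        nsteps = (nout - 1) * stride
        Y, ok = _fast.semi_implicit_run(y0, t_span[0], dt, nsteps, stride,
                                        *targs)
        if not ok or Y.shape[0] != nout:
            t_last = t_span[0] + (Y.shape[0] - 1) / opts.output_rate
            raise SimulationError("state blow-up (semi-implicit step)", t_last)
    elif opts.method == "rk45":
        sol = solve_ivp(fun, t_span, y0, method="RK45", t_eval=tgrid,
                        rtol=opts.rtol, atol=opts.atol)
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}",
                                  sol.t[-1] if sol.t.size else t_span[0])
        Y = sol.y.T
    else:
        raise ValueError(f"unknown solver method {opts.method!r}")

    if not np.all(np.isfinite(Y)):
        bad = np.flatnonzero(~np.all(np.isfinite(Y), axis=1))[0]
        raise SimulationError("state blow-up (non-finite values)",
                              tgrid[max(0, bad - 1)])
    # hard-stop diagnostic: joint angles beyond limits by more than 1 rad
    Qj = Y[:, :27]
    over = (Qj < arr.q_min - 1.0) | (Qj > arr.q_max + 1.0)
    if np.any(over):
        bad = np.flatnonzero(np.any(over, axis=1))[0]
        raise SimulationError("joint angle exceeded its limit by > 1 rad",
                              tgrid[max(0, bad - 1)])
    return _postprocess(model, arr, targs, tgrid, Y, grav)


def _postprocess(model, arr, targs, tgrid, Y, grav):
    T = tgrid.size
    qdd = np.empty((T, 27))
    Fpts = np.empty((T, 44, 3))
    Ppts = np.empty((T, 44, 3))
    tau_a = np.empty((T, 21))
    for ti in range(T):
        acc, ta = _fast.dyn_fast(tgrid[ti], Y[ti], *targs, Fpts[ti], Ppts[ti])
        qdd[ti] = acc
        tau_a[ti] = ta
    Q, Qd, Qdd = Y[:, :27], Y[:, 27:], qdd

    # pelvis-sensor specific force
    pelvis_mount = next(m for m in model.mountings if m.segment == "pelvis")
    from .quat import quat_to_matrix
    Rm = quat_to_matrix(pelvis_mount.mount_rotation)
    sens_body = np.array([arr.seg_body[0]])
    acc_s, _ = _core.sensor_series(Q, Qd, Qdd, arr.parent, arr.jtype, arr.axis,
                                   arr.p_off, sens_body,
                                   pelvis_mount.lever_arm[None, :],
                                   Rm[None, :, :], grav)
    pelvis_acc = acc_s[:, 0, :]

    segR, segp, _, _ = _core.body_kinematics_series(Q, Qd, Qdd, arr.parent,
                                                    arr.jtype, arr.axis,
                                                    arr.p_off, arr.seg_body)
    P = arr.int2pub
    q_pub = np.empty_like(Q)
    qd_pub = np.empty_like(Qd)
    qdd_pub = np.empty_like(Qdd)
    q_pub[:, P] = Q
    qd_pub[:, P] = Qd
    qdd_pub[:, P] = Qdd
    # per-public-joint active torques: tau_a comes out in public order already
    return SimResult(t=tgrid, q=q_pub, q_dot=qd_pub, q_ddot=qdd_pub,
                     grf=Fpts.sum(axis=1), point_forces=Fpts,
                     point_positions=Ppts, tau_a=tau_a,
                     pelvis_acc=pelvis_acc, seg_R=segR, seg_p=segp,
                     model=model)


# ---------------------------------------------------------------------------
# derived outputs and diagnostics
# ---------------------------------------------------------------------------

def grm_about_ankle(sim: SimResult, model: BodyModel, side: str = "l") -> np.ndarray:
    """Ground reaction moment of one foot's contact forces about the ankle
    centre projected onto the ground, in the foot-aligned horizontal frame.

    Components: (sagittal: about the lateral axis, frontal: about the
    anterior axis, transverse: about the vertical axis).
    """
    from .body import SEGMENTS
    seg = SEGMENTS.index(f"foot_{side}")
    sl = slice(0, 22) if side == "l" else slice(22, 44)
    T = sim.t.size
    out = np.empty((T, 3))
    up = np.array([0.0, 0.0, 1.0])
    for ti in range(T):
        ankle = sim.seg_p[ti, seg]
        origin = np.array([ankle[0], ankle[1], 0.0])
        M = np.zeros(3)
        for k in range(sl.start, sl.stop):
            M += np.cross(sim.point_positions[ti, k] - origin,
                          sim.point_forces[ti, k])
        ant = sim.seg_R[ti, seg] @ np.array([0.0, -1.0, 0.0])
        ant[2] = 0.0
        n = np.linalg.norm(ant)
        ant = ant / n if n > 1e-9 else np.array([0.0, -1.0, 0.0])
        lat = np.cross(up, ant)
        out[ti] = (M @ lat, M @ ant, M @ up)
    return out


def com_series(sim: SimResult, model: BodyModel) -> np.ndarray:
    """Whole-body COM position over time (T, 3)."""
    from .body import SEGMENTS
    masses = np.array([model.segments[s].mass for s in SEGMENTS])
    coms = np.array([model.segments[s].com_offset for s in SEGMENTS])
    pos = sim.seg_p + np.einsum("tsij,sj->tsi", sim.seg_R, coms)
    return (masses[:, None] * pos.transpose(1, 0, 2)).sum(axis=0) / masses.sum()


def newton_residual(sim: SimResult, model: BodyModel) -> np.ndarray:
    """|| m a_COM - (GRF + m g) || per sample (N): the whole-body Newton
    check.  Uses the analytic COM acceleration from the integrated states."""
    arr = _arrays(model)
    P = arr.int2pub
    Q = sim.q[:, P]
    Qd = sim.q_dot[:, P]
    Qdd = sim.q_ddot[:, P]
    sf = _core.com_specific_force_series(Q, Qd, Qdd, arr.parent, arr.jtype,
                                         arr.axis, arr.p_off, arr.mass, arr.com)
    resid = model.total_mass * sf - sim.grf
    return np.linalg.norm(resid, axis=1)


def angular_momentum(sim: SimResult, model: BodyModel) -> np.ndarray:
    """Whole-body angular momentum about the COM (T, 3), kg m^2/s."""
    from .body import SEGMENTS
    arr = _arrays(model)
    P = arr.int2pub
    segR, segp, segw, segv = _core.body_kinematics_series(
        sim.q[:, P], sim.q_dot[:, P], sim.q_ddot[:, P],
        arr.parent, arr.jtype, arr.axis, arr.p_off, arr.seg_body)
    masses = np.array([model.segments[s].mass for s in SEGMENTS])
    coms = np.array([model.segments[s].com_offset for s in SEGMENTS])
    inertias = np.array([model.segments[s].inertia for s in SEGMENTS])
    T = sim.t.size
    L = np.zeros((T, 3))
    for ti in range(T):
        rc_all = segp[ti] + np.einsum("sij,sj->si", segR[ti], coms)
        vc_all = segv[ti] + np.cross(segw[ti], np.einsum("sij,sj->si", segR[ti], coms))
        rC = (masses[:, None] * rc_all).sum(axis=0) / masses.sum()
        vC = (masses[:, None] * vc_all).sum(axis=0) / masses.sum()
        for s in range(12):
            Iw = segR[ti, s] @ inertias[s] @ segR[ti, s].T
            L[ti] += Iw @ segw[ti, s]
            L[ti] += masses[s] * np.cross(rc_all[s] - rC, vc_all[s] - vC)
    return L
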