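"""Reference joint-angle trajectories parameterized by spline nodes.

Each of the 21 controlled DOFs gets a cubic spline through a small set of
node values at fixed, evenly spaced node times; the node values are the
search variables of the trajectory optimization.  Node counts follow the
role rule: upper-body joints (lumbar, shoulders, elbows) get 2 nodes at the
motion start and end, jump-leg joints (hips, knees, ankles of the configured
jump legs) get 5 evenly spaced nodes, all other joints get 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .body import BodyModel, JOINTS, ConfigurationError

UPPER_BODY = {"lumbar", "shoulder", "elbow"}
LEG = {"hip", "knee", "ankle"}


class ExtrapolationError(ValueError):
    """Raised when a reference trajectory is evaluated outside its span."""


@dataclass
class ReferenceTrajectory:
    """Per-DOF node times and values (public joint-DOF order, 21 entries)."""

    dof_names: list[str]
    node_times: list[np.ndarray]
    node_values: list[np.ndarray]
    t_span: tuple[float, float] = (0.0, 1.0)
    _packed: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for nm, times in zip(self.dof_names, self.node_times):
            if np.any(np.diff(times) <= 0):
                raise ConfigurationError(f"{nm}: node times must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.node_values)

    # ---- GA packing -----------------------------------------------------
    def vector(self) -> np.ndarray:
        return np.concatenate(self.node_values)

    def with_vector(self, x: np.ndarray) -> "ReferenceTrajectory":
        vals, k = [], 0
        for v in self.node_values:
            vals.append(np.asarray(x[k:k + len(v)], dtype=float))
            k += len(v)
        if k != len(x):
            raise ValueError("node vector length mismatch")
        return ReferenceTrajectory(self.dof_names, self.node_times, vals, self.t_span)

    # ---- spline machinery ----------------------------------------------
    def splines(self) -> list[CubicSpline]:
        out = []
        for t, v in zip(self.node_times, self.node_values):
            if len(t) == 2:
                # two nodes: linear interpolant expressed as a degenerate cubic
                slope = (v[1] - v[0]) / (t[1] - t[0])
                cs = CubicSpline(t, v, bc_type=((1, slope), (1, slope)))
            else:
                # motion starts from rest: clamp the start derivative to zero,
                # natural (zero-curvature) end
                cs = CubicSpline(t, v, bc_type=((1, 0.0), (2, 0.0)))
            out.append(cs)
        return out

    def packed(self):
        """Padded (breaks, coefs, nseg) arrays for the numba kernels."""
        if self._packed is None:
            splines = self.splines()
            mmax = max(len(t) for t in self.node_times)
            breaks = np.zeros((21, mmax))
            coefs = np.zeros((21, mmax - 1, 4))
            nseg = np.zeros(21, dtype=np.int64)
            for k, cs in enumerate(splines):
                ns = cs.x.size - 1
                breaks[k, :ns + 1] = cs.x
                breaks[k, ns + 1:] = cs.x[-1]
                coefs[k, :ns, :] = cs.c.T
                nseg[k] = ns
            object.__setattr__(self, "_packed", (breaks, coefs, nseg))
        return self._packed


def spline_reference(traj: ReferenceTrajectory, t) -> tuple[np.ndarray, np.ndarray]:
    """Reference angles and angular velocities at time(s) t, per DOF.

    Returns arrays of shape (21,) for scalar t or (21, len(t)) otherwise.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lo, hi = traj.t_span
    if np.any(t_arr < lo - 1e-12) or np.any(t_arr > hi + 1e-12):
        raise ExtrapolationError(f"t outside the motion span [{lo}, {hi}]")
    q = np.empty((21, t_arr.size))
    qd = np.empty((21, t_arr.size))
    for k, cs in enumerate(traj.splines()):
        tc = np.clip(t_arr, cs.x[0], cs.x[-1])
        q[k] = cs(tc)
        qd[k] = cs(tc, 1)
    if np.isscalar(t) or np.ndim(t) == 0:
        return q[:, 0], qd[:, 0]
    return q, qd


def allocate_nodes(model: BodyModel, motion_span: tuple[float, float],
                   role_config: dict | None = None) -> ReferenceTrajectory:
    """Skeleton trajectory (all node values zero) with the role-based node
    counts: 2 for upper-body joints, 5 for jump-leg joints, 3 otherwise."""
    role_config = role_config or {}
    jump_legs = role_config.get("jump_legs", ["l", "r"])
    overrides = role_config.get("roles", {})
    t0, t1 = motion_span
    names, times, values = [], [], []
    for jname, base, _p, _c, nd in JOINTS:
        if jname in overrides:
            role = overrides[jname]
        elif base in UPPER_BODY:
            role = "upper"
        elif base in LEG:
            side = jname.rsplit("_", 1)[-1]
            role = "jump" if side in jump_legs else "other"
        else:
            raise ConfigurationError(f"joint {jname!r} has no role")
        m = {"upper": 2, "jump": 5, "other": 3}.get(role)
        if m is None:
            raise ConfigurationError(f"unknown role {role!r} for joint {jname}")
        for ax in model.joints[jname].dof_axes:
            names.append(f"{jname}_{ax}")
            times.append(np.linspace(t0, t1, m))
            values.append(np.zeros(m))
    return ReferenceTrajectory(names, times, values, t_span=(t0, t1))


def constant_reference(model: BodyModel, q_joint: np.ndarray,
                       motion_span: tuple[float, float],
                       role_config: dict | None = None) -> ReferenceTrajectory:
    """All nodes held at the given 21-vector of joint angles."""
    traj = allocate_nodes(model, motion_span, role_config)
    vals = [np.full_like(v, q_joint[k]) for k, v in enumerate(traj.node_values)]
    return ReferenceTrajectory(traj.dof_names, traj.node_times, vals, traj.t_span)
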