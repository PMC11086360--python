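"""Numba kernels for the articulated rigid-body dynamics.

All kernels work on the flattened 27-node tree from
:func:`grfest.body.model_arrays` (internal ordering: 6 root DOFs then joint
clusters; every node is a 1-DOF prismatic or revolute joint, and nodes at the
distal end of a joint cluster carry a segment's mass properties).

Spatial (6D) vectors are ordered [angular; linear] and expressed in the local
body frame at the body origin.  Gravity enters through the standard base-
acceleration trick, so the linear accelerations propagated here are specific
forces (true acceleration minus gravity) -- exactly what an accelerometer
measures.
"""

import warnings

import numpy as np
from numba import njit
from numba.core.errors import NumbaPerformanceWarning

# these are the clear reference kernels; the contiguity advisories do not
# matter off the hot path (grfest._fast carries the integration load)
warnings.simplefilter("ignore", NumbaPerformanceWarning)

G = 9.81


@njit(cache=True)
def _cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True)
def _rodrigues(axis, q):
    """Rotation matrix about a unit axis by angle q."""
    c, s = np.cos(q), np.sin(q)
    x, y, z = axis[0], axis[1], axis[2]
    C = 1.0 - c
    R = np.empty((3, 3))
    R[0, 0] = c + x * x * C
    R[0, 1] = x * y * C - z * s
    R[0, 2] = x * z * C + y * s
    R[1, 0] = y * x * C + z * s
    R[1, 1] = c + y * y * C
    R[1, 2] = y * z * C - x * s
    R[2, 0] = z * x * C - y * s
    R[2, 1] = z * y * C + x * s
    R[2, 2] = c + z * z * C
    return R


@njit(cache=True)
def kin_pass(q, qd, qdd, parent, jtype, axis, p_off, grav):
    """Outward kinematics pass.

    Returns world rotations/origins, body-frame spatial velocities and
    accelerations, and the per-node joint transforms (E: node-from-parent
    rotation, r: node origin in parent frame).  ``grav`` > 0 applies the
    base-acceleration trick so linear accelerations are specific forces.
    """
    n = q.shape[0]
    Rw = np.zeros((n, 3, 3))
    pw = np.zeros((n, 3))
    v = np.zeros((n, 6))
    a = np.zeros((n, 6))
    Es = np.zeros((n, 3, 3))
    rs = np.zeros((n, 3))
    for i in range(n):
        ax = axis[i]
        if jtype[i] == 1:
            Rj = _rodrigues(ax, q[i])
            E = Rj.T
            r = p_off[i].copy()
        else:
            E = np.eye(3)
            r = p_off[i] + q[i] * ax
        Es[i] = E
        rs[i] = r
        p = parent[i]
        if p >= 0:
            Rp = Rw[p]
            pp = pw[p]
            vp = v[p]
            ap = a[p]
        else:
            Rp = np.eye(3)
            pp = np.zeros(3)
            vp = np.zeros(6)
            ap = np.zeros(6)
            ap[5] = grav
        Rw[i] = Rp @ E.T
        pw[i] = pp + Rp @ r
        # spatial velocity: v_i = X v_p + S qd
        wq = E @ vp[:3]
        vq = E @ (vp[3:] + _cross(vp[:3], r))
        # spatial acceleration: a_i = X a_p + S qdd + v_i x (S qd)
        aw = E @ ap[:3]
        av = E @ (ap[3:] + _cross(ap[:3], r))
        if jtype[i] == 1:
            sv = ax * qd[i]
            v[i, :3] = wq + sv
            v[i, 3:] = vq
            a[i, :3] = aw + ax * qdd[i] + _cross(v[i, :3], sv)
            a[i, 3:] = av + _cross(v[i, 3:], sv)
        else:
            sv = ax * qd[i]
            v[i, :3] = wq
            v[i, 3:] = vq + sv
            a[i, :3] = aw
            a[i, 3:] = av + ax * qdd[i] + _cross(v[i, :3], sv)
    return Rw, pw, v, a, Es, rs


@njit(cache=True)
def rnea_from_pass(v, a, Rw, Es, rs, parent, jtype, axis, mass, com, inertia, fext_w):
    """Inward Newton-Euler pass: generalized forces given body kinematics and
    external wrenches (world coords, about each body origin)."""
    n = v.shape[0]
    f = np.zeros((n, 6))
    for i in range(n):
        m = mass[i]
        if m > 0.0:
            c = com[i]
            Ic = inertia[i]
            w = v[i, :3]
            vO = v[i, 3:]
            al = a[i, :3]
            aO = a[i, 3:]
            aC = aO + _cross(al, c) + _cross(w, vO + _cross(w, c))
            F = m * aC
            N = Ic @ al + _cross(w, Ic @ w)
            f[i, :3] = N + _cross(c, F)
            f[i, 3:] = F
        f[i, :3] -= Rw[i].T @ fext_w[i, :3]
        f[i, 3:] -= Rw[i].T @ fext_w[i, 3:]
    tau = np.zeros(n)
    for i in range(n - 1, -1, -1):
        if jtype[i] == 1:
            tau[i] = axis[i] @ f[i, :3]
        else:
            tau[i] = axis[i] @ f[i, 3:]
        p = parent[i]
        if p >= 0:
            E = Es[i]
            r = rs[i]
            Fp = E.T @ f[i, 3:]
            f[p, :3] += E.T @ f[i, :3] + _cross(r, Fp)
            f[p, 3:] += Fp
    return tau


@njit(cache=True)
def crba(Es, rs, parent, jtype, axis, mass, com, inertia):
    """Composite-rigid-body mass matrix (27x27, symmetric PD)."""
    n = parent.shape[0]
    Ic = np.zeros((n, 6, 6))
    for i in range(n):
        m = mass[i]
        if m > 0.0:
            c = com[i]
            cx = np.zeros((3, 3))
            cx[0, 1] = -c[2]
            cx[0, 2] = c[1]
            cx[1, 0] = c[2]
            cx[1, 2] = -c[0]
            cx[2, 0] = -c[1]
            cx[2, 1] = c[0]
            Ic[i, :3, :3] = inertia[i] + m * (cx @ cx.T)
            Ic[i, :3, 3:] = m * cx
            Ic[i, 3:, :3] = m * cx.T
            Ic[i, 3, 3] = m
            Ic[i, 4, 4] = m
            Ic[i, 5, 5] = m
    # motion transforms child-from-parent: X = [[E, 0], [-E rx, E]]
    X = np.zeros((n, 6, 6))
    for i in range(n):
        E = Es[i]
        r = rs[i]
        rx = np.zeros((3, 3))
        rx[0, 1] = -r[2]
        rx[0, 2] = r[1]
        rx[1, 0] = r[2]
        rx[1, 2] = -r[0]
        rx[2, 0] = -r[1]
        rx[2, 1] = r[0]
        X[i, :3, :3] = E
        X[i, 3:, 3:] = E
        X[i, 3:, :3] = -(E @ rx)
    for i in range(n - 1, -1, -1):
        p = parent[i]
        if p >= 0:
            Ic[p] += X[i].T @ Ic[i] @ X[i]
    M = np.zeros((n, n))
    for i in range(n):
        S = np.zeros(6)
        if jtype[i] == 1:
            S[:3] = axis[i]
        else:
            S[3:] = axis[i]
        F = Ic[i] @ S
        M[i, i] = S @ F
        j = i
        while parent[j] >= 0:
            F = X[j].T @ F
            j = parent[j]
            if jtype[j] == 1:
                M[i, j] = F[:3] @ axis[j]
            else:
                M[i, j] = F[3:] @ axis[j]
            M[j, i] = M[i, j]
    return M


@njit(cache=True)
def contact_forces(Rw, pw, v, cp_body, cp_pos, KG, DG, mus, mud, rz0, v0):
    """Per-point viscoelastic normal force and regularized Coulomb friction.

    Normal force is clamped to zero outside penetration and floored at zero
    (no ground suction); friction magnitude is mu(v_h) * Fv with
    mu(v_h) = mu_d + (mu_s - mu_d) exp(-v_h / v0) and a linear ramp below the
    regularization speed v0, so |Fh| <= mu_s * Fv always.
    """
    ncp = cp_body.shape[0]
    Fpts = np.zeros((ncp, 3))
    Ppts = np.zeros((ncp, 3))
    fext = np.zeros((pw.shape[0], 6))
    for k in range(ncp):
        b = cp_body[k]
        r = cp_pos[k]
        pos = pw[b] + Rw[b] @ r
        vel = Rw[b] @ (v[b, 3:] + _cross(v[b, :3], r))
        Ppts[k] = pos
        d = pos[2] - rz0
        if d < 0.0:
            ramp_d = min(1.0, -d / 0.001)
            Fz = -KG * d - DG * vel[2] * ramp_d
            if Fz < 0.0:
                Fz = 0.0
            if Fz > 0.0:
                vh = np.sqrt(vel[0] ** 2 + vel[1] ** 2)
                mu = mud + (mus - mud) * np.exp(-vh / v0)
                ramp = vh / v0 if vh < v0 else 1.0
                Fh = mu * Fz * ramp
                Fx = 0.0
                Fy = 0.0
                if vh > 1e-12:
                    Fx = -Fh * vel[0] / vh
                    Fy = -Fh * vel[1] / vh
                Fpts[k, 0] = Fx
                Fpts[k, 1] = Fy
                Fpts[k, 2] = Fz
                fext[b, 3] += Fx
                fext[b, 4] += Fy
                fext[b, 5] += Fz
                arm = pos - pw[b]
                fext[b, :3] += _cross(arm, Fpts[k])
    return Fpts, Ppts, fext


@njit(cache=True)
def eval_ppoly(breaks, coefs, nseg, t):
    """Evaluate a piecewise cubic (scipy PPoly layout) and its derivative,
    clamping t to the covered span."""
    t0 = breaks[0]
    t1 = breaks[nseg]
    if t < t0:
        t = t0
    elif t > t1:
        t = t1
    i = nseg - 1
    for k in range(nseg):
        if t < breaks[k + 1]:
            i = k
            break
    dt = t - breaks[i]
    c0, c1, c2, c3 = coefs[i, 0], coefs[i, 1], coefs[i, 2], coefs[i, 3]
    val = ((c0 * dt + c1) * dt + c2) * dt + c3
    der = (3.0 * c0 * dt + 2.0 * c1) * dt + c2
    return val, der


@njit(cache=True)
def joint_torques(t, q, qd, jointdof_int, spl_breaks, spl_coefs, spl_nseg,
                  KPD, DPD, q_min, q_max, passive, Kv, Dv):
    """Active PD + passive limit torques on the 21 joint DOFs and the virtual
    balance torque on the root Euler DOFs.  Returns (tau_full, tau_a_pub)."""
    n = q.shape[0]
    tau = np.zeros(n)
    tau_a = np.zeros(21)
    for k in range(21):
        i = jointdof_int[k]
        qr, qdr = eval_ppoly(spl_breaks[k], spl_coefs[k], spl_nseg[k], t)
        ta = KPD * (qr - q[i]) + DPD * (qdr - qd[i])
        aP = passive[i, 0]
        bP = passive[i, 1]
        cP = passive[i, 2]
        tp = aP * (np.exp(bP * (q_min[i] - q[i])) - np.exp(bP * (q[i] - q_max[i]))) - cP * qd[i]
        tau[i] = ta + tp
        tau_a[k] = ta
    for d in range(3):
        i = 3 + d
        tau[i] += -Kv[d] * q[i] - Dv[d] * qd[i]
    return tau, tau_a


@njit(cache=True)
def dyn_eval(t, y, parent, jtype, axis, p_off, mass, com, inertia,
             jointdof_int, spl_breaks, spl_coefs, spl_nseg,
             KPD, DPD, q_min, q_max, passive, Kv, Dv,
             KG, DG, mus, mud, rz0, v0, cp_body, cp_pos, grav):
    """Full dynamics evaluation at one state: generalized accelerations plus
    per-contact-point forces/positions and the active joint torques."""
    n = 27
    q = y[:n]
    qd = y[n:]
    zero = np.zeros(n)
    Rw, pw, v, a, Es, rs = kin_pass(q, qd, zero, parent, jtype, axis, p_off, grav)
    Fpts, Ppts, fext = contact_forces(Rw, pw, v, cp_body, cp_pos,
                                      KG, DG, mus, mud, rz0, v0)
    tau, tau_a = joint_torques(t, q, qd, jointdof_int, spl_breaks, spl_coefs,
                               spl_nseg, KPD, DPD, q_min, q_max, passive, Kv, Dv)
    Gam = rnea_from_pass(v, a, Rw, Es, rs, parent, jtype, axis, mass, com,
                         inertia, fext)
    M = crba(Es, rs, parent, jtype, axis, mass, com, inertia)
    qdd = np.linalg.solve(M, tau - Gam)
    return qdd, Fpts, Ppts, tau_a


@njit(cache=True)
def rhs(t, y, parent, jtype, axis, p_off, mass, com, inertia,
        jointdof_int, spl_breaks, spl_coefs, spl_nseg,
        KPD, DPD, q_min, q_max, passive, Kv, Dv,
        KG, DG, mus, mud, rz0, v0, cp_body, cp_pos, grav):
    qdd, _, _, _ = dyn_eval(t, y, parent, jtype, axis, p_off, mass, com,
                            inertia, jointdof_int, spl_breaks, spl_coefs,
                            spl_nseg, KPD, DPD, q_min, q_max, passive, Kv, Dv,
                            KG, DG, mus, mud, rz0, v0, cp_body, cp_pos, grav)
    out = np.empty(54)
    out[:27] = y[27:]
    out[27:] = qdd
    return out


@njit(cache=True)
def point_acc(Rw, v, a, b, r):
    """Specific force (world frame) of the body-fixed point r on body b,
    given a kin_pass run with the gravity trick."""
    al = a[b, :3]
    aO = a[b, 3:]
    w = v[b, :3]
    vO = v[b, 3:]
    acl = aO + _cross(al, r) + _cross(w, vO + _cross(w, r))
    return Rw[b] @ acl


@njit(cache=True)
def sensor_series(Q, Qd, Qdd, parent, jtype, axis, p_off,
                  sens_body, sens_pos, sens_rot, grav=G):
    """Ideal IMU signals for every sensor over a trajectory.

    Q, Qd, Qdd: (T, 27) internal coordinates.  Returns accel (T, S, 3)
    specific force in sensor frame and gyro (T, S, 3) angular velocity in
    sensor frame.
    """
    T = Q.shape[0]
    S = sens_body.shape[0]
    acc = np.zeros((T, S, 3))
    gyr = np.zeros((T, S, 3))
    for ti in range(T):
        Rw, pw, v, a, Es, rs = kin_pass(Q[ti], Qd[ti], Qdd[ti], parent, jtype,
                                        axis, p_off, grav)
        for s in range(S):
            b = sens_body[s]
            f_world = point_acc(Rw, v, a, b, sens_pos[s])
            Rm = sens_rot[s]
            acc[ti, s] = Rm.T @ (Rw[b].T @ f_world)
            gyr[ti, s] = Rm.T @ v[b, :3]
    return acc, gyr


@njit(cache=True)
def com_specific_force_series(Q, Qd, Qdd, parent, jtype, axis, p_off, mass, com_of):
    """Mass-weighted specific force of the whole-body COM (world frame) over a
    trajectory: equals a_COM - g, so the Newton check reduces to
    ``total_mass * sf_COM == total GRF``."""
    T = Q.shape[0]
    n = parent.shape[0]
    out = np.zeros((T, 3))
    mtot = 0.0
    for i in range(n):
        mtot += mass[i]
    for ti in range(T):
        Rw, pw, v, a, Es, rs = kin_pass(Q[ti], Qd[ti], Qdd[ti], parent, jtype,
                                        axis, p_off, G)
        acc = np.zeros(3)
        for i in range(n):
            if mass[i] > 0.0:
                acc += mass[i] * point_acc(Rw, v, a, i, com_of[i])
        out[ti] = acc / mtot
    return out


@njit(cache=True)
def body_kinematics_series(Q, Qd, Qdd, parent, jtype, axis, p_off, bodies):
    """World rotation, origin, angular velocity (world) and COM-frame data for
    selected bodies over a trajectory: returns (T, B, 3, 3) rotations,
    (T, B, 3) origins, (T, B, 3) world angular velocities and (T, B, 3)
    world linear velocities of the body origins."""
    T = Q.shape[0]
    B = bodies.shape[0]
    Rout = np.zeros((T, B, 3, 3))
    pout = np.zeros((T, B, 3))
    wout = np.zeros((T, B, 3))
    vout = np.zeros((T, B, 3))
    for ti in range(T):
        Rw, pw, v, a, Es, rs = kin_pass(Q[ti], Qd[ti], Qdd[ti], parent, jtype,
                                        axis, p_off, 0.0)
        for k in range(B):
            b = bodies[k]
            Rout[ti, k] = Rw[b]
            pout[ti, k] = pw[b]
            wout[ti, k] = Rw[b] @ v[b, :3]
            vout[ti, k] = Rw[b] @ v[b, 3:]
    return Rout, pout, wout, vout
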