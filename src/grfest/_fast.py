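"""Allocation-free fused dynamics kernel.

Functionally identical to the clear-reference kernels in ``grfest._core``
(kin_pass + contact_forces + joint_torques + rnea_from_pass + crba + solve),
but specialized to basis-vector joint axes and written with manual scalar
loops so a full right-hand-side evaluation stays in the tens of
microseconds.  The agreement of the two paths on random states is asserted
in the test suite.
"""

import numpy as np
from numba import njit

# scalar-parameter packing order for pscal
IDX_KPD, IDX_DPD, IDX_KG, IDX_DG, IDX_MUS, IDX_MUD, IDX_RZ0, IDX_V0, IDX_GRAV = range(9)


@njit(cache=True)
def _spline_eval(breaks, coefs, nseg, t):
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
    return (((c0 * dt + c1) * dt + c2) * dt + c3,
            (3.0 * c0 * dt + 2.0 * c1) * dt + c2)


@njit(cache=True)
def _chol_solve(M, b):
    """Cholesky solve for the SPD mass/iteration matrices (faster than the
    LAPACK round-trip at n = 27)."""
    n = M.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    x = np.zeros(n)
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, n):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def dyn_terms(t, y, parent, jtype, aid, p_off, mass, com, inertia,
              jointdof_int, spl_breaks, spl_coefs, spl_nseg,
              Kv, Dv, q_min, q_max, passive, cp_body, cp_pos, pscal,
              Fpts, Ppts, damp):
    """Mass matrix, generalized forces, contact data and active torques at
    one state.  Fpts/Ppts are (44, 3) output buffers; damp is a (44, 2)
    buffer receiving each point's vertical and horizontal contact-damping
    coefficients (N/(m/s)) for velocity-implicit stepping."""
    n = 27
    q = y[:n]
    qd = y[n:]
    KPD = pscal[IDX_KPD]
    DPD = pscal[IDX_DPD]
    KG = pscal[IDX_KG]
    DG = pscal[IDX_DG]
    mus = pscal[IDX_MUS]
    mud = pscal[IDX_MUD]
    rz0 = pscal[IDX_RZ0]
    v0 = pscal[IDX_V0]
    grav = pscal[IDX_GRAV]

    Es = np.empty((n, 3, 3))
    rs = np.empty((n, 3))
    Rw = np.empty((n, 3, 3))
    pw = np.empty((n, 3))
    v = np.empty((n, 6))
    a = np.empty((n, 6))

    # ---------------- outward kinematics (bias accelerations, qdd = 0) ----
    for i in range(n):
        k = aid[i]
        rx = p_off[i, 0]
        ry = p_off[i, 1]
        rz = p_off[i, 2]
        E = Es[i]
        if jtype[i] == 1:
            c = np.cos(q[i])
            s = np.sin(q[i])
            if k == 0:
                E[0, 0] = 1.0; E[0, 1] = 0.0; E[0, 2] = 0.0
                E[1, 0] = 0.0; E[1, 1] = c;   E[1, 2] = s
                E[2, 0] = 0.0; E[2, 1] = -s;  E[2, 2] = c
            elif k == 1:
                E[0, 0] = c;   E[0, 1] = 0.0; E[0, 2] = -s
                E[1, 0] = 0.0; E[1, 1] = 1.0; E[1, 2] = 0.0
                E[2, 0] = s;   E[2, 1] = 0.0; E[2, 2] = c
            else:
                E[0, 0] = c;   E[0, 1] = s;   E[0, 2] = 0.0
                E[1, 0] = -s;  E[1, 1] = c;   E[1, 2] = 0.0
                E[2, 0] = 0.0; E[2, 1] = 0.0; E[2, 2] = 1.0
        else:
            E[0, 0] = 1.0; E[0, 1] = 0.0; E[0, 2] = 0.0
            E[1, 0] = 0.0; E[1, 1] = 1.0; E[1, 2] = 0.0
            E[2, 0] = 0.0; E[2, 1] = 0.0; E[2, 2] = 1.0
            if k == 0:
                rx += q[i]
            elif k == 1:
                ry += q[i]
            else:
                rz += q[i]
        rs[i, 0] = rx
        rs[i, 1] = ry
        rs[i, 2] = rz

        p = parent[i]
        if p >= 0:
            Rp = Rw[p]
            # Rw[i] = Rp @ E.T
            for r_ in range(3):
                for c_ in range(3):
                    Rw[i, r_, c_] = (Rp[r_, 0] * E[c_, 0] + Rp[r_, 1] * E[c_, 1]
                                     + Rp[r_, 2] * E[c_, 2])
            for r_ in range(3):
                pw[i, r_] = (pw[p, r_] + Rp[r_, 0] * rx + Rp[r_, 1] * ry
                             + Rp[r_, 2] * rz)
            vp0 = v[p, 0]; vp1 = v[p, 1]; vp2 = v[p, 2]
            vp3 = v[p, 3]; vp4 = v[p, 4]; vp5 = v[p, 5]
            ap0 = a[p, 0]; ap1 = a[p, 1]; ap2 = a[p, 2]
            ap3 = a[p, 3]; ap4 = a[p, 4]; ap5 = a[p, 5]
        else:
            for r_ in range(3):
                for c_ in range(3):
                    Rw[i, r_, c_] = E[c_, r_]
            pw[i, 0] = rx
            pw[i, 1] = ry
            pw[i, 2] = rz
            vp0 = vp1 = vp2 = vp3 = vp4 = vp5 = 0.0
            ap0 = ap1 = ap2 = 0.0
            ap3 = 0.0; ap4 = 0.0; ap5 = grav

        # linear parts at the new origin (parent coords)
        tv0 = vp3 + vp1 * rz - vp2 * ry
        tv1 = vp4 + vp2 * rx - vp0 * rz
        tv2 = vp5 + vp0 * ry - vp1 * rx
        ta0 = ap3 + ap1 * rz - ap2 * ry
        ta1 = ap4 + ap2 * rx - ap0 * rz
        ta2 = ap5 + ap0 * ry - ap1 * rx
        # rotate into the new frame
        w0 = E[0, 0] * vp0 + E[0, 1] * vp1 + E[0, 2] * vp2
        w1 = E[1, 0] * vp0 + E[1, 1] * vp1 + E[1, 2] * vp2
        w2 = E[2, 0] * vp0 + E[2, 1] * vp1 + E[2, 2] * vp2
        u0 = E[0, 0] * tv0 + E[0, 1] * tv1 + E[0, 2] * tv2
        u1 = E[1, 0] * tv0 + E[1, 1] * tv1 + E[1, 2] * tv2
        u2 = E[2, 0] * tv0 + E[2, 1] * tv1 + E[2, 2] * tv2
        aw0 = E[0, 0] * ap0 + E[0, 1] * ap1 + E[0, 2] * ap2
        aw1 = E[1, 0] * ap0 + E[1, 1] * ap1 + E[1, 2] * ap2
        aw2 = E[2, 0] * ap0 + E[2, 1] * ap1 + E[2, 2] * ap2
        au0 = E[0, 0] * ta0 + E[0, 1] * ta1 + E[0, 2] * ta2
        au1 = E[1, 0] * ta0 + E[1, 1] * ta1 + E[1, 2] * ta2
        au2 = E[2, 0] * ta0 + E[2, 1] * ta1 + E[2, 2] * ta2

        qdi = qd[i]
        if jtype[i] == 1:
            # v = Xv_p + e_k qd ; a += v x (e_k qd)
            if k == 0:
                w0 += qdi
            elif k == 1:
                w1 += qdi
            else:
                w2 += qdi
            v[i, 0] = w0; v[i, 1] = w1; v[i, 2] = w2
            v[i, 3] = u0; v[i, 4] = u1; v[i, 5] = u2
            # cross(v_ang, qd e_k) and cross(v_lin, qd e_k)
            if k == 0:
                aw1 += w2 * qdi
                aw2 += -w1 * qdi
                au1 += u2 * qdi
                au2 += -u1 * qdi
            elif k == 1:
                aw0 += -w2 * qdi
                aw2 += w0 * qdi
                au0 += -u2 * qdi
                au2 += u0 * qdi
            else:
                aw0 += w1 * qdi
                aw1 += -w0 * qdi
                au0 += u1 * qdi
                au1 += -u0 * qdi
            a[i, 0] = aw0; a[i, 1] = aw1; a[i, 2] = aw2
            a[i, 3] = au0; a[i, 4] = au1; a[i, 5] = au2
        else:
            if k == 0:
                u0 += qdi
            elif k == 1:
                u1 += qdi
            else:
                u2 += qdi
            v[i, 0] = w0; v[i, 1] = w1; v[i, 2] = w2
            v[i, 3] = u0; v[i, 4] = u1; v[i, 5] = u2
            # a += v_ang x (qd e_k) on the linear part
            if k == 0:
                au1 += w2 * qdi
                au2 += -w1 * qdi
            elif k == 1:
                au0 += -w2 * qdi
                au2 += w0 * qdi
            else:
                au0 += w1 * qdi
                au1 += -w0 * qdi
            a[i, 0] = aw0; a[i, 1] = aw1; a[i, 2] = aw2
            a[i, 3] = au0; a[i, 4] = au1; a[i, 5] = au2

    # ---------------- contact forces --------------------------------------
    fext = np.zeros((n, 6))
    ncp = cp_body.shape[0]
    for kk in range(ncp):
        b = cp_body[kk]
        r0 = cp_pos[kk, 0]
        r1 = cp_pos[kk, 1]
        r2 = cp_pos[kk, 2]
        R = Rw[b]
        px = pw[b, 0] + R[0, 0] * r0 + R[0, 1] * r1 + R[0, 2] * r2
        py = pw[b, 1] + R[1, 0] * r0 + R[1, 1] * r1 + R[1, 2] * r2
        pz = pw[b, 2] + R[2, 0] * r0 + R[2, 1] * r1 + R[2, 2] * r2
        Ppts[kk, 0] = px
        Ppts[kk, 1] = py
        Ppts[kk, 2] = pz
        Fpts[kk, 0] = 0.0
        Fpts[kk, 1] = 0.0
        Fpts[kk, 2] = 0.0
        damp[kk, 0] = 0.0
        damp[kk, 1] = 0.0
        d = pz - rz0
        if d < 0.0:
            # body-frame point velocity then world frame
            bv0 = v[b, 3] + v[b, 1] * r2 - v[b, 2] * r1
            bv1 = v[b, 4] + v[b, 2] * r0 - v[b, 0] * r2
            bv2 = v[b, 5] + v[b, 0] * r1 - v[b, 1] * r0
            wv0 = R[0, 0] * bv0 + R[0, 1] * bv1 + R[0, 2] * bv2
            wv1 = R[1, 0] * bv0 + R[1, 1] * bv1 + R[1, 2] * bv2
            wv2 = R[2, 0] * bv0 + R[2, 1] * bv1 + R[2, 2] * bv2
            ramp_d = -d / 0.001
            if ramp_d > 1.0:
                ramp_d = 1.0
            Fz = -KG * d - DG * wv2 * ramp_d
            if Fz > 0.0:
                vh = np.sqrt(wv0 * wv0 + wv1 * wv1)
                mu = mud + (mus - mud) * np.exp(-vh / v0)
                ramp = vh / v0 if vh < v0 else 1.0
                Fh = mu * Fz * ramp
                Fx = 0.0
                Fy = 0.0
                if vh > 1e-12:
                    Fx = -Fh * wv0 / vh
                    Fy = -Fh * wv1 / vh
                Fpts[kk, 0] = Fx
                Fpts[kk, 1] = Fy
                Fpts[kk, 2] = Fz
                damp[kk, 0] = DG * ramp_d
                damp[kk, 1] = mu * Fz / (v0 if vh < v0 else vh)
                fext[b, 3] += Fx
                fext[b, 4] += Fy
                fext[b, 5] += Fz
                ax_ = px - pw[b, 0]
                ay_ = py - pw[b, 1]
                az_ = pz - pw[b, 2]
                fext[b, 0] += ay_ * Fz - az_ * Fy
                fext[b, 1] += az_ * Fx - ax_ * Fz
                fext[b, 2] += ax_ * Fy - ay_ * Fx

    # ---------------- joint torques ---------------------------------------
    tau = np.zeros(n)
    tau_a = np.empty(21)
    for kk in range(21):
        i = jointdof_int[kk]
        qr, qdr = _spline_eval(spl_breaks[kk], spl_coefs[kk], spl_nseg[kk], t)
        ta = KPD * (qr - q[i]) + DPD * (qdr - qd[i])
        aP = passive[i, 0]
        bP = passive[i, 1]
        cP = passive[i, 2]
        tau[i] = ta + aP * (np.exp(bP * (q_min[i] - q[i]))
                            - np.exp(bP * (q[i] - q_max[i]))) - cP * qd[i]
        tau_a[kk] = ta
    for d_ in range(3):
        i = 3 + d_
        tau[i] += -Kv[d_] * q[i] - Dv[d_] * qd[i]

    # ---------------- inward Newton-Euler (bias forces) -------------------
    f = np.zeros((n, 6))
    for i in range(n):
        m = mass[i]
        if m > 0.0:
            c0 = com[i, 0]
            c1 = com[i, 1]
            c2 = com[i, 2]
            Ic = inertia[i]
            w0 = v[i, 0]; w1 = v[i, 1]; w2 = v[i, 2]
            al0 = a[i, 0]; al1 = a[i, 1]; al2 = a[i, 2]
            # vC = vO + w x c ; aC = aO + al x c + w x vC
            vC0 = v[i, 3] + w1 * c2 - w2 * c1
            vC1 = v[i, 4] + w2 * c0 - w0 * c2
            vC2 = v[i, 5] + w0 * c1 - w1 * c0
            aC0 = a[i, 3] + al1 * c2 - al2 * c1 + w1 * vC2 - w2 * vC1
            aC1 = a[i, 4] + al2 * c0 - al0 * c2 + w2 * vC0 - w0 * vC2
            aC2 = a[i, 5] + al0 * c1 - al1 * c0 + w0 * vC1 - w1 * vC0
            F0 = m * aC0
            F1 = m * aC1
            F2 = m * aC2
            # N = Ic al + w x (Ic w)
            h0 = Ic[0, 0] * w0 + Ic[0, 1] * w1 + Ic[0, 2] * w2
            h1 = Ic[1, 0] * w0 + Ic[1, 1] * w1 + Ic[1, 2] * w2
            h2 = Ic[2, 0] * w0 + Ic[2, 1] * w1 + Ic[2, 2] * w2
            N0 = Ic[0, 0] * al0 + Ic[0, 1] * al1 + Ic[0, 2] * al2 + w1 * h2 - w2 * h1
            N1 = Ic[1, 0] * al0 + Ic[1, 1] * al1 + Ic[1, 2] * al2 + w2 * h0 - w0 * h2
            N2 = Ic[2, 0] * al0 + Ic[2, 1] * al1 + Ic[2, 2] * al2 + w0 * h1 - w1 * h0
            f[i, 0] = N0 + c1 * F2 - c2 * F1
            f[i, 1] = N1 + c2 * F0 - c0 * F2
            f[i, 2] = N2 + c0 * F1 - c1 * F0
            f[i, 3] = F0
            f[i, 4] = F1
            f[i, 5] = F2
        # external wrench (world coords about body origin) into body coords
        R = Rw[i]
        e0 = fext[i, 0]; e1 = fext[i, 1]; e2 = fext[i, 2]
        e3 = fext[i, 3]; e4 = fext[i, 4]; e5 = fext[i, 5]
        if e0 != 0.0 or e1 != 0.0 or e2 != 0.0 or e3 != 0.0 or e4 != 0.0 or e5 != 0.0:
            f[i, 0] -= R[0, 0] * e0 + R[1, 0] * e1 + R[2, 0] * e2
            f[i, 1] -= R[0, 1] * e0 + R[1, 1] * e1 + R[2, 1] * e2
            f[i, 2] -= R[0, 2] * e0 + R[1, 2] * e1 + R[2, 2] * e2
            f[i, 3] -= R[0, 0] * e3 + R[1, 0] * e4 + R[2, 0] * e5
            f[i, 4] -= R[0, 1] * e3 + R[1, 1] * e4 + R[2, 1] * e5
            f[i, 5] -= R[0, 2] * e3 + R[1, 2] * e4 + R[2, 2] * e5

    Gam = np.empty(n)
    for i in range(n - 1, -1, -1):
        k = aid[i]
        if jtype[i] == 1:
            Gam[i] = f[i, k]
        else:
            Gam[i] = f[i, 3 + k]
        p = parent[i]
        if p >= 0:
            E = Es[i]
            r0 = rs[i, 0]; r1 = rs[i, 1]; r2 = rs[i, 2]
            # parent coords: F_p = E.T f_lin ; N_p = E.T n + r x F_p
            F0 = E[0, 0] * f[i, 3] + E[1, 0] * f[i, 4] + E[2, 0] * f[i, 5]
            F1 = E[0, 1] * f[i, 3] + E[1, 1] * f[i, 4] + E[2, 1] * f[i, 5]
            F2 = E[0, 2] * f[i, 3] + E[1, 2] * f[i, 4] + E[2, 2] * f[i, 5]
            N0 = E[0, 0] * f[i, 0] + E[1, 0] * f[i, 1] + E[2, 0] * f[i, 2] \
                + r1 * F2 - r2 * F1
            N1 = E[0, 1] * f[i, 0] + E[1, 1] * f[i, 1] + E[2, 1] * f[i, 2] \
                + r2 * F0 - r0 * F2
            N2 = E[0, 2] * f[i, 0] + E[1, 2] * f[i, 1] + E[2, 2] * f[i, 2] \
                + r0 * F1 - r1 * F0
            f[p, 0] += N0
            f[p, 1] += N1
            f[p, 2] += N2
            f[p, 3] += F0
            f[p, 4] += F1
            f[p, 5] += F2

    # ---------------- CRBA mass matrix ------------------------------------
    Icmp = np.zeros((n, 6, 6))
    for i in range(n):
        m = mass[i]
        if m > 0.0:
            c0 = com[i, 0]
            c1 = com[i, 1]
            c2 = com[i, 2]
            Ic = inertia[i]
            # Icmp[:3,:3] = Ic + m*(cx cx^T); cx cx^T = |c|^2 I - c c^T
            cc = c0 * c0 + c1 * c1 + c2 * c2
            for r_ in range(3):
                for c_ in range(3):
                    Icmp[i, r_, c_] = Ic[r_, c_] - m * com[i, r_] * com[i, c_]
                Icmp[i, r_, r_] += m * cc
            # [:3,3:] = m cx ; [3:,:3] = m cx^T ; [3:,3:] = m I
            Icmp[i, 0, 4] = -m * c2
            Icmp[i, 0, 5] = m * c1
            Icmp[i, 1, 3] = m * c2
            Icmp[i, 1, 5] = -m * c0
            Icmp[i, 2, 3] = -m * c1
            Icmp[i, 2, 4] = m * c0
            Icmp[i, 3, 1] = m * c2
            Icmp[i, 3, 2] = -m * c1
            Icmp[i, 4, 0] = -m * c2
            Icmp[i, 4, 2] = m * c0
            Icmp[i, 5, 0] = m * c1
            Icmp[i, 5, 1] = -m * c0
            Icmp[i, 3, 3] = m
            Icmp[i, 4, 4] = m
            Icmp[i, 5, 5] = m

    T6 = np.empty((6, 6))
    X6 = np.empty((6, 6))
    for i in range(n - 1, -1, -1):
        p = parent[i]
        if p < 0:
            continue
        E = Es[i]
        r0 = rs[i, 0]; r1 = rs[i, 1]; r2 = rs[i, 2]
        # X = [[E, 0], [-E rx, E]]
        for r_ in range(3):
            for c_ in range(3):
                X6[r_, c_] = E[r_, c_]
                X6[3 + r_, 3 + c_] = E[r_, c_]
                X6[r_, 3 + c_] = 0.0
        # -E @ skew(r)
        X6[3, 0] = -(E[0, 1] * r2 - E[0, 2] * r1)
        X6[3, 1] = -(E[0, 2] * r0 - E[0, 0] * r2)
        X6[3, 2] = -(E[0, 0] * r1 - E[0, 1] * r0)
        X6[4, 0] = -(E[1, 1] * r2 - E[1, 2] * r1)
        X6[4, 1] = -(E[1, 2] * r0 - E[1, 0] * r2)
        X6[4, 2] = -(E[1, 0] * r1 - E[1, 1] * r0)
        X6[5, 0] = -(E[2, 1] * r2 - E[2, 2] * r1)
        X6[5, 1] = -(E[2, 2] * r0 - E[2, 0] * r2)
        X6[5, 2] = -(E[2, 0] * r1 - E[2, 1] * r0)
        # Icmp[p] += X^T Icmp[i] X
        for r_ in range(6):
            for c_ in range(6):
                s = 0.0
                for kq in range(6):
                    s += Icmp[i, r_, kq] * X6[kq, c_]
                T6[r_, c_] = s
        for r_ in range(6):
            for c_ in range(6):
                s = 0.0
                for kq in range(6):
                    s += X6[kq, r_] * T6[kq, c_]
                Icmp[p, r_, c_] += s

    M = np.zeros((n, n))
    Fv6 = np.empty(6)
    for i in range(n):
        k = aid[i]
        col = k if jtype[i] == 1 else 3 + k
        for r_ in range(6):
            Fv6[r_] = Icmp[i, r_, col]
        M[i, i] = Fv6[col]
        j = i
        while parent[j] >= 0:
            E = Es[j]
            r0 = rs[j, 0]; r1 = rs[j, 1]; r2 = rs[j, 2]
            F0 = E[0, 0] * Fv6[3] + E[1, 0] * Fv6[4] + E[2, 0] * Fv6[5]
            F1 = E[0, 1] * Fv6[3] + E[1, 1] * Fv6[4] + E[2, 1] * Fv6[5]
            F2 = E[0, 2] * Fv6[3] + E[1, 2] * Fv6[4] + E[2, 2] * Fv6[5]
            N0 = E[0, 0] * Fv6[0] + E[1, 0] * Fv6[1] + E[2, 0] * Fv6[2] \
                + r1 * F2 - r2 * F1
            N1 = E[0, 1] * Fv6[0] + E[1, 1] * Fv6[1] + E[2, 1] * Fv6[2] \
                + r2 * F0 - r0 * F2
            N2 = E[0, 2] * Fv6[0] + E[1, 2] * Fv6[1] + E[2, 2] * Fv6[2] \
                + r0 * F1 - r1 * F0
            Fv6[0] = N0
            Fv6[1] = N1
            Fv6[2] = N2
            Fv6[3] = F0
            Fv6[4] = F1
            Fv6[5] = F2
            j = parent[j]
            kj = aid[j]
            Mij = Fv6[kj] if jtype[j] == 1 else Fv6[3 + kj]
            M[i, j] = Mij
            M[j, i] = Mij

    return M, tau, Gam, tau_a, Rw, pw


@njit(cache=True)
def dyn_fast(t, y, parent, jtype, aid, p_off, mass, com, inertia,
             jointdof_int, spl_breaks, spl_coefs, spl_nseg,
             Kv, Dv, q_min, q_max, passive, cp_body, cp_pos, pscal,
             Fpts, Ppts):
    """Generalized accelerations, contact forces and active torques at one
    state.  Fpts/Ppts are caller-provided (44, 3) output buffers."""
    damp = np.empty((cp_body.shape[0], 2))
    M, tau, Gam, tau_a, Rw, pw = dyn_terms(
        t, y, parent, jtype, aid, p_off, mass, com, inertia, jointdof_int,
        spl_breaks, spl_coefs, spl_nseg, Kv, Dv, q_min, q_max, passive,
        cp_body, cp_pos, pscal, Fpts, Ppts, damp)
    qdd = _chol_solve(M, tau - Gam)
    return qdd, tau_a


@njit(cache=True)
def rhs_fast(t, y, parent, jtype, aid, p_off, mass, com, inertia,
             jointdof_int, spl_breaks, spl_coefs, spl_nseg,
             Kv, Dv, q_min, q_max, passive, cp_body, cp_pos, pscal,
             Fpts, Ppts):
    qdd, _ = dyn_fast(t, y, parent, jtype, aid, p_off, mass, com, inertia,
                      jointdof_int, spl_breaks, spl_coefs, spl_nseg,
                      Kv, Dv, q_min, q_max, passive, cp_body, cp_pos, pscal,
                      Fpts, Ppts)
    out = np.empty(54)
    out[:27] = y[27:]
    out[27:] = qdd
    return out


@njit(cache=True)
def semi_implicit_run(y0, t0, dt, nsteps, stride,
                      parent, jtype, aid, p_off, mass, com, inertia,
                      jointdof_int, spl_breaks, spl_coefs, spl_nseg,
                      Kv, Dv, q_min, q_max, passive, cp_body, cp_pos, pscal):
    """Fixed-step velocity-implicit (semi-implicit Euler) integration.

    The contact damping terms -- the stiff part of the dynamics -- are
    treated implicitly through the per-point damping coefficients and point
    Jacobians: solve (M + dt C) dqd = dt (tau - Gamma), qd += dqd,
    q += dt qd.  Everything else is explicit.  Returns (Y, ok) with Y the
    (nsteps // stride + 1, 54) output states.
    """
    n = 27
    ncp = cp_body.shape[0]
    nout = nsteps // stride + 1
    Y = np.empty((nout, 54))
    y = y0.copy()
    Y[0] = y
    Fpts = np.empty((ncp, 3))
    Ppts = np.empty((ncp, 3))
    damp = np.empty((ncp, 2))
    anc = np.empty(27, dtype=np.int64)
    Jc = np.empty((27, 3))
    kout = 1
    for step in range(nsteps):
        t = t0 + step * dt
        M, tau, Gam, tau_a, Rw, pw = dyn_terms(
            t, y, parent, jtype, aid, p_off, mass, com, inertia,
            jointdof_int, spl_breaks, spl_coefs, spl_nseg, Kv, Dv,
            q_min, q_max, passive, cp_body, cp_pos, pscal, Fpts, Ppts, damp)
        A = M.copy()
        for kk in range(ncp):
            dz = damp[kk, 0]
            ch = damp[kk, 1]
            if dz == 0.0 and ch == 0.0:
                continue
            b = cp_body[kk]
            nanc = 0
            j = b
            while j >= 0:
                anc[nanc] = j
                nanc += 1
                j = parent[j]
            for a_ in range(nanc):
                i = anc[a_]
                k = aid[i]
                if jtype[i] == 1:
                    awx = Rw[i, 0, k]
                    awy = Rw[i, 1, k]
                    awz = Rw[i, 2, k]
                    rx = Ppts[kk, 0] - pw[i, 0]
                    ry = Ppts[kk, 1] - pw[i, 1]
                    rz = Ppts[kk, 2] - pw[i, 2]
                    Jc[a_, 0] = awy * rz - awz * ry
                    Jc[a_, 1] = awz * rx - awx * rz
                    Jc[a_, 2] = awx * ry - awy * rx
                else:
                    Jc[a_, 0] = 1.0 if k == 0 else 0.0
                    Jc[a_, 1] = 1.0 if k == 1 else 0.0
                    Jc[a_, 2] = 1.0 if k == 2 else 0.0
            for a_ in range(nanc):
                i = anc[a_]
                for b_ in range(nanc):
                    j2 = anc[b_]
                    A[i, j2] += dt * (dz * Jc[a_, 2] * Jc[b_, 2]
                                      + ch * (Jc[a_, 0] * Jc[b_, 0]
                                              + Jc[a_, 1] * Jc[b_, 1]))
        rhsv = tau - Gam
        dqd = _chol_solve(A, dt * rhsv)
        ok = True
        for i in range(n):
            y[n + i] += dqd[i]
            if not np.isfinite(y[n + i]):
                ok = False
        for i in range(n):
            y[i] += dt * y[n + i]
        if not ok:
            return Y[:kout], False
        if (step + 1) % stride == 0:
            Y[kout] = y
            kout += 1
    return Y, True
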