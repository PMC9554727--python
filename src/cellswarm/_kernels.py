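"""Numba kernels for pairwise force evaluation and time stepping.

Two families of kernels live here: ground-truth dynamics used by the
synthetic population simulator (analytic species forces, RK4), and
learned-model dynamics used by data-driven validation simulations
(library forces with sparse coefficients, forward Euler against
interpolated neighbour data).

Angle convention: theta_ij is the angle between cell i's velocity and the
displacement x_j - x_i.  When the focal speed falls below ``eps_v`` the
directional factors cos(n*theta), n >= 1, are set to zero so that only
isotropic modes act.
"""

import numpy as np
from numba import njit

EPS_V = 1e-12


@njit(cache=True, fastmath=False)
def _angular_factors(vx, vy, dx, dy, r, eps_v):
    """Return (cos(theta), cos(2*theta)) for velocity (vx,vy) and
    displacement (dx,dy) of length r; zeros when the speed is degenerate."""
    s2 = vx * vx + vy * vy
    if s2 <= eps_v * eps_v:
        return 0.0, 0.0
    s = np.sqrt(s2)
    c = (vx * dx + vy * dy) / (s * r)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c, 2.0 * c * c - 1.0


@njit(cache=True)
def truth_accel(X, V, has_ar, has_al, has_dr, ar_p, al_p, dr_p, eps_v, out):
    """Ground-truth accelerations, Eq.-style second-order directional IPS.

    X, V : (N, 2); has_* : (N,) uint8 per-cell force flags;
    ar_p : (N, 5) = (amp0, amp2, decay_fast, decay_slow, ratio);
    al_p : (N, 3) = (amp0, amp1, decay); dr_p : (N, 1) = (coef,).
    Sums run over j != i and are divided by N_tot.  Returns -1 on success,
    or the index of a cell coincident with another (r == 0).
    """
    N = X.shape[0]
    for i in range(N):
        axi = 0.0
        ayi = 0.0
        xi = X[i, 0]
        yi = X[i, 1]
        vxi = V[i, 0]
        vyi = V[i, 1]
        si = np.sqrt(vxi * vxi + vyi * vyi)
        for j in range(N):
            if j == i:
                continue
            dx = X[j, 0] - xi
            dy = X[j, 1] - yi
            r = np.sqrt(dx * dx + dy * dy)
            if r == 0.0:
                return i
            c1, c2 = _angular_factors(vxi, vyi, dx, dy, r, eps_v)
            if has_ar[i] != 0:
                f = (ar_p[i, 0] + ar_p[i, 1] * c2) * (
                    np.exp(-ar_p[i, 2] * r) - ar_p[i, 4] * np.exp(-ar_p[i, 3] * r)
                )
                axi += f * (-dx)
                ayi += f * (-dy)
            if has_al[i] != 0:
                f = -(al_p[i, 0] + al_p[i, 1] * c1) * np.exp(-al_p[i, 2] * r)
                axi += f * (vxi - V[j, 0])
                ayi += f * (vyi - V[j, 1])
            if has_dr[i] != 0:
                f = -dr_p[i, 0] * si
                axi += f * vxi
                ayi += f * vyi
        out[i, 0] = axi / N
        out[i, 1] = ayi / N
    return -1


@njit(cache=True)
def rk4_simulate(X0, V0, has_ar, has_al, has_dr, ar_p, al_p, dr_p,
                 n_coarse, n_sub, h, blowup, eps_v, Xout, Vout):
    """Integrate the ground-truth system with RK4 on substeps of size h.

    Records positions/velocities at the ``n_coarse`` coarse frames
    (frame k corresponds to k * n_sub substeps).  Returns (-1, -1) on
    success, (cell, frame) on coincidence (cell >= 0, frame = step) or
    blow-up (encoded as cell index with frame < -1 never used; we return
    (cell, step) and a status via the first element sign convention
    handled by the caller).
    """
    N = X0.shape[0]
    X = X0.copy()
    V = V0.copy()
    k1x = np.empty((N, 2))
    k1v = np.empty((N, 2))
    k2v = np.empty((N, 2))
    k3v = np.empty((N, 2))
    k4v = np.empty((N, 2))
    Xt = np.empty((N, 2))
    Vt = np.empty((N, 2))
    Xout[0, :, :] = X
    Vout[0, :, :] = V
    for k in range(1, n_coarse):
        for s in range(n_sub):
            step = (k - 1) * n_sub + s
            # k1
            bad = truth_accel(X, V, has_ar, has_al, has_dr, ar_p, al_p, dr_p, eps_v, k1v)
            if bad >= 0:
                return bad, step
            k1x[:] = V
            # k2
            Xt[:] = X + 0.5 * h * k1x
            Vt[:] = V + 0.5 * h * k1v
            bad = truth_accel(Xt, Vt, has_ar, has_al, has_dr, ar_p, al_p, dr_p, eps_v, k2v)
            if bad >= 0:
                return bad, step
            k2x = Vt.copy()
            # k3
            Xt[:] = X + 0.5 * h * k2x
            Vt[:] = V + 0.5 * h * k2v
            bad = truth_accel(Xt, Vt, has_ar, has_al, has_dr, ar_p, al_p, dr_p, eps_v, k3v)
            if bad >= 0:
                return bad, step
            k3x = Vt.copy()
            # k4
            Xt[:] = X + h * k3x
            Vt[:] = V + h * k3v
            bad = truth_accel(Xt, Vt, has_ar, has_al, has_dr, ar_p, al_p, dr_p, eps_v, k4v)
            if bad >= 0:
                return bad, step
            k4x = Vt.copy()
            X += (h / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            V += (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            for i in range(N):
                if (np.abs(X[i, 0]) > blowup or np.abs(X[i, 1]) > blowup
                        or not np.isfinite(X[i, 0]) or not np.isfinite(X[i, 1])):
                    return i, step
        Xout[k, :, :] = X
        Vout[k, :, :] = V
    return -1, -1


@njit(cache=True)
def model_accel(x, y, vx, vy, Xn, Vn, skip,
                ar_n, ar_l, ar_w, al_n, al_l, al_w, dr_n, dr_l, dr_w,
                alpha, n_tot, eps_v):
    """Acceleration of one focal cell at (x, y, vx, vy) under a sparse
    library model, with neighbour states Xn, Vn (N, 2); row ``skip`` is
    excluded (the focal cell's slot in the data).

    Library blocks: attraction-repulsion cos(n th) p_l(alpha r) e^{-alpha r/2}
    times (x_i - x_j); alignment (1 + cos(n th)) e^{-2 l r} times (v_i - v_j);
    drag (1 + cos(n th)) |v|^l times v_i.  All sums divided by n_tot.
    """
    n_ar = ar_w.shape[0]
    n_al = al_w.shape[0]
    n_dr = dr_w.shape[0]
    lag_max = 0
    for t in range(n_ar):
        if ar_l[t] > lag_max:
            lag_max = ar_l[t]
    lag = np.empty(lag_max + 1)
    # speed powers for drag (exponents 0..4)
    s = np.sqrt(vx * vx + vy * vy)
    sp = np.empty(5)
    sp[0] = 1.0
    for q in range(1, 5):
        sp[q] = sp[q - 1] * s
    ax = 0.0
    ay = 0.0
    N = Xn.shape[0]
    for j in range(N):
        if j == skip:
            continue
        dx = Xn[j, 0] - x
        dy = Xn[j, 1] - y
        r = np.sqrt(dx * dx + dy * dy)
        if r == 0.0:
            continue
        c1, c2 = _angular_factors(vx, vy, dx, dy, r, eps_v)
        t2 = np.exp(-2.0 * r)
        if n_ar > 0:
            xx = alpha * r
            lag[0] = 1.0
            if lag_max >= 1:
                lag[1] = 1.0 - xx
                for q in range(1, lag_max):
                    lag[q + 1] = ((2.0 * q + 1.0 - xx) * lag[q] - q * lag[q - 1]) / (q + 1.0)
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            for t in range(n_ar):
                v = ar_w[t] * lag[ar_l[t]]
                if ar_n[t] == 0:
                    s0 += v
                elif ar_n[t] == 1:
                    s1 += v
                else:
                    s2 += v
            # e^{-(alpha/2) r} with alpha = 36 equals t2**9; for general
            # alpha fall back to exp.
            if alpha == 36.0:
                e = t2 ** 9
            else:
                e = np.exp(-0.5 * alpha * r)
            f = (s0 + s1 * c1 + s2 * c2) * e
            ax += f * (-dx)
            ay += f * (-dy)
        if n_al > 0:
            f = 0.0
            for t in range(n_al):
                ell = al_l[t]
                if t2 > 0.0:
                    ew = t2 ** ell
                elif ell > 0:
                    ew = 0.0
                else:
                    # exp(-2r) underflowed; growing terms overflow to inf
                    # and the caller scores the simulation as divergent
                    ew = np.exp(-2.0 * ell * r)
                if al_n[t] == 0:
                    fac = 2.0
                elif al_n[t] == 1:
                    fac = 1.0 + c1
                else:
                    fac = 1.0 + c2
                f += al_w[t] * fac * ew
            ax += f * (vx - Vn[j, 0])
            ay += f * (vy - Vn[j, 1])
        if n_dr > 0:
            f = 0.0
            for t in range(n_dr):
                if dr_n[t] == 0:
                    fac = 2.0
                else:
                    fac = 1.0 + c1
                f += dr_w[t] * fac * sp[dr_l[t]]
            ax += f * vx
            ay += f * vy
    return ax / n_tot, ay / n_tot


@njit(cache=True)
def simulate_cell(x0, y0, vx0, vy0, Xf, Vf, skip,
                  ar_n, ar_l, ar_w, al_n, al_l, al_w, dr_n, dr_l, dr_w,
                  alpha, n_tot, h, n_sub, n_frames, v_data, num_cap, eps_v,
                  xbar, vbar):
    """Data-driven forward Euler simulation of a single cell.

    Xf, Vf : (n_fine, N, 2) neighbour positions/velocities tabulated on the
    fine grid (step h = dt / n_sub); the trajectory of slot ``skip`` is
    ignored.  Records the focal state at the ``n_frames`` coarse frames in
    xbar, vbar and accumulates the squared velocity mismatch against
    v_data (n_frames, 2).  Stops early once the accumulated mismatch
    exceeds ``num_cap`` (pass inf to disable).

    Returns (numerator, status): status 0 = completed, 1 = early exit on
    num_cap, 2 = non-finite state (blow-up).
    """
    x = x0
    y = y0
    vx = vx0
    vy = vy0
    num = 0.0
    for k in range(n_frames):
        xbar[k, 0] = x
        xbar[k, 1] = y
        vbar[k, 0] = vx
        vbar[k, 1] = vy
        dvx = vx - v_data[k, 0]
        dvy = vy - v_data[k, 1]
        num += dvx * dvx + dvy * dvy
        if num > num_cap:
            return num, 1
        if k == n_frames - 1:
            break
        for ss in range(n_sub):
            g = k * n_sub + ss
            axx, ayy = model_accel(x, y, vx, vy, Xf[g], Vf[g], skip,
                                   ar_n, ar_l, ar_w, al_n, al_l, al_w,
                                   dr_n, dr_l, dr_w, alpha, n_tot, eps_v)
            # positions advance with the pre-update velocity
            x += h * vx
            y += h * vy
            vx += h * axx
            vy += h * ayy
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(vx) and np.isfinite(vy)):
            return num, 2
    return num, 0
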