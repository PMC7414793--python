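"""Fused per-pixel Levenberg-Marquardt kernel (numba).

Numerically equivalent to the batched numpy engine in
:mod:`flimglia.fitting` for the standard three-parameter fit
(a1, tau1, tau2 with the amplitude profiled out); the numpy path remains
the reference implementation and handles the optional offset/shift
parameters.  The kernel walks each pixel's 256-channel histogram in
cache with multiplicative recurrences for the exponentials
(``e^{-t_{n+1}/tau} = e^{-t_n/tau} * e^{-dt/tau}``), which is what makes
whole-experiment fitting fast on one core.

Compilation is cached on disk (``cache=True``), so only the first call
in a fresh environment pays the JIT cost.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a hard speedup, soft dep
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def _eval_model(y, w, a1, t1, t2, kj, dt, inc0, c_out):
    """Fill c_out with the unit-amplitude shape; return (chi2, A).

    c_out receives the convolved two-component shape; the least-squares
    amplitude A is profiled out against (y, w) over channels >= inc0.
    """
    T = y.shape[0]
    nz = kj.shape[0]
    # prefix sums of kj * exp(+t_j/tau) for both components
    C1 = np.empty(nz)
    C2 = np.empty(nz)
    u1 = np.exp(dt / t1)
    u2 = np.exp(dt / t2)
    e1 = 1.0
    e2 = 1.0
    acc1 = 0.0
    acc2 = 0.0
    for j in range(nz):
        acc1 += kj[j] * e1
        acc2 += kj[j] * e2
        C1[j] = acc1
        C2[j] = acc2
        e1 *= u1
        e2 *= u2
    r1 = 1.0 / u1
    r2 = 1.0 / u2
    d1 = 1.0
    d2 = 1.0
    s_wyc = 0.0
    s_wcc = 0.0
    for n in range(T):
        j = n if n < nz else nz - 1
        c = a1 * d1 * C1[j] + (1.0 - a1) * d2 * C2[j]
        c_out[n] = c
        if n >= inc0:
            s_wyc += w[n] * y[n] * c
            s_wcc += w[n] * c * c
        d1 *= r1
        d2 *= r2
    if s_wcc < 1e-300:
        s_wcc = 1e-300
    A = s_wyc / s_wcc
    if A < 0.0:
        A = 0.0
    chi2 = 0.0
    for n in range(inc0, T):
        r = y[n] - A * c_out[n]
        chi2 += w[n] * r * r
    return chi2, A


@njit(cache=True, fastmath=True)
def _lm_pixel(y, w, p, kj, dt, inc0, lb, ub, tol, max_iter, scratch):
    """LM refinement of one pixel from p (in place); returns
    (chi2, converged, n_iter).  scratch is a (10, T) workspace."""
    T = y.shape[0]
    nz = kj.shape[0]
    c1 = scratch[0]
    c2 = scratch[1]
    g1 = scratch[2]  # d conv1 / d tau1
    g2 = scratch[3]
    cc = scratch[4]
    ct = scratch[5]  # trial shape
    C1 = np.empty(nz)
    C2 = np.empty(nz)
    Q1 = np.empty(nz)
    Q2 = np.empty(nz)
    JtJ = np.empty((3, 3))
    grad = np.empty(3)
    delta = np.empty(3)
    ptr = np.empty(3)

    chi2, _ = _eval_model(y, w, p[0], p[1], p[2], kj, dt, inc0, cc)
    lam = 1e-3
    converged = False
    n_iter = 0
    for _ in range(max_iter):
        a1, t1, t2 = p[0], p[1], p[2]
        # component convolutions + tau-derivatives via prefix sums
        u1 = np.exp(dt / t1)
        u2 = np.exp(dt / t2)
        e1 = 1.0
        e2 = 1.0
        a_c1 = 0.0
        a_c2 = 0.0
        a_q1 = 0.0
        a_q2 = 0.0
        for j in range(nz):
            tj = j * dt
            a_c1 += kj[j] * e1
            a_c2 += kj[j] * e2
            a_q1 += kj[j] * tj * e1
            a_q2 += kj[j] * tj * e2
            C1[j] = a_c1
            C2[j] = a_c2
            Q1[j] = a_q1
            Q2[j] = a_q2
            e1 *= u1
            e2 *= u2
        r1 = 1.0 / u1
        r2 = 1.0 / u2
        d1 = 1.0
        d2 = 1.0
        den = 0.0
        num = 0.0
        for n in range(T):
            j = n if n < nz else nz - 1
            tn = n * dt
            v1 = d1 * C1[j]
            v2 = d2 * C2[j]
            c1[n] = v1
            c2[n] = v2
            g1[n] = (tn * v1 - d1 * Q1[j]) / (t1 * t1)
            g2[n] = (tn * v2 - d2 * Q2[j]) / (t2 * t2)
            c = a1 * v1 + (1.0 - a1) * v2
            cc[n] = c
            if n >= inc0:
                num += w[n] * y[n] * c
                den += w[n] * c * c
            d1 *= r1
            d2 *= r2
        if den < 1e-300:
            den = 1e-300
        A = num / den
        if A < 0.0:
            A = 0.0
        # accumulate the VarPro-exact normal equations
        u_a = 0.0
        v_a = 0.0
        u_1 = 0.0
        v_1 = 0.0
        u_2 = 0.0
        v_2 = 0.0
        for n in range(inc0, T):
            S_a = c1[n] - c2[n]
            S_1 = a1 * g1[n]
            S_2 = (1.0 - a1) * g2[n]
            wy = w[n] * y[n]
            wc = w[n] * cc[n]
            u_a += wy * S_a
            v_a += wc * S_a
            u_1 += wy * S_1
            v_1 += wc * S_1
            u_2 += wy * S_2
            v_2 += wc * S_2
        dA_a = (u_a - 2.0 * A * v_a) / den
        dA_1 = (u_1 - 2.0 * A * v_1) / den
        dA_2 = (u_2 - 2.0 * A * v_2) / den
        jtj00 = 0.0
        jtj01 = 0.0
        jtj02 = 0.0
        jtj11 = 0.0
        jtj12 = 0.0
        jtj22 = 0.0
        g_0 = 0.0
        g_1v = 0.0
        g_2v = 0.0
        for n in range(inc0, T):
            c = cc[n]
            J0 = A * (c1[n] - c2[n]) + dA_a * c
            J1 = A * a1 * g1[n] + dA_1 * c
            J2 = A * (1.0 - a1) * g2[n] + dA_2 * c
            wn = w[n]
            rn = y[n] - A * c
            jtj00 += wn * J0 * J0
            jtj01 += wn * J0 * J1
            jtj02 += wn * J0 * J2
            jtj11 += wn * J1 * J1
            jtj12 += wn * J1 * J2
            jtj22 += wn * J2 * J2
            g_0 += wn * J0 * rn
            g_1v += wn * J1 * rn
            g_2v += wn * J2 * rn
        JtJ[0, 0] = jtj00 + lam * max(jtj00, 1e-30)
        JtJ[0, 1] = jtj01
        JtJ[0, 2] = jtj02
        JtJ[1, 0] = jtj01
        JtJ[1, 1] = jtj11 + lam * max(jtj11, 1e-30)
        JtJ[1, 2] = jtj12
        JtJ[2, 0] = jtj02
        JtJ[2, 1] = jtj12
        JtJ[2, 2] = jtj22 + lam * max(jtj22, 1e-30)
        grad[0] = g_0
        grad[1] = g_1v
        grad[2] = g_2v
        # 3x3 solve by Gaussian elimination with partial pivoting
        ok = _solve3(JtJ, grad, delta)
        if not ok:
            lam *= 6.0
            n_iter += 1
            if lam > 1e9:
                break
            continue
        for k in range(3):
            v = p[k] + delta[k]
            if v < lb[k]:
                v = lb[k]
            if v > ub[k]:
                v = ub[k]
            ptr[k] = v
        chi2_t, _ = _eval_model(y, w, ptr[0], ptr[1], ptr[2], kj, dt, inc0, ct)
        rel_gain = (chi2 - chi2_t) / max(chi2, 1e-30)
        max_step = 0.0
        for k in range(3):
            s = abs(ptr[k] - p[k]) / (abs(p[k]) + 1e-3)
            if s > max_step:
                max_step = s
        improved = chi2_t < chi2
        n_iter += 1
        if improved:
            for k in range(3):
                p[k] = ptr[k]
            chi2 = chi2_t
            lam = max(lam * 0.25, 1e-10)
            if max_step < tol or abs(rel_gain) < 1e-7:
                converged = True
                break
        else:
            lam *= 6.0
            if lam > 1e9:
                if abs(rel_gain) < 1e-8:
                    converged = True
                break
    return chi2, converged, n_iter


@njit(cache=True, fastmath=True)
def _solve3(M, b, x):
    """In-place 3x3 linear solve; returns False when singular."""
    n = 3
    for col in range(n):
        piv = col
        best = abs(M[col, col])
        for r in range(col + 1, n):
            if abs(M[r, col]) > best:
                best = abs(M[r, col])
                piv = r
        if best < 1e-300:
            return False
        if piv != col:
            for k in range(n):
                M[col, k], M[piv, k] = M[piv, k], M[col, k]
            b[col], b[piv] = b[piv], b[col]
        inv = 1.0 / M[col, col]
        for r in range(col + 1, n):
            f = M[r, col] * inv
            for k in range(col, n):
                M[r, k] -= f * M[col, k]
            b[r] -= f * b[col]
    for r in range(n - 1, -1, -1):
        s = b[r]
        for k in range(r + 1, n):
            s -= M[r, k] * x[k]
        x[r] = s / M[r, r]
    return True


@njit(cache=True, fastmath=True)
def fit_batch(
    y_all,
    p0,
    kj,
    dt,
    inc0,
    lb,
    ub,
    tol,
    max_iter,
    two_pass,
    uniform,
    combos,
):
    """Two-pass LM fit of an (N, T) batch; returns parameter/qc arrays.

    ``two_pass`` selects the model-frozen reweighting; ``uniform`` selects
    unweighted least squares (otherwise Neyman weights).  ``combos`` is the
    coarse grid used as a multi-start fallback on non-convergence, ordered
    a1-ascending so ties resolve to the lowest a1.
    """
    N, T = y_all.shape
    params = np.empty((N, 3))
    chi2_out = np.empty(N)
    conv_out = np.zeros(N, dtype=np.bool_)
    iter_out = np.zeros(N, dtype=np.int32)
    amp_out = np.empty(N)
    scratch = np.empty((10, T))
    w = np.empty(T)
    p = np.empty(3)
    pg = np.empty(3)
    n_combo = combos.shape[0]
    for i in range(N):
        y = y_all[i]
        for n in range(T):
            if uniform:
                w[n] = 1.0
            else:
                w[n] = 1.0 / max(y[n], 1.0)
        for k in range(3):
            p[k] = p0[i, k]
        cap = min(max_iter, 8) if two_pass else max_iter
        chi2, convd, it = _lm_pixel(y, w, p, kj, dt, inc0, lb, ub, tol, cap, scratch)
        if two_pass:
            cc = scratch[4]
            chi2, A = _eval_model(y, w, p[0], p[1], p[2], kj, dt, inc0, cc)
            for n in range(T):
                w[n] = 1.0 / max(A * cc[n], 1.0)
            chi2, convd, it2 = _lm_pixel(
                y, w, p, kj, dt, inc0, lb, ub, tol, max_iter, scratch
            )
            it += it2
        if not convd:
            # coarse-grid multi-start fallback
            best_chi2 = 1e300
            bi = 0
            ct = scratch[5]
            for ci in range(n_combo):
                c2v, _ = _eval_model(
                    y, w, combos[ci, 0], combos[ci, 1], combos[ci, 2],
                    kj, dt, inc0, ct,
                )
                if c2v < best_chi2:
                    best_chi2 = c2v
                    bi = ci
            for k in range(3):
                v = combos[bi, k]
                if v < lb[k]:
                    v = lb[k]
                if v > ub[k]:
                    v = ub[k]
                pg[k] = v
            chi2_g, conv_g, it_g = _lm_pixel(
                y, w, pg, kj, dt, inc0, lb, ub, tol, max_iter, scratch
            )
            it += it_g
            if chi2_g < chi2 or conv_g:
                chi2 = chi2_g
                for k in range(3):
                    p[k] = pg[k]
                convd = conv_g or convd
        # final amplitude and reported (Neyman or uniform) chi2
        cc = scratch[4]
        _, A = _eval_model(y, w, p[0], p[1], p[2], kj, dt, inc0, cc)
        chi2_rep = 0.0
        for n in range(inc0, T):
            r = y[n] - A * cc[n]
            wn = 1.0 if uniform else 1.0 / max(y[n], 1.0)
            chi2_rep += wn * r * r
        for k in range(3):
            params[i, k] = p[k]
        chi2_out[i] = chi2_rep
        conv_out[i] = convd
        iter_out[i] = it
        amp_out[i] = A
    return params, chi2_out, conv_out, iter_out, amp_out
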