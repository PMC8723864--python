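"""Numba-compiled right-hand sides and fixed-step integrators.

Parameters arrive packed in a flat float64 array in the order of
:data:`pbcsync.params.PARAM_ORDER`.  All loops are classical RK4; the
delay-coupled pair uses a ring history buffer with cubic Hermite
interpolation for delayed voltage lookups (method of steps).  Node
derivatives are stored from the final RK4 stage, whose O(dt^3) slope
error keeps the interpolant at the integrator's own order.
"""

import numpy as np
from numba import njit

# indices into the packed parameter array (PARAM_ORDER)
_CM, _GNA, _GK, _GL, _GNAP, _GCAN = 0, 1, 2, 3, 4, 5
_VNA, _VK, _VL, _VM, _VN, _VP, _VH = 6, 7, 8, 9, 10, 11, 12
_SM, _SN, _SH, _SMP = 13, 14, 15, 16
_TAUN, _TAUH = 17, 18
_NCAN, _KCAN = 19, 20
_EPS, _D, _CAC, _LC = 21, 22, 23, 24

OK = 0
DIVERGED = 1


@njit(cache=True)
def _vdot(V, n, h, Ca, I_ext, P):
    """Somatic voltage derivative: all membrane currents plus I_ext lumped."""
    m = 1.0 / (1.0 + np.exp((V - P[_VM]) / P[_SM]))
    mp = 1.0 / (1.0 + np.exp((V - P[_VP]) / P[_SMP]))
    fca = 1.0 / (1.0 + (P[_KCAN] / Ca) ** P[_NCAN])
    I_Na = P[_GNA] * m * m * m * (1.0 - n) * (V - P[_VNA])
    I_NaP = P[_GNAP] * mp * h * (V - P[_VNA])
    I_CAN = P[_GCAN] * fca * (V - P[_VNA])
    I_K = P[_GK] * n ** 4 * (V - P[_VK])
    I_L = P[_GL] * (V - P[_VL])
    return (-I_Na - I_NaP - I_CAN - I_K - I_L - I_ext) / P[_CM]


@njit(cache=True)
def _gates(V, P):
    """(dn-coefficients) n_inf, tau_n, h_inf, tau_h at voltage V."""
    n_inf = 1.0 / (1.0 + np.exp((V - P[_VN]) / P[_SN]))
    h_inf = 1.0 / (1.0 + np.exp((V - P[_VH]) / P[_SH]))
    tau_n = P[_TAUN] / np.cosh((V - P[_VN]) / (2.0 * P[_SN]))
    tau_h = P[_TAUH] / np.cosh((V - P[_VH]) / (2.0 * P[_SH]))
    return n_inf, tau_n, h_inf, tau_h


@njit(cache=True)
def rhs5(y, I_exc, P, out):
    V, n, h, Ca, l = y[0], y[1], y[2], y[3], y[4]
    n_inf, tau_n, h_inf, tau_h = _gates(V, P)
    out[0] = _vdot(V, n, h, Ca, I_exc, P)
    out[1] = (n_inf - n) / tau_n
    out[2] = (h_inf - h) / tau_h
    out[3] = -P[_EPS] * P[_D] * (l - P[_LC])
    out[4] = P[_EPS] / P[_D] * (Ca - P[_CAC])


@njit(cache=True)
def rhs3(y, I_exc, Ca, P, out):
    """Somatic subsystem with calcium held fixed (equilibrium analysis)."""
    V, n, h = y[0], y[1], y[2]
    n_inf, tau_n, h_inf, tau_h = _gates(V, P)
    out[0] = _vdot(V, n, h, Ca, I_exc, P)
    out[1] = (n_inf - n) / tau_n
    out[2] = (h_inf - h) / tau_h


@njit(cache=True)
def rhs8(y, Vd21, Vd12, g_c, I1, I2, P, out):
    """Coupled pair sharing one calcium subsystem.

    ``Vd21`` is V2 at t - tau1 (seen by neuron 1), ``Vd12`` is V1 at
    t - tau2 (seen by neuron 2).
    """
    Ca, l = y[6], y[7]
    for k in range(2):
        V, n, h = y[3 * k], y[3 * k + 1], y[3 * k + 2]
        Vd = Vd21 if k == 0 else Vd12
        I_exc = I1 if k == 0 else I2
        I_c = g_c * (Vd - V)
        n_inf, tau_n, h_inf, tau_h = _gates(V, P)
        out[3 * k] = _vdot(V, n, h, Ca, I_exc + I_c, P)
        out[3 * k + 1] = (n_inf - n) / tau_n
        out[3 * k + 2] = (h_inf - h) / tau_h
    out[6] = -P[_EPS] * P[_D] * (l - P[_LC])
    out[7] = P[_EPS] / P[_D] * (Ca - P[_CAC])


@njit(cache=True)
def integrate5(y0, I_exc, P, dt, n_steps, sample_every):
    """RK4 on the 5-D single neuron; returns (samples, status, fail_step)."""
    y = y0.copy()
    n_samp = n_steps // sample_every + 1
    out = np.empty((n_samp, 5))
    out[0] = y
    k1 = np.empty(5); k2 = np.empty(5); k3 = np.empty(5); k4 = np.empty(5)
    tmp = np.empty(5)
    idx = 1
    for step in range(n_steps):
        rhs5(y, I_exc, P, k1)
        for i in range(5):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        rhs5(tmp, I_exc, P, k2)
        for i in range(5):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        rhs5(tmp, I_exc, P, k3)
        for i in range(5):
            tmp[i] = y[i] + dt * k3[i]
        rhs5(tmp, I_exc, P, k4)
        for i in range(5):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % sample_every == 0:
            if not np.isfinite(y[0]):
                return out[:idx], DIVERGED, step + 1
            out[idx] = y
            idx += 1
    return out, OK, -1


@njit(cache=True)
def integrate8_nodelay(y0, g_c, I1, I2, P, dt, n_steps, sample_every):
    """RK4 on the 8-D coupled pair with zero delays (instantaneous coupling)."""
    y = y0.copy()
    n_samp = n_steps // sample_every + 1
    out = np.empty((n_samp, 8))
    out[0] = y
    k1 = np.empty(8); k2 = np.empty(8); k3 = np.empty(8); k4 = np.empty(8)
    tmp = np.empty(8)
    idx = 1
    for step in range(n_steps):
        rhs8(y, y[3], y[0], g_c, I1, I2, P, k1)
        for i in range(8):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        rhs8(tmp, tmp[3], tmp[0], g_c, I1, I2, P, k2)
        for i in range(8):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        rhs8(tmp, tmp[3], tmp[0], g_c, I1, I2, P, k3)
        for i in range(8):
            tmp[i] = y[i] + dt * k3[i]
        rhs8(tmp, tmp[3], tmp[0], g_c, I1, I2, P, k4)
        for i in range(8):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % sample_every == 0:
            if not np.isfinite(y[0]) or not np.isfinite(y[3]):
                return out[:idx], DIVERGED, step + 1
            out[idx] = y
            idx += 1
    return out, OK, -1


@njit(cache=True)
def _hermite(s, dt, k_cur, hV, hd, V0, L):
    """Cubic Hermite lookup of a history ring at time ``s``.

    Nodes 0..k_cur are stored (ring of length L).  Pre-zero times resolve
    to the constant initial history V0.  Times inside the current step
    (possible only for delays shorter than dt) extrapolate the last
    completed interval.
    """
    if s <= 0.0:
        return V0
    j = int(np.floor(s / dt))
    if j > k_cur - 1:
        j = k_cur - 1
    theta = s / dt - j
    jj = j % L
    j1 = (j + 1) % L
    t2 = theta * theta
    t3 = t2 * theta
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + theta
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    return (h00 * hV[jj] + h10 * dt * hd[jj]
            + h01 * hV[j1] + h11 * dt * hd[j1])


@njit(cache=True)
def integrate8_dde(y0, g_c, tau1, tau2, I1, I2, P, dt, n_steps, sample_every,
                   hV1, hV2, hd1, hd2):
    """Method-of-steps RK4 on the delay-coupled pair.

    ``hV1, hV2, hd1, hd2`` are pre-allocated ring buffers (length L >=
    max(tau)/dt + 4) that carry the voltage history; they are initialized
    here to the constant initial history and updated in place, so the
    caller can reuse or inspect them (the Benettin driver does both).
    Returns (samples, status, fail_step).
    """
    L = hV1.shape[0]
    y = y0.copy()
    V10, V20 = y0[0], y0[3]
    hV1[:] = V10
    hV2[:] = V20
    hd1[:] = 0.0
    hd2[:] = 0.0
    k1 = np.empty(8); k2 = np.empty(8); k3 = np.empty(8); k4 = np.empty(8)
    tmp = np.empty(8)
    # true derivative at node 0
    rhs8(y, _hermite(-tau1, dt, 0, hV2, hd2, V20, L),
         _hermite(-tau2, dt, 0, hV1, hd1, V10, L), g_c, I1, I2, P, k1)
    hd1[0] = k1[0]
    hd2[0] = k1[3]
    n_samp = n_steps // sample_every + 1
    out = np.empty((n_samp, 8))
    out[0] = y
    idx = 1
    for step in range(n_steps):
        t = step * dt
        # stage 1
        vd21 = y[3] if tau1 == 0.0 else _hermite(t - tau1, dt, step, hV2, hd2, V20, L)
        vd12 = y[0] if tau2 == 0.0 else _hermite(t - tau2, dt, step, hV1, hd1, V10, L)
        rhs8(y, vd21, vd12, g_c, I1, I2, P, k1)
        # stage 2
        for i in range(8):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        th = t + 0.5 * dt
        vd21 = tmp[3] if tau1 == 0.0 else _hermite(th - tau1, dt, step, hV2, hd2, V20, L)
        vd12 = tmp[0] if tau2 == 0.0 else _hermite(th - tau2, dt, step, hV1, hd1, V10, L)
        rhs8(tmp, vd21, vd12, g_c, I1, I2, P, k2)
        # stage 3
        for i in range(8):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        vd21 = tmp[3] if tau1 == 0.0 else _hermite(th - tau1, dt, step, hV2, hd2, V20, L)
        vd12 = tmp[0] if tau2 == 0.0 else _hermite(th - tau2, dt, step, hV1, hd1, V10, L)
        rhs8(tmp, vd21, vd12, g_c, I1, I2, P, k3)
        # stage 4
        for i in range(8):
            tmp[i] = y[i] + dt * k3[i]
        te = t + dt
        vd21 = tmp[3] if tau1 == 0.0 else _hermite(te - tau1, dt, step, hV2, hd2, V20, L)
        vd12 = tmp[0] if tau2 == 0.0 else _hermite(te - tau2, dt, step, hV1, hd1, V10, L)
        rhs8(tmp, vd21, vd12, g_c, I1, I2, P, k4)
        for i in range(8):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        node = (step + 1) % L
        hV1[node] = y[0]
        hV2[node] = y[3]
        hd1[node] = k4[0]
        hd2[node] = k4[3]
        if (step + 1) % sample_every == 0:
            if not np.isfinite(y[0]) or not np.isfinite(y[3]):
                return out[:idx], DIVERGED, step + 1
            out[idx] = y
            idx += 1
    return out, OK, -1


@njit(cache=True)
def _rk4_step3(y, I_exc, Ca, P, dt, k1, k2, k3, k4, tmp):
    rhs3(y, I_exc, Ca, P, k1)
    for i in range(3):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    rhs3(tmp, I_exc, Ca, P, k2)
    for i in range(3):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    rhs3(tmp, I_exc, Ca, P, k3)
    for i in range(3):
        tmp[i] = y[i] + dt * k3[i]
    rhs3(tmp, I_exc, Ca, P, k4)
    for i in range(3):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def _rk4_step5(y, I_exc, P, dt, k1, k2, k3, k4, tmp):
    rhs5(y, I_exc, P, k1)
    for i in range(5):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    rhs5(tmp, I_exc, P, k2)
    for i in range(5):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    rhs5(tmp, I_exc, P, k3)
    for i in range(5):
        tmp[i] = y[i] + dt * k3[i]
    rhs5(tmp, I_exc, P, k4)
    for i in range(5):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def benettin_ode(y0, I_exc, Ca_fixed, ndim, P, dt, renorm_steps, n_renorms,
                 d0, discard, perturb_index=0):
    """Benettin two-trajectory maximal-Lyapunov estimate on the single neuron.

    ``ndim`` = 3 (somatic, calcium fixed at ``Ca_fixed``) or 5 (full).
    The perturbation d0 is applied to V.  Returns the running-estimate
    series over renormalizations (1/ms); the caller averages the
    post-discard tail.
    """
    yr = y0[:ndim].copy()
    yp = y0[:ndim].copy()
    yp[perturb_index] += d0
    k1 = np.empty(ndim); k2 = np.empty(ndim); k3 = np.empty(ndim)
    k4 = np.empty(ndim); tmp = np.empty(ndim)
    logs = np.empty(n_renorms)
    T = renorm_steps * dt
    for r in range(n_renorms):
        for _ in range(renorm_steps):
            if ndim == 3:
                _rk4_step3(yr, I_exc, Ca_fixed, P, dt, k1, k2, k3, k4, tmp)
                _rk4_step3(yp, I_exc, Ca_fixed, P, dt, k1, k2, k3, k4, tmp)
            else:
                _rk4_step5(yr, I_exc, P, dt, k1, k2, k3, k4, tmp)
                _rk4_step5(yp, I_exc, P, dt, k1, k2, k3, k4, tmp)
        d2 = 0.0
        for i in range(ndim):
            d2 += (yp[i] - yr[i]) ** 2
        dist = np.sqrt(d2)
        if dist == 0.0 or not np.isfinite(dist):
            logs[r] = np.nan
            continue
        logs[r] = np.log(dist / d0) / T
        a = d0 / dist
        for i in range(ndim):
            yp[i] = yr[i] + a * (yp[i] - yr[i])
    # running mean of post-discard tail
    series = np.empty(n_renorms)
    acc = 0.0
    cnt = 0
    for r in range(n_renorms):
        if r >= discard and np.isfinite(logs[r]):
            acc += logs[r]
            cnt += 1
        series[r] = acc / cnt if cnt > 0 else np.nan
    return series


@njit(cache=True)
def benettin_dde(y0, g_c, tau1, tau2, I1, I2, P, dt, renorm_steps, n_renorms,
                 d0, discard, L):
    """Benettin estimate for the delay-coupled pair.

    The perturbed trajectory starts with its V1 history (and state)
    uniformly shifted by d0; the separation norm runs over the 8-D state
    plus both voltage history rings, and renormalization rescales state
    and history together so the perturbation stays a valid DDE initial
    segment.
    """
    yr = y0.copy()
    yp = y0.copy()
    yp[0] += d0
    hV1r = np.full(L, yr[0]); hV2r = np.full(L, yr[3])
    hd1r = np.zeros(L); hd2r = np.zeros(L)
    hV1p = np.full(L, yp[0]); hV2p = np.full(L, yp[3])
    hd1p = np.zeros(L); hd2p = np.zeros(L)
    V10r, V20r = yr[0], yr[3]
    V10p, V20p = yp[0], yp[3]
    k1 = np.empty(8); k2 = np.empty(8); k3 = np.empty(8); k4 = np.empty(8)
    tmp = np.empty(8)
    logs = np.empty(n_renorms)
    T = renorm_steps * dt
    step = 0
    for r in range(n_renorms):
        for _ in range(renorm_steps):
            t = step * dt
            for w in range(2):
                if w == 0:
                    y, hV1, hV2, hd1, hd2, V10, V20 = yr, hV1r, hV2r, hd1r, hd2r, V10r, V20r
                else:
                    y, hV1, hV2, hd1, hd2, V10, V20 = yp, hV1p, hV2p, hd1p, hd2p, V10p, V20p
                vd21 = y[3] if tau1 == 0.0 else _hermite(t - tau1, dt, step, hV2, hd2, V20, L)
                vd12 = y[0] if tau2 == 0.0 else _hermite(t - tau2, dt, step, hV1, hd1, V10, L)
                rhs8(y, vd21, vd12, g_c, I1, I2, P, k1)
                for i in range(8):
                    tmp[i] = y[i] + 0.5 * dt * k1[i]
                th = t + 0.5 * dt
                vd21 = tmp[3] if tau1 == 0.0 else _hermite(th - tau1, dt, step, hV2, hd2, V20, L)
                vd12 = tmp[0] if tau2 == 0.0 else _hermite(th - tau2, dt, step, hV1, hd1, V10, L)
                rhs8(tmp, vd21, vd12, g_c, I1, I2, P, k2)
                for i in range(8):
                    tmp[i] = y[i] + 0.5 * dt * k2[i]
                vd21 = tmp[3] if tau1 == 0.0 else _hermite(th - tau1, dt, step, hV2, hd2, V20, L)
                vd12 = tmp[0] if tau2 == 0.0 else _hermite(th - tau2, dt, step, hV1, hd1, V10, L)
                rhs8(tmp, vd21, vd12, g_c, I1, I2, P, k3)
                for i in range(8):
                    tmp[i] = y[i] + dt * k3[i]
                te = t + dt
                vd21 = tmp[3] if tau1 == 0.0 else _hermite(te - tau1, dt, step, hV2, hd2, V20, L)
                vd12 = tmp[0] if tau2 == 0.0 else _hermite(te - tau2, dt, step, hV1, hd1, V10, L)
                rhs8(tmp, vd21, vd12, g_c, I1, I2, P, k4)
                for i in range(8):
                    y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                node = (step + 1) % L
                hV1[node] = y[0]
                hV2[node] = y[3]
                hd1[node] = k4[0]
                hd2[node] = k4[3]
            step += 1
        d2 = 0.0
        for i in range(8):
            d2 += (yp[i] - yr[i]) ** 2
        for i in range(L):
            d2 += (hV1p[i] - hV1r[i]) ** 2 + (hV2p[i] - hV2r[i]) ** 2
        dist = np.sqrt(d2)
        if dist == 0.0 or not np.isfinite(dist):
            logs[r] = np.nan
            continue
        logs[r] = np.log(dist / d0) / T
        a = d0 / dist
        for i in range(8):
            yp[i] = yr[i] + a * (yp[i] - yr[i])
        for i in range(L):
            hV1p[i] = hV1r[i] + a * (hV1p[i] - hV1r[i])
            hV2p[i] = hV2r[i] + a * (hV2p[i] - hV2r[i])
            hd1p[i] = hd1r[i] + a * (hd1p[i] - hd1r[i])
            hd2p[i] = hd2r[i] + a * (hd2p[i] - hd2r[i])
    series = np.empty(n_renorms)
    acc = 0.0
    cnt = 0
    for r in range(n_renorms):
        if r >= discard and np.isfinite(logs[r]):
            acc += logs[r]
            cnt += 1
        series[r] = acc / cnt if cnt > 0 else np.nan
    return series
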