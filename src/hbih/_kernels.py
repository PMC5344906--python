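"""Compiled inner loops: RK4 integration and two-trajectory Lyapunov runs.

The vector field here must stay numerically identical to
:func:`hbih.model.derivatives`; a unit test pins the two against each
other at machine precision.  Parameters travel as a flat float64 vector so
the loops stay allocation-free.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import ModelParameters, temperature_factors

# layout of the packed parameter vector
(_C_M, _G_D, _G_R, _G_SD, _G_SR, _G_L, _G_H,
 _V0_D, _V0_R, _V0_SD, _V0_H,
 _S_D, _S_R, _S_SD, _S_H,
 _TAU_R, _TAU_SD, _TAU_SR, _TAU_H,
 _E_D, _E_R, _E_SD, _E_SR, _E_L, _E_H,
 _KAPPA, _ETA, _K_SR, _RHO, _PHI, _SLOW) = range(31)

NPARAMS = 31

# integration status codes
STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_CROSSING_OVERFLOW = 2


def pack_params(params: ModelParameters, slow_only: bool = False) -> np.ndarray:
    """Flatten a parameter set (plus precomputed rho/phi) for the kernels."""
    p = params.slow() if slow_only else params
    rho, phi = temperature_factors(p.T)
    pv = np.empty(NPARAMS)
    pv[_C_M] = p.C_m
    pv[_G_D] = p.g_d
    pv[_G_R] = p.g_r
    pv[_G_SD] = p.g_sd
    pv[_G_SR] = p.g_sr
    pv[_G_L] = p.g_l
    pv[_G_H] = p.g_h
    pv[_V0_D] = p.V0_d
    pv[_V0_R] = p.V0_r
    pv[_V0_SD] = p.V0_sd
    pv[_V0_H] = p.V0_h
    pv[_S_D] = p.s_d
    pv[_S_R] = p.s_r
    pv[_S_SD] = p.s_sd
    pv[_S_H] = p.s_h
    pv[_TAU_R] = p.tau_r
    pv[_TAU_SD] = p.tau_sd
    pv[_TAU_SR] = p.tau_sr
    pv[_TAU_H] = p.tau_h
    pv[_E_D] = p.E_d
    pv[_E_R] = p.E_r
    pv[_E_SD] = p.E_sd
    pv[_E_SR] = p.E_sr
    pv[_E_L] = p.E_l
    pv[_E_H] = p.E_h
    pv[_KAPPA] = p.kappa
    pv[_ETA] = p.eta
    pv[_K_SR] = p.K_sr
    pv[_RHO] = rho
    pv[_PHI] = phi
    pv[_SLOW] = 1.0 if slow_only else 0.0
    return pv


@njit(cache=True, fastmath=True, inline="always")
def _rhs(V, ar, asd, asr, ah, pv):
    rho = pv[_RHO]
    phi = pv[_PHI]
    ad = 1.0 / (1.0 + np.exp(-pv[_S_D] * (V - pv[_V0_D])))
    I_d = rho * pv[_G_D] * ad * (V - pv[_E_D])
    I_r = rho * pv[_G_R] * ar * (V - pv[_E_R])
    I_sd = rho * pv[_G_SD] * asd * (V - pv[_E_SD])
    a2 = asr * asr
    I_sr = rho * pv[_G_SR] * (a2 / (a2 + pv[_K_SR])) * (V - pv[_E_SR])
    I_h = rho * pv[_G_H] * ah * (V - pv[_E_H])
    I_l = rho * pv[_G_L] * (V - pv[_E_L])
    dV = -(I_d + I_r + I_sd + I_sr + I_h + I_l) / pv[_C_M]
    if pv[_SLOW] != 0.0:
        dar = 0.0
    else:
        arinf = 1.0 / (1.0 + np.exp(-pv[_S_R] * (V - pv[_V0_R])))
        dar = phi * (arinf - ar) / pv[_TAU_R]
    asdinf = 1.0 / (1.0 + np.exp(-pv[_S_SD] * (V - pv[_V0_SD])))
    dasd = phi * (asdinf - asd) / pv[_TAU_SD]
    dasr = phi * (-pv[_ETA] * I_sd - pv[_KAPPA] * asr) / pv[_TAU_SR]
    ahinf = 1.0 / (1.0 + np.exp(-pv[_S_H] * (V - pv[_V0_H])))
    dah = phi * (ahinf - ah) / pv[_TAU_H]
    return dV, dar, dasd, dasr, dah


@njit(cache=True)
def rhs_vector(y, pv):
    """Single right-hand-side evaluation (used to pin against the
    reference implementation in :mod:`hbih.model`)."""
    dV, dar, dasd, dasr, dah = _rhs(y[0], y[1], y[2], y[3], y[4], pv)
    out = np.empty(5)
    out[0] = dV
    out[1] = dar
    out[2] = dasd
    out[3] = dasr
    out[4] = dah
    return out


@njit(cache=True, fastmath=True, inline="always")
def _rk4_step(V, ar, asd, asr, ah, pv, dt):
    k1V, k1r, k1sd, k1sr, k1h = _rhs(V, ar, asd, asr, ah, pv)
    h2 = 0.5 * dt
    k2V, k2r, k2sd, k2sr, k2h = _rhs(
        V + h2 * k1V, ar + h2 * k1r, asd + h2 * k1sd, asr + h2 * k1sr, ah + h2 * k1h, pv
    )
    k3V, k3r, k3sd, k3sr, k3h = _rhs(
        V + h2 * k2V, ar + h2 * k2r, asd + h2 * k2sd, asr + h2 * k2sr, ah + h2 * k2h, pv
    )
    k4V, k4r, k4sd, k4sr, k4h = _rhs(
        V + dt * k3V, ar + dt * k3r, asd + dt * k3sd, asr + dt * k3sr, ah + dt * k3h, pv
    )
    c = dt / 6.0
    return (
        V + c * (k1V + 2.0 * k2V + 2.0 * k3V + k4V),
        ar + c * (k1r + 2.0 * k2r + 2.0 * k3r + k4r),
        asd + c * (k1sd + 2.0 * k2sd + 2.0 * k3sd + k4sd),
        asr + c * (k1sr + 2.0 * k2sr + 2.0 * k3sr + k4sr),
        ah + c * (k1h + 2.0 * k2h + 2.0 * k3h + k4h),
    )


@njit(cache=True, fastmath=True)
def rk4_run(y0, pv, dt, n_equil, n_steps, stride, threshold, rec_t, rec_y, cross_t):
    """Integrate, recording every ``stride``-th state and every upward
    crossing of ``threshold`` (linearly interpolated, full resolution).

    Recorded times are absolute: the equilibration segment occupies
    [0, n_equil*dt) and is integrated but not recorded.

    Returns ``(n_recorded, n_crossings, status, t_fail)``.
    """
    V = y0[0]
    ar = y0[1]
    asd = y0[2]
    asr = y0[3]
    ah = y0[4]
    for i in range(n_equil):
        V, ar, asd, asr, ah = _rk4_step(V, ar, asd, asr, ah, pv, dt)
        if not (-1.0e6 < V < 1.0e6):
            return 0, 0, STATUS_NONFINITE, (i + 1) * dt
    t0 = n_equil * dt
    nrec = 0
    if rec_t.shape[0] > 0:
        rec_t[0] = t0
        rec_y[0, 0] = V
        rec_y[0, 1] = ar
        rec_y[0, 2] = asd
        rec_y[0, 3] = asr
        rec_y[0, 4] = ah
        nrec = 1
    ncross = 0
    status = STATUS_OK
    for i in range(n_steps):
        Vp = V
        V, ar, asd, asr, ah = _rk4_step(V, ar, asd, asr, ah, pv, dt)
        if not (-1.0e6 < V < 1.0e6):
            return nrec, ncross, STATUS_NONFINITE, t0 + (i + 1) * dt
        if Vp < threshold and V >= threshold:
            if ncross < cross_t.shape[0]:
                frac = (threshold - Vp) / (V - Vp)
                cross_t[ncross] = t0 + (i + frac) * dt
                ncross += 1
            else:
                status = STATUS_CROSSING_OVERFLOW
        if (i + 1) % stride == 0 and nrec < rec_t.shape[0]:
            rec_t[nrec] = t0 + (i + 1) * dt
            rec_y[nrec, 0] = V
            rec_y[nrec, 1] = ar
            rec_y[nrec, 2] = asd
            rec_y[nrec, 3] = asr
            rec_y[nrec, 4] = ah
            nrec += 1
    return nrec, ncross, status, 0.0


@njit(cache=True)
def lz_production_steps(s):
    """Kaspar-Schuster production-step count c(n) of a symbol array.

    The first symbol is always inserted; a candidate word is extended
    while it can be copied from anywhere in the already-seen sequence
    (overlap allowed); each failure inserts a new vocabulary word; a
    candidate still pending at the end counts as one final step.
    """
    n = s.shape[0]
    c = 1
    l = 1
    i = 0
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


@njit(cache=True, fastmath=True)
def mle_run(y0, pv, dt, n_equil, n_intervals, steps_per_interval, d0, direction,
            scale, logs, seps):
    """Two-trajectory (Benettin-style) maximal-Lyapunov-exponent run.

    A companion trajectory starts displaced by ``d0`` along ``direction``
    (a unit vector in the per-variable ``scale`` metric).  After each
    renormalization interval the log distance ratio is accumulated into
    ``logs`` and the companion is pulled back to distance ``d0`` along the
    current separation vector.  ``seps`` receives the pre-renormalization
    scaled distances (for attractor-size saturation diagnostics).

    Returns a status code.
    """
    V = y0[0]
    ar = y0[1]
    asd = y0[2]
    asr = y0[3]
    ah = y0[4]
    for i in range(n_equil):
        V, ar, asd, asr, ah = _rk4_step(V, ar, asd, asr, ah, pv, dt)
        if not (-1.0e6 < V < 1.0e6):
            return STATUS_NONFINITE
    V2 = V + d0 * direction[0] * scale[0]
    ar2 = ar + d0 * direction[1] * scale[1]
    asd2 = asd + d0 * direction[2] * scale[2]
    asr2 = asr + d0 * direction[3] * scale[3]
    ah2 = ah + d0 * direction[4] * scale[4]
    for k in range(n_intervals):
        for i in range(steps_per_interval):
            V, ar, asd, asr, ah = _rk4_step(V, ar, asd, asr, ah, pv, dt)
            V2, ar2, asd2, asr2, ah2 = _rk4_step(V2, ar2, asd2, asr2, ah2, pv, dt)
        if not (-1.0e6 < V < 1.0e6) or not (-1.0e6 < V2 < 1.0e6):
            return STATUS_NONFINITE
        e0 = (V2 - V) / scale[0]
        e1 = (ar2 - ar) / scale[1]
        e2 = (asd2 - asd) / scale[2]
        e3 = (asr2 - asr) / scale[3]
        e4 = (ah2 - ah) / scale[4]
        d = np.sqrt(e0 * e0 + e1 * e1 + e2 * e2 + e3 * e3 + e4 * e4)
        seps[k] = d
        if d <= 0.0:
            # identical trajectories: log ratio is -inf in theory; record a
            # strongly contracting placeholder and re-seed the offset
            logs[k] = -36.0
            V2 = V + d0 * direction[0] * scale[0]
            ar2 = ar + d0 * direction[1] * scale[1]
            asd2 = asd + d0 * direction[2] * scale[2]
            asr2 = asr + d0 * direction[3] * scale[3]
            ah2 = ah + d0 * direction[4] * scale[4]
            continue
        logs[k] = np.log(d / d0)
        f = d0 / d
        V2 = V + (V2 - V) * f
        ar2 = ar + (ar2 - ar) * f
        asd2 = asd + (asd2 - asd) * f
        asr2 = asr + (asr2 - asr) * f
        ah2 = ah + (ah2 - ah) * f
    return STATUS_OK
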