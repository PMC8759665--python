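"""Numba-compiled core: gate kinetics, HCO vector fields, adaptive integrator.

Unit convention (asserted in the test suite): time in seconds, voltage in mV,
conductance in nS, current in pA, capacitance in nF, so that pA/nF = mV/s.

State vector layout (full model, 16 variables):
    [V1, hNaF1, mNaS1, hNaS1, mK1, mCaS1, hCaS1, mSyn1,
     V2, hNaF2, mNaS2, hNaS2, mK2, mCaS2, hCaS2, mSyn2]

Reduced (constant-hCaS) model, 14 variables: same per-neuron block with the
hCaS slot removed; hCaS1/hCaS2 enter as parameters.

Parameter array layout:
    [gNaF, gNaS, gK, gCaS, gleak, gSyn, ENa, EK, ECa, Eleak, ESyn, C]
"""

import math

import numpy as np
from numba import njit

NVAR_FULL = 16
NVAR_REDUCED = 14


# ---------------------------------------------------------------------------
# Gate kinetics.  Each voltage-dependent gate x relaxes as
# x' = (x_inf(V) - x) / tau_x(V); the fast-sodium activation is instantaneous.
# ---------------------------------------------------------------------------

@njit(cache=True, error_model="numpy")
def minf_naf(V):
    return 1.0 / (1.0 + math.exp((V + 20.0) / -7.8))


@njit(cache=True, error_model="numpy")
def inf_hnaf(V):
    return 1.0 / (1.0 + math.exp((V + 23.0) / 7.0))


@njit(cache=True, error_model="numpy")
def tau_hnaf(V):
    return 0.03 / (math.exp((V + 40.0) / 15.0) + math.exp((V + 40.0) / -16.0))


@njit(cache=True, error_model="numpy")
def inf_mnas(V):
    return 1.0 / (1.0 + math.exp((V + 42.0) / -4.1))


@njit(cache=True, error_model="numpy")
def inf_hnas(V):
    return 1.0 / (1.0 + math.exp((V + 55.0) / 5.0))


@njit(cache=True, error_model="numpy")
def inf_mk(V):
    return 1.0 / (1.0 + math.exp((V + 21.0) / -15.0))


@njit(cache=True, error_model="numpy")
def tau_mk(V):
    return 0.007 / (math.exp((V + 46.0) / 40.0) + math.exp((V + 46.0) / -50.0))


@njit(cache=True, error_model="numpy")
def inf_mcas(V):
    return 1.0 / (1.0 + math.exp((V + 45.59) / -4.27))


@njit(cache=True, error_model="numpy")
def _xoverexpm1(x, k):
    # x / (1 - exp(-x/k)) with the removable singularity at x = 0 -> k
    if abs(x) < 1e-9:
        return k
    return x / (-math.expm1(-x / k))


@njit(cache=True, error_model="numpy")
def tau_mcas(V):
    # Bell-shaped tau = c / (sum of two rational terms), the same
    # flattened-fraction form as the other voltage-dependent taus.  Each
    # term is positive for all V, with removable singularities at V = -48
    # and V = -51 handled analytically (x/(1-exp(-x/k)) -> k as x -> 0).
    return 0.001 / (0.02 * _xoverexpm1(V + 48.0, 4.5)
                    + 0.05 * _xoverexpm1(-(V + 51.0), 4.5))


@njit(cache=True, error_model="numpy")
def inf_hcas(V):
    # very steep (0.75 mV) inactivation curve: hCaS deinactivates only at
    # the deep hyperpolarizations of the slow rhythm's silent phase, which
    # is what lets the fast rhythm coexist with hCaS nearly inactivated
    return 1.0 / (1.0 + math.exp((V + 58.93) / 0.75))


@njit(cache=True, error_model="numpy")
def inf_msyn(Vpre):
    return 1.0 / (1.0 + math.exp(Vpre / -0.4))


TAU_MNAS = 0.001
TAU_HNAS = 0.1
TAU_HCAS = 0.485
TAU_MSYN = 0.009


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------

@njit(cache=True, error_model="numpy")
def rhs_full(y, p, gE, EE, dy):
    """Full 16-variable HCO derivative; pulse conductance gE is constant
    within an integration segment (square pulse handled by segmentation)."""
    for i in range(2):
        o = 8 * i
        V = y[o]
        hNaF = y[o + 1]
        mNaS = y[o + 2]
        hNaS = y[o + 3]
        mK = y[o + 4]
        mCaS = y[o + 5]
        hCaS = y[o + 6]
        mSyn = y[o + 7]
        msyn_pre = y[8 * (1 - i) + 7]

        m = minf_naf(V)
        mk2 = mK * mK
        itot = (p[0] * m * m * m * hNaF * (V - p[6])
                + p[1] * mNaS * hNaS * (V - p[6])
                + p[2] * mk2 * mk2 * (V - p[7])
                + p[3] * mCaS * mCaS * mCaS * hCaS * (V - p[8])
                + p[4] * (V - p[9])
                + p[5] * msyn_pre * (V - p[10])
                + gE * (V - EE))
        dy[o] = -itot / p[11]
        dy[o + 1] = (inf_hnaf(V) - hNaF) / tau_hnaf(V)
        dy[o + 2] = (inf_mnas(V) - mNaS) / TAU_MNAS
        dy[o + 3] = (inf_hnas(V) - hNaS) / TAU_HNAS
        dy[o + 4] = (inf_mk(V) - mK) / tau_mk(V)
        dy[o + 5] = (inf_mcas(V) - mCaS) / tau_mcas(V)
        dy[o + 6] = (inf_hcas(V) - hCaS) / TAU_HCAS
        dy[o + 7] = (inf_msyn(V) - mSyn) / TAU_MSYN


@njit(cache=True, error_model="numpy")
def rhs_reduced(y, p, gE, EE, h1, h2, dy):
    """14-variable constant-hCaS HCO: hCaS equations removed, levels are
    parameters, so solver error control sees the true reduced dimension."""
    for i in range(2):
        o = 7 * i
        V = y[o]
        hNaF = y[o + 1]
        mNaS = y[o + 2]
        hNaS = y[o + 3]
        mK = y[o + 4]
        mCaS = y[o + 5]
        mSyn = y[o + 6]
        msyn_pre = y[7 * (1 - i) + 6]
        hCaS = h1 if i == 0 else h2

        m = minf_naf(V)
        mk2 = mK * mK
        itot = (p[0] * m * m * m * hNaF * (V - p[6])
                + p[1] * mNaS * hNaS * (V - p[6])
                + p[2] * mk2 * mk2 * (V - p[7])
                + p[3] * mCaS * mCaS * mCaS * hCaS * (V - p[8])
                + p[4] * (V - p[9])
                + p[5] * msyn_pre * (V - p[10])
                + gE * (V - EE))
        dy[o] = -itot / p[11]
        dy[o + 1] = (inf_hnaf(V) - hNaF) / tau_hnaf(V)
        dy[o + 2] = (inf_mnas(V) - mNaS) / TAU_MNAS
        dy[o + 3] = (inf_hnas(V) - hNaS) / TAU_HNAS
        dy[o + 4] = (inf_mk(V) - mK) / tau_mk(V)
        dy[o + 5] = (inf_mcas(V) - mCaS) / tau_mcas(V)
        dy[o + 6] = (inf_msyn(V) - mSyn) / TAU_MSYN


@njit(cache=True, error_model="numpy")
def _rhs(y, p, gE, EE, mode, h1, h2, dy):
    if mode == 0:
        rhs_full(y, p, gE, EE, dy)
    else:
        rhs_reduced(y, p, gE, EE, h1, h2, dy)


# ---------------------------------------------------------------------------
# Dormand-Prince 5(4) adaptive integrator with FSAL and cubic-Hermite
# dense output on a uniform sampling grid.
# ---------------------------------------------------------------------------

@njit(cache=True, error_model="numpy")
def integrate_segment(y0, t0, t1, p, gE, EE, rtol, atol, max_step, dt_out,
                      mode, h1, h2):
    """Integrate from t0 to t1 with constant pulse conductance gE.

    Returns (ts, ys, yfinal, ok).  If dt_out > 0, ts/ys hold samples on the
    grid t0 + k*dt_out (k >= 1) that fall in (t0, t1]; yfinal is the exact
    state at t1.  If dt_out <= 0 no dense output is stored (ts/ys empty).
    """
    n = y0.shape[0]
    y = y0.copy()
    t = t0

    f = np.empty(n)
    _rhs(y, p, gE, EE, mode, h1, h2, f)

    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)

    if dt_out > 0.0:
        nout = int(math.floor((t1 - t0) / dt_out + 1e-9))
        ts = np.empty(nout)
        ys = np.empty((nout, n))
    else:
        nout = 0
        ts = np.empty(0)
        ys = np.empty((0, n))
    iout = 0

    h = min(1e-6, t1 - t0)
    if max_step > 0.0:
        h = min(h, max_step)
    ok = True

    while t < t1 - 1e-13:
        if t + h > t1:
            h = t1 - t

        # stage 2
        for j in range(n):
            ytmp[j] = y[j] + h * 0.2 * f[j]
        _rhs(ytmp, p, gE, EE, mode, h1, h2, k2)
        # stage 3
        for j in range(n):
            ytmp[j] = y[j] + h * (3.0 / 40.0 * f[j] + 9.0 / 40.0 * k2[j])
        _rhs(ytmp, p, gE, EE, mode, h1, h2, k3)
        # stage 4
        for j in range(n):
            ytmp[j] = y[j] + h * (44.0 / 45.0 * f[j] - 56.0 / 15.0 * k2[j]
                                  + 32.0 / 9.0 * k3[j])
        _rhs(ytmp, p, gE, EE, mode, h1, h2, k4)
        # stage 5
        for j in range(n):
            ytmp[j] = y[j] + h * (19372.0 / 6561.0 * f[j]
                                  - 25360.0 / 2187.0 * k2[j]
                                  + 64448.0 / 6561.0 * k3[j]
                                  - 212.0 / 729.0 * k4[j])
        _rhs(ytmp, p, gE, EE, mode, h1, h2, k5)
        # stage 6
        for j in range(n):
            ytmp[j] = y[j] + h * (9017.0 / 3168.0 * f[j]
                                  - 355.0 / 33.0 * k2[j]
                                  + 46732.0 / 5247.0 * k3[j]
                                  + 49.0 / 176.0 * k4[j]
                                  - 5103.0 / 18656.0 * k5[j])
        _rhs(ytmp, p, gE, EE, mode, h1, h2, k6)
        # 5th-order solution
        for j in range(n):
            ynew[j] = y[j] + h * (35.0 / 384.0 * f[j]
                                  + 500.0 / 1113.0 * k3[j]
                                  + 125.0 / 192.0 * k4[j]
                                  - 2187.0 / 6784.0 * k5[j]
                                  + 11.0 / 84.0 * k6[j])
        _rhs(ynew, p, gE, EE, mode, h1, h2, k7)

        # embedded error estimate
        errnorm = 0.0
        for j in range(n):
            e = h * (71.0 / 57600.0 * f[j]
                     - 71.0 / 16695.0 * k3[j]
                     + 71.0 / 1920.0 * k4[j]
                     - 17253.0 / 339200.0 * k5[j]
                     + 22.0 / 525.0 * k6[j]
                     - 1.0 / 40.0 * k7[j])
            sc = atol + rtol * max(abs(y[j]), abs(ynew[j]))
            q = e / sc
            errnorm += q * q
        errnorm = math.sqrt(errnorm / n)
        if not math.isfinite(errnorm):
            errnorm = 1e6  # wild trial step: reject and shrink

        if errnorm <= 1.0:
            tnew = t + h
            # dense output by cubic Hermite on the accepted step
            if dt_out > 0.0:
                while iout < nout:
                    s = t0 + (iout + 1) * dt_out
                    if s > tnew + 1e-13:
                        break
                    th = (s - t) / h
                    th2 = th * th
                    a = th2 * (3.0 - 2.0 * th)
                    b = h * th * (th - 1.0) * (th - 1.0)
                    c = h * th2 * (th - 1.0)
                    for j in range(n):
                        ys[iout, j] = (y[j] + a * (ynew[j] - y[j])
                                       + b * f[j] + c * k7[j])
                    ts[iout] = s
                    iout += 1
            t = tnew
            for j in range(n):
                y[j] = ynew[j]
                f[j] = k7[j]  # FSAL
            if not np.isfinite(y[0]) or not np.isfinite(y[8 if mode == 0 else 7]):
                ok = False
                break
            fac = 0.9 * errnorm ** -0.2 if errnorm > 1e-10 else 5.0
        else:
            fac = max(0.2, 0.9 * errnorm ** -0.2)
        fac = min(5.0, max(0.2, fac))
        h *= fac
        if max_step > 0.0 and h > max_step:
            h = max_step
        if h < 1e-14:
            ok = False
            break

    return ts[:iout], ys[:iout], y, ok
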