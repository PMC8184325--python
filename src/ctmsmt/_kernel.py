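"""Numerical core: gating-rate functions and the fixed-step forward-Euler loop.

Everything in this module works on plain floats / ndarrays so that it can be
JIT-compiled with numba when available; the public, validated API lives in
:mod:`ctmsmt.hh`.  Internal units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# Half-width of the window around each removable 0/0 point inside which the
# analytic limit is substituted (mV).
SINGULARITY_EPS = 1e-6


@njit(cache=False)
def rates(V, V_T, tau_max):
    """All voltage-dependent channel kinetics at membrane potential ``V``.

    Returns (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n, p_inf, tau_p)
    with rates in 1/ms, tau_p in ms.  The three removable singularities
    (alpha_m, beta_m, alpha_n) are replaced by their analytic limits within
    ``SINGULARITY_EPS`` of the singular voltage.
    """
    x = V - V_T - 13.0
    if abs(x) < SINGULARITY_EPS:
        alpha_m = 0.32 * 4.0
    else:
        alpha_m = -0.32 * x / (np.exp(-x / 4.0) - 1.0)

    x = V - V_T - 40.0
    if abs(x) < SINGULARITY_EPS:
        beta_m = 0.28 * 5.0
    else:
        beta_m = 0.28 * x / (np.exp(x / 5.0) - 1.0)

    alpha_h = 0.128 * np.exp(-(V - V_T - 17.0) / 18.0)
    beta_h = 4.0 / (1.0 + np.exp(-(V - V_T - 40.0) / 5.0))

    x = V - V_T - 15.0
    if abs(x) < SINGULARITY_EPS:
        alpha_n = 0.032 * 5.0
    else:
        alpha_n = -0.032 * x / (np.exp(-x / 5.0) - 1.0)

    beta_n = 0.5 * np.exp(-(V - V_T - 10.0) / 40.0)

    p_inf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0))
    # exp overflow at extreme voltages underflows tau_p to 0; keep it positive
    # so the relaxation toward p_inf stays defined while blowup is detected on V
    if not tau_p > 1e-12:
        tau_p = 1e-12

    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n, p_inf, tau_p


@njit(cache=False)
def ionic_current(V, m, h, n, p, g_leak, gbar_Na, gbar_K, gbar_M, E_leak, E_Na, E_K):
    """Total ionic current density J_leak + J_Na + J_K + J_M (uA/cm^2)."""
    J_leak = g_leak * (V - E_leak)
    J_Na = gbar_Na * m ** 3 * h * (V - E_Na)
    J_K = gbar_K * n ** 4 * (V - E_K)
    J_M = gbar_M * p * (V - E_K)
    return J_leak + J_Na + J_K + J_M


@njit(cache=False)
def euler(
    stim,
    dt,
    n_steps,
    V0,
    m0,
    h0,
    n0,
    p0,
    C_m,
    g_leak,
    gbar_Na,
    gbar_K,
    gbar_M,
    E_leak,
    E_Na,
    E_K,
    V_T,
    tau_max,
):
    """Fixed-step forward-Euler integration of the membrane equations.

    ``stim`` holds the stimulus current density on the dt grid with the
    depolarizing-positive public sign convention; the membrane equation
    subtracts the stimulus term, so the sign is flipped here — in exactly
    this one place.

    Gates are clamped to [0, 1] after every step.  Returns the voltage trace
    (length ``n_steps + 1``), the four gate traces, and the index of the
    first non-finite step (-1 if the integration stayed finite).
    """
    V_tr = np.empty(n_steps + 1)
    m_tr = np.empty(n_steps + 1)
    h_tr = np.empty(n_steps + 1)
    n_tr = np.empty(n_steps + 1)
    p_tr = np.empty(n_steps + 1)

    V = V0
    m = m0
    h = h0
    n = n0
    p = p0
    V_tr[0] = V
    m_tr[0] = m
    h_tr[0] = h
    n_tr[0] = n
    p_tr[0] = p

    n_stim = stim.shape[0]
    blowup = -1

    for k in range(n_steps):
        J_stim = -stim[k] if k < n_stim else 0.0

        am, bm, ah, bh, an, bn, p_inf, tau_p = rates(V, V_T, tau_max)
        J_ion = ionic_current(
            V, m, h, n, p, g_leak, gbar_Na, gbar_K, gbar_M, E_leak, E_Na, E_K
        )
        dV = (-J_ion - J_stim) / C_m

        m = m + dt * (am * (1.0 - m) - bm * m)
        h = h + dt * (ah * (1.0 - h) - bh * h)
        n = n + dt * (an * (1.0 - n) - bn * n)
        p = p + dt * (p_inf - p) / tau_p
        # forward Euler can overshoot the unit interval during the AP upstroke
        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0

        V = V + dt * dV

        V_tr[k + 1] = V
        m_tr[k + 1] = m
        h_tr[k + 1] = h
        n_tr[k + 1] = n
        p_tr[k + 1] = p

        if not np.isfinite(V):
            blowup = k
            break

    return V_tr, m_tr, h_tr, n_tr, p_tr, blowup
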