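"""Conductance-based point-neuron model of a cortical cell under TMS drive.

The membrane carries four currents — transient sodium, delayed-rectifier
potassium, slow non-inactivating potassium (M-current) and leak — plus the
stimulus current density induced by the magnetic pulse:

    C_m dV/dt = -J_leak - J_Na - J_K - J_M - J_stim

with J_leak = g_leak (V - E_leak), J_Na = gbar_Na m^3 h (V - E_Na),
J_K = gbar_K n^4 (V - E_K) and J_M = gbar_M p (V - E_K).  The gates m, h, n
follow first-order alpha/beta kinetics; the M-current gate p relaxes toward
p_inf(V) with time constant tau_p(V).

Units are mV, ms, uA/cm^2, mS/cm^2 and uF/cm^2 internally; the simulation
step is expressed in microseconds at the interface and converted once.

The public stimulus convention is depolarizing-positive: a positive waveform
sample drives the membrane toward threshold.  The sign flip demanded by the
minus sign in the membrane equation happens in one place, inside the Euler
kernel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import brentq

from . import _kernel
from .errors import ConvergenceError, InvalidInputError, NumericalBlowupError

if TYPE_CHECKING:  # pragma: no cover
    from .pulses import StimulusWaveform

__all__ = [
    "HHParameters",
    "MembraneState",
    "RateSet",
    "SimulationConfig",
    "VoltageTrace",
    "compute_rates",
    "steady_state_gating",
    "derivatives",
    "current_densities",
    "find_resting_state",
    "integrate",
    "detect_spike",
]


@dataclass(frozen=True)
class HHParameters:
    """Membrane parameters of the regular-spiking cortical neuron.

    Defaults are the standard values used throughout this package; every
    field can be overridden one at a time (see :mod:`ctmsmt.sensitivity`).
    """

    C_m: float = 1.0  #: membrane capacitance, uF/cm^2
    g_leak: float = 0.016  #: leak conductance, mS/cm^2
    gbar_Na: float = 50.0  #: max sodium conductance, mS/cm^2
    gbar_K: float = 4.8  #: max delayed-rectifier conductance, mS/cm^2
    gbar_M: float = 0.13  #: max M-current (slow K) conductance, mS/cm^2
    E_leak: float = -70.3  #: leak reversal, mV
    E_Na: float = 50.0  #: sodium reversal, mV
    E_K: float = -90.0  #: potassium reversal, mV
    V_T: float = -61.5  #: spike-threshold adjustment voltage, mV
    tau_max: float = 1123.5  #: maximal M-current time constant, ms

    def __post_init__(self) -> None:
        for name in ("C_m", "g_leak", "gbar_Na", "gbar_K", "gbar_M"):
            if not getattr(self, name) >= 0.0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not self.C_m > 0.0:
            raise InvalidInputError("C_m must be strictly positive")
        if not (self.E_Na > self.E_leak > self.E_K):
            raise InvalidInputError("reversals must satisfy E_Na > E_leak > E_K")

    def replace(self, **changes) -> "HHParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class MembraneState:
    """Membrane potential and gating variables at one instant."""

    V_m: float  #: mV
    m: float  #: Na activation
    h: float  #: Na inactivation
    n: float  #: K activation
    p: float  #: slow-K activation

    def __post_init__(self) -> None:
        if not math.isfinite(self.V_m):
            raise InvalidInputError("V_m must be finite")
        for g in ("m", "h", "n", "p"):
            v = getattr(self, g)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"gate {g}={v} outside [0, 1]")


@dataclass(frozen=True)
class RateSet:
    """Channel kinetics evaluated at one membrane potential."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    p_inf: float
    tau_p: float


@dataclass(frozen=True)
class SimulationConfig:
    """Solver settings: fixed-step Euler on a 20 ms window by default."""

    dt: float = 1.0  #: integration step, us
    n_steps: int = 20000  #: iteration count (20 ms window at the default dt)
    spike_voltage: float = 0.0  #: action-potential detection level, mV
    settle_tolerance: float = 1e-6  #: resting-state convergence tolerance, mV/ms

    def __post_init__(self) -> None:
        if not self.dt > 0.0:
            raise InvalidInputError("dt must be positive")
        if self.n_steps < 1:
            raise InvalidInputError("n_steps must be >= 1")

    @property
    def window_us(self) -> float:
        return self.dt * self.n_steps

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class VoltageTrace:
    """Sampled membrane-potential trajectory plus spike metadata."""

    times: np.ndarray  #: us, length n_steps + 1
    V_m: np.ndarray  #: mV
    spiked: bool
    spike_time: float | None  #: us of the first upward crossing, None if no spike
    gates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def final_state(self) -> MembraneState:
        return MembraneState(
            V_m=float(self.V_m[-1]),
            m=float(self.gates["m"][-1]),
            h=float(self.gates["h"][-1]),
            n=float(self.gates["n"][-1]),
            p=float(self.gates["p"][-1]),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as ``time_us,V_m_mV`` with a JSON spike sidecar."""
        path = Path(path)
        arr = np.column_stack([self.times, self.V_m])
        np.savetxt(path, arr, delimiter=",", header="time_us,V_m_mV", comments="")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"spiked": self.spiked, "spike_time_us": self.spike_time})
        )


def compute_rates(V_m: float, params: HHParameters) -> RateSet:
    """Evaluate all six alpha/beta rate functions plus p_inf and tau_p.

    The removable 0/0 singularities of alpha_m (at V_T + 13), beta_m
    (at V_T + 40) and alpha_n (at V_T + 15) return the analytic limits
    0.32*4, 0.28*5 and 0.032*5 respectively.
    """
    if not math.isfinite(V_m):
        raise InvalidInputError("V_m must be finite")
    vals = _kernel.rates(float(V_m), params.V_T, params.tau_max)
    return RateSet(*[float(v) for v in vals])


def steady_state_gating(V_m: float, params: HHParameters) -> tuple[float, float, float, float]:
    """Gate fixed points at a clamped potential: x_inf = alpha/(alpha+beta), p = p_inf."""
    r = compute_rates(V_m, params)
    m = r.alpha_m / (r.alpha_m + r.beta_m)
    h = r.alpha_h / (r.alpha_h + r.beta_h)
    n = r.alpha_n / (r.alpha_n + r.beta_n)
    return m, h, n, r.p_inf


def current_densities(state: MembraneState, params: HHParameters) -> dict[str, float]:
    """Per-channel ionic current densities (uA/cm^2) at the given state."""
    V = state.V_m
    return {
        "leak": params.g_leak * (V - params.E_leak),
        "Na": params.gbar_Na * state.m ** 3 * state.h * (V - params.E_Na),
        "K": params.gbar_K * state.n ** 4 * (V - params.E_K),
        "M": params.gbar_M * state.p * (V - params.E_K),
    }


def derivatives(
    state: MembraneState, J_stim: float, params: HHParameters
) -> tuple[float, float, float, float, float]:
    """Time derivatives (dV/dt in mV/ms; gate derivatives in 1/ms).

    ``J_stim`` uses the public depolarizing-positive convention; the membrane
    equation subtracts the stimulus, so the sign is flipped here.
    """
    if not math.isfinite(J_stim):
        raise InvalidInputError("J_stim must be finite")
    r = compute_rates(state.V_m, params)
    J_ion = sum(current_densities(state, params).values())
    dV = (-J_ion - (-J_stim)) / params.C_m
    dm = r.alpha_m * (1.0 - state.m) - r.beta_m * state.m
    dh = r.alpha_h * (1.0 - state.h) - r.beta_h * state.h
    dn = r.alpha_n * (1.0 - state.n) - r.beta_n * state.n
    dp = (r.p_inf - state.p) / r.tau_p
    return dV, dm, dh, dn, dp


def _net_steady_current(V: float, params: HHParameters) -> float:
    m, h, n, p = steady_state_gating(V, params)
    return float(
        _kernel.ionic_current(
            V, m, h, n, p,
            params.g_leak, params.gbar_Na, params.gbar_K, params.gbar_M,
            params.E_leak, params.E_Na, params.E_K,
        )
    )


@lru_cache(maxsize=64)
def _resting_state_cached(params: HHParameters, tol: float) -> MembraneState:
    # first zero of the steady-state I-V curve above E_K: the stable rest point
    lo = params.E_K + 0.25
    grid = np.arange(lo, min(params.E_Na, 0.0), 0.25)
    f_lo = _net_steady_current(lo, params)
    V_rest = None
    for V in grid[1:]:
        f = _net_steady_current(float(V), params)
        if f_lo == 0.0:
            V_rest = float(V - 0.25)
            break
        if f_lo < 0.0 <= f or f_lo > 0.0 >= f:
            V_rest = brentq(
                _net_steady_current, V - 0.25, V, args=(params,), xtol=1e-12
            )
            break
        f_lo = f
    if V_rest is None:
        raise ConvergenceError("no resting fixed point found between E_K and 0 mV")
    m, h, n, p = steady_state_gating(V_rest, params)
    state = MembraneState(V_m=float(V_rest), m=m, h=h, n=n, p=p)
    dV = derivatives(state, 0.0, params)[0]
    if abs(dV) > tol:
        raise ConvergenceError(f"resting state residual |dV/dt| = {abs(dV):.3g} mV/ms")
    return state


def find_resting_state(
    params: HHParameters,
    config: SimulationConfig | None = None,
    method: str = "algebraic",
) -> MembraneState:
    """Resting state of the unstimulated membrane.

    ``method='algebraic'`` (default) solves the steady-state current balance
    directly, with gates at their fixed points.  ``method='settle'``
    integrates the free membrane for up to 5 s of simulated time and is used
    as an independent cross-check; the two agree to well under 0.01 mV.
    """
    config = config or SimulationConfig()
    tol = config.settle_tolerance
    if method == "algebraic":
        return _resting_state_cached(params, tol)
    if method != "settle":
        raise InvalidInputError(f"unknown method {method!r}")

    # settle at a coarser step: gate time constants are >= ~0.1 ms
    dt_ms = 0.02
    chunk = 25000  # 0.5 s of simulated time per chunk
    V = params.E_leak
    m, h, n, p = steady_state_gating(V, params)
    stim = np.zeros(1)
    for _ in range(10):  # up to 5 s
        V_tr, m_tr, h_tr, n_tr, p_tr, blow = _kernel.euler(
            stim, dt_ms, chunk, V, m, h, n, p,
            params.C_m, params.g_leak, params.gbar_Na, params.gbar_K,
            params.gbar_M, params.E_leak, params.E_Na, params.E_K,
            params.V_T, params.tau_max,
        )
        if blow >= 0:
            raise NumericalBlowupError(blow)
        V, m, h, n, p = (float(a[-1]) for a in (V_tr, m_tr, h_tr, n_tr, p_tr))
        state = MembraneState(V_m=V, m=m, h=h, n=n, p=p)
        if abs(derivatives(state, 0.0, params)[0]) < tol:
            ms, hs, ns, ps = steady_state_gating(V, params)
            return MembraneState(V_m=V, m=ms, h=hs, n=ns, p=ps)
    raise ConvergenceError("resting state did not settle within 5 s of simulated time")


def detect_spike(
    V_m: np.ndarray, dt: float, spike_voltage: float = 0.0
) -> tuple[bool, float | None]:
    """First upward crossing of ``spike_voltage`` in a raw voltage trace.

    Returns ``(spiked, spike_time_us)`` where the spike time is the time of
    the first sample strictly above the detection level whose predecessor was
    at or below it.
    """
    V_m = np.asarray(V_m, dtype=float)
    if V_m.size == 0:
        raise InvalidInputError("empty trace")
    above = V_m > spike_voltage
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if crossings.size == 0:
        return False, None
    return True, float((crossings[0] + 1) * dt)


def integrate(
    initial: MembraneState,
    stimulus: "StimulusWaveform",
    config: SimulationConfig | None = None,
    params: HHParameters | None = None,
) -> VoltageTrace:
    """Forward-Euler integration of the driven membrane over the full window.

    The stimulus must be sampled on the configured dt grid and fit inside
    the window; the remainder of the window is stimulus-free so that delayed
    spikes can develop.
    """
    config = config or SimulationConfig()
    params = params or HHParameters()
    if abs(stimulus.dt - config.dt) > 1e-9 * max(stimulus.dt, config.dt):
        raise InvalidInputError(
            f"stimulus dt {stimulus.dt} us does not match solver dt {config.dt} us"
        )
    samples = np.ascontiguousarray(stimulus.samples, dtype=float)
    if samples.shape[0] > config.n_steps:
        from .errors import WindowOverflowError

        raise WindowOverflowError(
            f"stimulus of {samples.shape[0]} samples exceeds the "
            f"{config.n_steps}-step window"
        )

    dt_ms = config.dt / 1000.0
    V_tr, m_tr, h_tr, n_tr, p_tr, blow = _kernel.euler(
        samples, dt_ms, config.n_steps,
        initial.V_m, initial.m, initial.h, initial.n, initial.p,
        params.C_m, params.g_leak, params.gbar_Na, params.gbar_K, params.gbar_M,
        params.E_leak, params.E_Na, params.E_K, params.V_T, params.tau_max,
    )
    if blow >= 0:
        raise NumericalBlowupError(blow)

    spiked, spike_time = detect_spike(V_tr, config.dt, config.spike_voltage)
    times = np.arange(config.n_steps + 1) * config.dt
    return VoltageTrace(
        times=times,
        V_m=V_tr,
        spiked=spiked,
        spike_time=spike_time,
        gates={"m": m_tr, "h": h_tr, "n": n_tr, "p": p_tr},
    )
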