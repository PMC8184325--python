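"""Bisection searches for motor-threshold surrogates.

The model's surrogate for the motor threshold is the smallest stimulus that
elicits an action potential in the point neuron.  Two searches are provided:

* amplitude search — minimum intensity (%MSO) for a fixed pulse shape;
* width search — minimum major-phase width (ThPW, us) at a fixed intensity,
  with the compensatory phase re-derived at every trial width so that charge
  balance is preserved.

Both are plain deterministic bisections: the low endpoint of the bracket
never spikes, the high endpoint always spikes, and the reported value is the
high endpoint of the final bracket (the smallest width/intensity known to
spike, within tolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DegenerateStimulusError, UnexcitableConfigurationError
from .hh import HHParameters, SimulationConfig, find_resting_state, integrate
from .pulses import CouplingModel, PulseSpec, build_pulse

__all__ = [
    "ThresholdResult",
    "find_threshold_amplitude",
    "find_threshold_pulse_width",
    "strength_duration_curve",
]

logger = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    """Outcome of one bisection search."""

    value: float  #: threshold amplitude (%MSO) or width (us)
    mode: str  #: 'amplitude-search' or 'width-search'
    tolerance: float
    bracket_history: list[tuple[float, float]] = field(repr=False)
    converged: bool = True
    iterations: int = 0
    spec: PulseSpec | None = None
    spike_time_us: float | None = None  #: spike time at the reported threshold

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "mode": self.mode,
            "tolerance": self.tolerance,
            "converged": self.converged,
            "iterations": self.iterations,
            "spike_time_us": self.spike_time_us,
            "spec": None if self.spec is None else self.spec.__dict__,
            "bracket_history": self.bracket_history,
        }


def _spikes(
    spec: PulseSpec,
    params: HHParameters,
    config: SimulationConfig,
    coupling: CouplingModel,
    resting,
) -> tuple[bool, float | None]:
    wf = build_pulse(spec, coupling, config.dt)
    trace = integrate(resting, wf, config, params)
    return trace.spiked, trace.spike_time


def find_threshold_amplitude(
    spec: PulseSpec,
    params: HHParameters | None = None,
    config: SimulationConfig | None = None,
    coupling: CouplingModel | None = None,
    lo: float = 0.0,
    hi: float = 200.0,
    tol: float = 0.05,
) -> ThresholdResult:
    """Minimum intensity (%MSO) that elicits an action potential.

    The search brackets the threshold between a non-spiking ``lo`` and a
    spiking ``hi`` (doubled up to 400 %MSO if needed) and bisects to ``tol``.
    The ``amplitude`` field of ``spec`` is ignored; the returned value is the
    high endpoint of the final bracket.
    """
    params = params or HHParameters()
    config = config or SimulationConfig()
    coupling = coupling or CouplingModel()
    resting = find_resting_state(params, config)

    def spikes_at(amplitude: float) -> tuple[bool, float | None]:
        return _spikes(spec.replace(amplitude=amplitude), params, config, coupling, resting)

    if lo > 0.0 and spikes_at(lo)[0]:
        raise DegenerateStimulusError(f"lower bound {lo} %MSO already spikes")
    while not spikes_at(hi)[0]:
        hi *= 2.0
        if hi > 400.0:
            raise UnexcitableConfigurationError(
                "no action potential up to 400 %MSO for this configuration"
            )

    history = [(lo, hi)]
    iterations = 0
    spike_time = None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        spiked, t_sp = spikes_at(mid)
        logger.debug("amplitude bisection: lo=%.4f hi=%.4f mid=%.4f spiked=%s", lo, hi, mid, spiked)
        if spiked:
            hi, spike_time = mid, t_sp
        else:
            lo = mid
        history.append((lo, hi))
        iterations += 1

    if spike_time is None:
        spike_time = spikes_at(hi)[1]
    return ThresholdResult(
        value=hi,
        mode="amplitude-search",
        tolerance=tol,
        bracket_history=history,
        converged=hi - lo <= tol,
        iterations=iterations,
        spec=spec.replace(amplitude=hi),
        spike_time_us=spike_time,
    )


def find_threshold_pulse_width(
    spec: PulseSpec,
    params: HHParameters | None = None,
    config: SimulationConfig | None = None,
    coupling: CouplingModel | None = None,
    lo: float = 1.0,
    hi: float = 1000.0,
    tol: float = 0.1,
) -> ThresholdResult:
    """Minimum major-phase width (us) that spikes at the fixed intensity.

    ``spec.amplitude`` is held fixed; ``spec.main_pw`` is the free variable.
    The compensatory phase is rebuilt at every trial width, preserving charge
    balance.  The reported value is the high endpoint of the final bracket.
    """
    params = params or HHParameters()
    config = config or SimulationConfig()
    coupling = coupling or CouplingModel()
    resting = find_resting_state(params, config)

    def spikes_at(width: float) -> tuple[bool, float | None]:
        return _spikes(spec.replace(main_pw=width), params, config, coupling, resting)

    if spikes_at(lo)[0]:
        raise DegenerateStimulusError(f"lower bound {lo} us already spikes")
    if not spikes_at(hi)[0]:
        raise UnexcitableConfigurationError(
            f"no action potential at width {hi} us for amplitude {spec.amplitude} %MSO"
        )

    history = [(lo, hi)]
    iterations = 0
    spike_time = None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        spiked, t_sp = spikes_at(mid)
        logger.debug("width bisection: lo=%.3f hi=%.3f mid=%.3f spiked=%s", lo, hi, mid, spiked)
        if spiked:
            hi, spike_time = mid, t_sp
        else:
            lo = mid
        history.append((lo, hi))
        iterations += 1

    if spike_time is None:
        spike_time = spikes_at(hi)[1]
    return ThresholdResult(
        value=hi,
        mode="width-search",
        tolerance=tol,
        bracket_history=history,
        converged=hi - lo <= tol,
        iterations=iterations,
        spec=spec.replace(main_pw=hi),
        spike_time_us=spike_time,
    )


def strength_duration_curve(
    spec: PulseSpec,
    widths,
    params: HHParameters | None = None,
    config: SimulationConfig | None = None,
    coupling: CouplingModel | None = None,
    **search_kwargs,
) -> pd.DataFrame:
    """Threshold intensity as a function of major-phase width.

    Runs the amplitude search at every width and returns a DataFrame with
    columns ``width_us`` and ``mt_pct_mso``, sorted by width.
    """
    widths = list(widths)
    if not widths:
        raise ValueError("width list must be nonempty")
    rows = []
    for w in sorted(widths):
        res = find_threshold_amplitude(
            spec.replace(main_pw=w), params, config, coupling, **search_kwargs
        )
        rows.append({"width_us": w, "mt_pct_mso": res.value})
    return pd.DataFrame(rows)
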