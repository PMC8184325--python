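"""Comparison of model threshold estimates against published measurements.

The packaged fixture carries the experimentally measured population-average
values that are printed as numbers in the source reports: the resting motor
threshold of the 60 us, m = 0.2 unidirectional pulse (32% MSO) and the
threshold pulse width measured at 120% of that RMT (47.3 us).  Records whose
provenance is ``figure-derived-approximate`` are for plotting only and are
never eligible for quantitative validation.

Two error metrics are reported for every matched model/experiment pair:

* absolute error in %MSO points, |model - experimental|;
* relative error in percent, 100 |model - experimental| / experimental.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import InvalidInputError
from .hh import HHParameters, SimulationConfig
from .pulses import CouplingModel, PulseSpec
from .thresholds import find_threshold_amplitude, find_threshold_pulse_width

__all__ = [
    "ExperimentalRecord",
    "load_experimental_records",
    "absolute_error_points",
    "relative_error_percent",
    "validation_report",
    "run_default_validation",
    "REFERENCE_PULSE",
]

#: The pulse whose printed RMT anchors validation: unidirectional, 60 us
#: major phase, m = 0.2, initial direction AP.
REFERENCE_PULSE = PulseSpec(family="unidirectional", main_pw=60.0, m_ratio=0.2, direction="AP")


@dataclass(frozen=True)
class ExperimentalRecord:
    """One published threshold measurement."""

    label: str
    measure: str  #: RMT / AMT / ThPW
    value: float  #: %MSO or us
    units: str
    provenance: str  #: 'printed-in-text' or 'figure-derived-approximate'
    source: str

    @property
    def acceptance_eligible(self) -> bool:
        return self.provenance == "printed-in-text"


def load_experimental_records() -> list[ExperimentalRecord]:
    """Load the packaged fixture of published threshold values."""
    text = resources.files("ctmsmt.data").joinpath("experimental_records.json").read_text()
    payload = json.loads(text)
    return [ExperimentalRecord(**rec) for rec in payload["records"]]


def absolute_error_points(model: float, experimental: float) -> float:
    """Absolute difference |model - experimental| in the measure's own units."""
    import math

    if not (math.isfinite(model) and math.isfinite(experimental)):
        raise InvalidInputError("both values must be finite")
    return abs(model - experimental)


def relative_error_percent(model: float, experimental: float) -> float:
    """Relative error 100 * |model - experimental| / experimental, percent."""
    if experimental == 0.0:
        raise InvalidInputError("experimental value must be nonzero")
    return 100.0 * absolute_error_points(model, experimental) / abs(experimental)


def validation_report(
    estimates: dict[str, float],
    records: list[ExperimentalRecord] | None = None,
) -> pd.DataFrame:
    """One row per model estimate matched to a published record by label.

    Columns: label, measure, model, experimental, units, abs_error,
    rel_error_pct, provenance, acceptance_eligible.  Unmatched labels are
    skipped with a warning.
    """
    records = load_experimental_records() if records is None else records
    by_label = {rec.label: rec for rec in records}
    rows = []
    for label, model_value in estimates.items():
        rec = by_label.get(label)
        if rec is None:
            warnings.warn(f"no experimental record matches label {label!r}; row skipped")
            continue
        rows.append(
            {
                "label": label,
                "measure": rec.measure,
                "model": model_value,
                "experimental": rec.value,
                "units": rec.units,
                "abs_error": absolute_error_points(model_value, rec.value),
                "rel_error_pct": relative_error_percent(model_value, rec.value),
                "provenance": rec.provenance,
                "acceptance_eligible": rec.acceptance_eligible,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "measure",
            "model",
            "experimental",
            "units",
            "abs_error",
            "rel_error_pct",
            "provenance",
            "acceptance_eligible",
        ],
    )


def run_default_validation(
    params: HHParameters | None = None,
    config: SimulationConfig | None = None,
    coupling: CouplingModel | None = None,
    test_intensity_factor: float = 1.2,
    rmt_reference: str = "model",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Compute the two model estimates and compare them to the fixture.

    The width search runs at ``test_intensity_factor`` times either the
    model's own RMT estimate (``rmt_reference='model'``, default) or the
    published experimental RMT (``rmt_reference='experimental'``).
    Returns (report DataFrame, raw estimates dict).
    """
    records = load_experimental_records()
    rmt_result = find_threshold_amplitude(REFERENCE_PULSE, params, config, coupling)

    if rmt_reference == "model":
        test_amplitude = test_intensity_factor * rmt_result.value
    elif rmt_reference == "experimental":
        exp_rmt = next(r for r in records if r.measure == "RMT" and r.acceptance_eligible)
        test_amplitude = test_intensity_factor * exp_rmt.value
    else:
        raise InvalidInputError("rmt_reference must be 'model' or 'experimental'")

    thpw_result = find_threshold_pulse_width(
        REFERENCE_PULSE.replace(amplitude=test_amplitude), params, config, coupling
    )
    estimates = {
        "#1RMT 60us m0.2 unidirectional AP": rmt_result.value,
        "ThPW at 120% #1RMT": thpw_result.value,
    }
    return validation_report(estimates, records), estimates
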