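"""Construction of cTMS stimulus waveforms in physical current-density units.

A controllable-TMS device produces near-rectangular coil-voltage pulses; the
induced cortical electric field, and hence the tissue current density, is
proportional to the coil voltage.  This module maps a declarative pulse
description (family, main-phase width, m-ratio, intensity in %MSO) onto a
sampled current-density waveform for the point-neuron model:

    %MSO -> coil voltage -> E-field -> J = sigma * E

Charge balance: the capacitors of the device must return to their initial
state, so every pulse carries a compensatory phase whose area cancels the
major phase ("almost zero net current at the end of each pulse").  The
compensatory peak is ``m_ratio`` times the major peak and its width is
``main_pw / m_ratio``; after rounding widths to the sample grid the
compensatory amplitude is re-solved so the discrete areas cancel exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np

from .errors import InvalidInputError, WaveformFormatError

__all__ = [
    "PulseSpec",
    "CouplingModel",
    "StimulusWaveform",
    "mso_to_current_density",
    "build_pulse",
    "load_waveform_csv",
]

FAMILIES = ("monophasic", "unidirectional", "bidirectional")


@dataclass(frozen=True)
class PulseSpec:
    """Declarative description of one cTMS pulse.

    The pulse is named by the width of its major (higher-amplitude) phase;
    ``m_ratio`` is the peak of the minor, compensatory phase divided by the
    peak of the major phase.  The bidirectional family is the symmetric
    special case m = 1.  ``direction`` (PA/AP) is the cortical direction of
    the initial phase; for a single-compartment neuron it is metadata only.

    ``major_phase_first`` controls phase order (major phase leads by
    default); ``depolarizing_phase`` maps either the major or the initial
    phase onto the depolarizing (positive) sign — with the default order the
    two conventions coincide.
    """

    family: str
    main_pw: float  #: major-phase width, us
    m_ratio: float = 0.2
    direction: str = "PA"
    amplitude: float = 0.0  #: stimulus intensity, %MSO
    depolarizing_phase: str = "major"
    major_phase_first: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidInputError(f"unknown pulse family {self.family!r}")
        if not self.main_pw > 0.0:
            raise InvalidInputError("main_pw must be positive")
        if self.family == "bidirectional" and self.m_ratio != 1.0:
            object.__setattr__(self, "m_ratio", 1.0)
        if not (0.0 < self.m_ratio <= 1.0):
            raise InvalidInputError("m_ratio must lie in (0, 1]")
        if self.direction not in ("PA", "AP"):
            raise InvalidInputError("direction must be 'PA' or 'AP'")
        if self.amplitude < 0.0:
            raise InvalidInputError("amplitude (%MSO) must be non-negative")
        if self.depolarizing_phase not in ("major", "initial"):
            raise InvalidInputError("depolarizing_phase must be 'major' or 'initial'")

    def replace(self, **changes) -> "PulseSpec":
        return replace(self, **changes)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PulseSpec":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CouplingModel:
    """Scalar mapping from stimulator output to cortical current density.

    At full output the device applies ``mso_voltage`` to the coil; each kV of
    coil voltage induces ``efield_per_kv`` V/m at the hand-motor target, and
    Ohmic tissue with conductivity ``conductivity`` converts the field to a
    current density.  With the defaults, 1 kV -> 100 V/m -> 27 A/m^2.
    """

    mso_voltage: float = 2800.0  #: coil voltage at 100% MSO, V
    efield_per_kv: float = 100.0  #: induced E-field per kV, (V/m)/kV
    conductivity: float = 0.27  #: tissue conductivity, S/m

    def __post_init__(self) -> None:
        for name in ("mso_voltage", "efield_per_kv", "conductivity"):
            if not getattr(self, name) > 0.0:
                raise InvalidInputError(f"{name} must be positive")

    @property
    def current_density_per_kv(self) -> float:
        """Induced current density per kV of coil voltage, A/m^2."""
        return self.efield_per_kv * self.conductivity

    def replace(self, **changes) -> "CouplingModel":
        return replace(self, **changes)


@dataclass
class StimulusWaveform:
    """A pulse realized on the solver's sample grid.

    ``samples`` hold the stimulus current density in uA/cm^2 with the
    depolarizing-positive sign convention; ``phase_boundaries`` are the
    sample indices at which a new phase starts (excluding 0).
    """

    dt: float  #: us
    samples: np.ndarray  #: uA/cm^2
    phase_boundaries: tuple[int, ...]
    spec: Union[PulseSpec, str]

    @property
    def duration_us(self) -> float:
        return self.samples.shape[0] * self.dt

    @property
    def net_charge(self) -> float:
        """Signed area, uA/cm^2 * us."""
        return float(self.samples.sum() * self.dt)

    @property
    def rectified_charge(self) -> float:
        return float(np.abs(self.samples).sum() * self.dt)

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if self.samples.size else 0.0

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        arr = np.column_stack([np.arange(len(self.samples)) * self.dt, self.samples])
        np.savetxt(
            path, arr, delimiter=",", header="time_us,J_uA_per_cm2", comments=""
        )


def mso_to_current_density(amplitude: float, coupling: CouplingModel | None = None) -> float:
    """Map stimulator intensity (%MSO) to cortical current density (uA/cm^2).

    amplitude/100 * (mso_voltage/1000 kV) * efield_per_kv * conductivity
    gives A/m^2; 1 A/m^2 = 100 uA/cm^2.
    """
    coupling = coupling or CouplingModel()
    if amplitude < 0.0:
        raise InvalidInputError("amplitude (%MSO) must be non-negative")
    j_a_per_m2 = (
        amplitude / 100.0 * coupling.mso_voltage / 1000.0 * coupling.current_density_per_kv
    )
    return j_a_per_m2 * 100.0


def build_pulse(
    spec: PulseSpec,
    coupling: CouplingModel | None = None,
    dt: float = 1.0,
) -> StimulusWaveform:
    """Realize a pulse spec as a charge-balanced sampled waveform.

    The major phase is a rectangle of ``main_pw`` at the mapped amplitude;
    the compensatory phase is a rectangle of nominal width ``main_pw /
    m_ratio`` at ``m_ratio`` times the amplitude, re-solved after grid
    rounding so that the discrete phase areas cancel exactly.  For the
    bidirectional family the two phases are equal-width mirror images.
    """
    coupling = coupling or CouplingModel()
    if dt <= 0.0:
        raise InvalidInputError("dt must be positive")
    J_peak = mso_to_current_density(spec.amplitude, coupling)

    n_major = max(1, round(spec.main_pw / dt))
    if spec.family == "bidirectional":
        n_minor = n_major
    else:
        n_minor = max(1, round(spec.main_pw / spec.m_ratio / dt))
    # exact discrete charge balance after rounding
    J_minor = J_peak * n_major / n_minor

    major = np.full(n_major, J_peak)
    minor = np.full(n_minor, -J_minor)

    if spec.major_phase_first:
        samples = np.concatenate([major, minor])
        boundaries = (n_major,)
        initial_is_major = True
    else:
        samples = np.concatenate([minor, major])
        boundaries = (n_minor,)
        initial_is_major = False

    depolarize_major = (
        spec.depolarizing_phase == "major"
        or (spec.depolarizing_phase == "initial" and initial_is_major)
    )
    if not depolarize_major:
        samples = -samples

    return StimulusWaveform(dt=dt, samples=samples, phase_boundaries=boundaries, spec=spec)


def load_waveform_csv(
    path: str | Path,
    amplitude: float,
    coupling: CouplingModel | None = None,
    dt: float = 1.0,
) -> StimulusWaveform:
    """Load a user-supplied normalized waveform and scale it to %MSO units.

    The file must be a two-column CSV ``time_us,normalized_amplitude`` with
    uniform sample spacing (jitter beyond 1% is rejected).  Samples are
    resampled onto the dt grid by nearest-sample lookup and scaled by the
    current density mapped from ``amplitude``.
    """
    coupling = coupling or CouplingModel()
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty files warn before the shape check below
            data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:
        raise WaveformFormatError(f"cannot parse waveform CSV {path}: {exc}") from exc
    if data.size == 0 or data.shape[0] < 2 or data.shape[1] != 2:
        raise WaveformFormatError(
            f"waveform CSV {path} must have >= 2 rows of time_us,normalized_amplitude"
        )
    t, a = data[:, 0], data[:, 1]
    spacing = np.diff(t)
    mean_dt = float(spacing.mean())
    if mean_dt <= 0 or np.any(np.abs(spacing - mean_dt) > 0.01 * mean_dt):
        raise WaveformFormatError("nonuniform sample spacing beyond 1% jitter")

    duration = t[-1] - t[0] + mean_dt
    n_out = max(1, round(duration / dt))
    t_out = t[0] + np.arange(n_out) * dt
    idx = np.clip(np.round((t_out - t[0]) / mean_dt).astype(int), 0, len(a) - 1)
    samples = a[idx] * mso_to_current_density(amplitude, coupling)
    return StimulusWaveform(dt=dt, samples=samples, phase_boundaries=(), spec="external")
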