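"""Exception types raised by the simulator and the threshold searches."""


class CtmsmtError(Exception):
    """Base class for all modeled errors in this package."""


class InvalidInputError(CtmsmtError, ValueError):
    """A physically or numerically invalid input (non-finite voltage, negative amplitude, ...)."""


class NumericalBlowupError(CtmsmtError, ArithmeticError):
    """The membrane state became non-finite during integration."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite membrane state at Euler step {step}")


class ConvergenceError(CtmsmtError, RuntimeError):
    """An iterative procedure (resting-state settle) failed to converge."""


class UnexcitableConfigurationError(CtmsmtError, RuntimeError):
    """No spike could be elicited at the maximum allowed stimulus."""


class DegenerateStimulusError(CtmsmtError, RuntimeError):
    """The lower search bound already elicits a spike; the threshold is not bracketed."""


class WindowOverflowError(CtmsmtError, ValueError):
    """The stimulus waveform does not fit inside the simulation window."""


class WaveformFormatError(CtmsmtError, ValueError):
    """A user-supplied waveform file violates the expected CSV format."""
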