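"""Exception hierarchy for the felanding package."""


class FelandingError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FelandingError, ValueError):
    """A configuration field violates its invariant; the message names the field."""


class NoContactError(FelandingError, ValueError):
    """The vertical ground-reaction force never exceeds the contact threshold."""


class DegeneratePhaseError(FelandingError, ValueError):
    """Maximum elbow flexion occurs at or before ground contact."""


class SignalError(FelandingError, ValueError):
    """A signal is too short, non-finite, or otherwise unusable."""


class TrainingDivergedError(FelandingError, RuntimeError):
    """Training loss became non-finite; carries the epoch at which it happened."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training loss became non-finite at epoch {epoch}")


class UndefinedMetricError(FelandingError, ValueError):
    """A classifier metric has a zero denominator (reported via flags, raised on request)."""
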