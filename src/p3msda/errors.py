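"""Exception types shared across the package."""


class P3MSDAError(Exception):
    """Base class for package errors."""


class ConfigurationError(P3MSDAError):
    """A configuration value violates its documented constraints."""


class EmptySelectionError(P3MSDAError):
    """An operation that requires at least one trial/subject got none."""


class DegenerateInputError(P3MSDAError):
    """Input is numerically degenerate (e.g. zero-energy denominator)."""


class TrainingDivergedError(P3MSDAError):
    """Optimisation produced non-finite losses; carries diagnostics."""

    def __init__(self, message: str, epoch: int | None = None,
                 batch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
        self.batch = batch
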