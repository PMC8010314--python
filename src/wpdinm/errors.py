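"""Exception hierarchy for the pipeline."""


class WpdinmError(Exception):
    """Base class for all package-specific errors."""


class ParseError(WpdinmError):
    """A malformed line in an input file; message names file and line."""


class DimensionError(WpdinmError):
    """Inconsistent vector/matrix dimensions (e.g. ragged expression rows)."""


class ConfigError(WpdinmError):
    """A configuration value outside its admissible range."""


class DegenerateInputError(WpdinmError):
    """Input that makes a formula ill-defined (e.g. all-zero spectra)."""


class EmptyInputError(WpdinmError):
    """A required structure is empty (e.g. no domains)."""


class ConvergenceError(WpdinmError):
    """Score iteration exceeded max_iter without meeting the tolerance."""

    def __init__(self, message: str, residual_sq: float | None = None):
        super().__init__(message)
        self.residual_sq = residual_sq
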