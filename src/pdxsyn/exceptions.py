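"""Exception hierarchy for pdxsyn."""


class PdxsynError(Exception):
    """Base class for all pdxsyn errors."""


class DataFormatError(PdxsynError):
    """The input table cannot be parsed or lacks a required column."""


class ValidationError(PdxsynError):
    """One or more rows violate a record invariant (e.g. volume <= 0)."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class DuplicateRecordError(ValidationError):
    """Multiple discrepant measurements for the same (mouse, day)."""


class ArmLabelError(DataFormatError):
    """A treatment label could not be mapped to one of C, A, B, AB."""


class InsufficientDataError(PdxsynError):
    """Fewer than two mice contribute to a required (arm, day) summary."""


class ExtrapolationError(PdxsynError):
    """A requested day lies outside a mouse's observed span."""


class InferenceError(PdxsynError):
    """A resampling procedure cannot produce a valid interval."""


class ConfigurationError(PdxsynError):
    """A simulation or analysis configuration is internally inconsistent."""
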