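"""Exception hierarchy for the screening pipeline.

Every hard failure carries enough context (batch, condition, line number)
to make an excluded plate or condition auditable from the log alone.
"""


class CiliaScreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CiliaScreenError):
    """A simulation or run configuration is invalid (names the offending field/condition)."""


class ValidationError(CiliaScreenError):
    """A data table failed validation."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateControlsError(CiliaScreenError):
    """Control pool has zero spread (MAD = 0); the batch must be excluded."""

    def __init__(self, message: str, batch=None):
        self.batch = batch
        super().__init__(message)


class ZeroVarianceError(CiliaScreenError):
    """Both comparison groups have zero variance; SSMD is undefined."""


class StructuralError(CiliaScreenError):
    """The data violate the layout the analysis assumes (missing control class,
    condition spanning batches, missing matched control)."""


class UnclassifiableProfileError(CiliaScreenError):
    """A z-profile channel is all zero; no peak can be located."""
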