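"""Exception hierarchy used across the package."""


class MitofluxError(Exception):
    """Base class for all package errors."""


class FormatError(MitofluxError):
    """A text input does not match the documented dialect."""


class ValidationError(MitofluxError):
    """Input parsed but violates an invariant (e.g. non-monotone times)."""


class LayoutError(MitofluxError):
    """A well id is absent from, or inconsistent with, the plate layout."""


class ProtocolError(MitofluxError):
    """A measurement schedule is incompatible with the requested protocol."""


class DensityError(MitofluxError):
    """Requested cell count cannot be placed in the field of view."""


class DenominatorError(MitofluxError):
    """Normalization denominator is absent, zero, or negative."""

    def __init__(self, message: str, flags: set[str] | None = None):
        super().__init__(message)
        self.flags = flags or set()


class QCError(MitofluxError):
    """Insufficient data for a plate-level QC computation."""


class ConfigError(MitofluxError):
    """A run configuration is invalid."""


class PipelineError(MitofluxError):
    """One or more wells failed during an end-to-end run."""

    def __init__(self, message: str, well_errors: dict[str, str] | None = None):
        super().__init__(message)
        self.well_errors = well_errors or {}
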