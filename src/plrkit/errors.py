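"""Exception hierarchy shared across the toolkit."""


class PlrkitError(Exception):
    """Base class for all plrkit errors."""


class SchemaError(PlrkitError, ValueError):
    """An input table is missing required columns or has unparseable fields."""


class ValidationError(PlrkitError, ValueError):
    """A value violates a domain invariant (e.g. non-positive pupil area)."""


class FitError(PlrkitError, RuntimeError):
    """A curve fit failed to converge after all restarts.

    Carries optimizer diagnostics in ``details`` when available.
    """

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details


class DegenerateFitError(FitError):
    """The data cannot identify the model (e.g. a constant trace)."""
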