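"""Exception hierarchy shared across the package."""


class FluxmaintError(Exception):
    """Base class for all package errors."""


class FormatError(FluxmaintError):
    """A file or formula could not be parsed."""


class ConfigurationError(FluxmaintError):
    """A model lacks a required component (e.g. maintenance reaction)."""


class ValidationError(FluxmaintError):
    """Input data violates a documented precondition."""


class MappingError(FluxmaintError):
    """A reaction or metabolite id could not be resolved."""


class EngineError(FluxmaintError):
    """The LP solver failed in an unexpected way."""


class EstimationError(FluxmaintError):
    """No feasible grid point was found during maintenance estimation."""


class InsufficientDataError(FluxmaintError):
    """Too few data points for the requested computation."""


class WashoutError(FluxmaintError):
    """Requested dilution rate exceeds the maximal growth rate."""
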