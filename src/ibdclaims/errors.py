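"""Exception hierarchy for the pipeline."""


class IbdClaimsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IbdClaimsError):
    """A configuration field is missing, malformed or out of range."""


class DataError(IbdClaimsError):
    """An input table violates its contract (duplicate ids, missing persons...)."""


class CoverageError(IbdClaimsError):
    """An age group with positive standard weight has no rate / no population."""


class UndefinedRateError(IbdClaimsError):
    """Cases observed against a zero population denominator."""


class TrendFitError(IbdClaimsError):
    """The Poisson IRLS fitter failed to converge."""
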