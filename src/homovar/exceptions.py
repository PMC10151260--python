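"""Exception hierarchy for homovar."""


class HomovarError(Exception):
    """Base class for all homovar errors."""


class ValidationError(HomovarError, ValueError):
    """Input fails a precondition (group too small, bad alpha, ...)."""


class ConfigurationError(HomovarError, ValueError):
    """Malformed configuration: missing column, unknown test name, bad scenario."""


class DegenerateDataError(HomovarError, ValueError):
    """Data admit no meaningful statistic (e.g. a zero sample variance)."""


class NumericalError(HomovarError, RuntimeError):
    """A numerical routine failed to converge."""
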