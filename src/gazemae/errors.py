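"""Exception hierarchy for the gazemae pipeline."""


class GazemaeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazemaeError):
    """An experiment or stimulus configuration violates its invariants."""


class ParameterError(GazemaeError):
    """A model parameter is outside its admissible range."""


class DataError(GazemaeError):
    """Input data are malformed, empty, or insufficient for an operation."""
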