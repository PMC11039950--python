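"""Exception hierarchy for the MR pipeline."""


class GutmrError(Exception):
    """Base class for all package errors."""


class FormatError(GutmrError):
    """A delimited input file violates the expected layout or value ranges."""


class ConfigError(GutmrError):
    """A configuration object carries impossible or inconsistent values."""


class DegenerateInstrumentError(GutmrError):
    """An instrument with zero exposure effect cannot yield a Wald ratio."""


class InsufficientInstrumentsError(GutmrError):
    """An estimator was asked to run on fewer instruments than it requires."""


class EmptyInstrumentSetError(GutmrError):
    """Harmonization left no usable instrument for an exposure-outcome pair."""
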