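"""Exception hierarchy shared across the pipeline stages."""


class EpinetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpinetError):
    """Invalid parameter, threshold, or simulation specification."""


class DataError(EpinetError):
    """Input data violate a precondition (missing columns, degenerate values)."""


class FormatError(DataError):
    """A file does not conform to its declared on-disk format."""


class PedigreeError(DataError):
    """Pedigree is cyclic or references unknown individuals."""


class NumericalError(EpinetError):
    """A model fit or decomposition failed numerically."""
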