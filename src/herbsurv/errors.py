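"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration 2, data 3, numerical 4.
"""


class HerbsurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HerbsurvError):
    """Invalid configuration; the message names the offending field."""


class DataError(HerbsurvError):
    """Malformed or inconsistent input data."""


class NumericalError(HerbsurvError):
    """An iterative fit failed to converge or hit a degenerate state."""
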