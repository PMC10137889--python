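"""Exception types shared across the package."""


class PopgenflowError(Exception):
    """Base class for all package errors."""


class AlignmentError(PopgenflowError):
    """Malformed alignment: unequal lengths, empty input, bad alphabet."""


class MappingError(PopgenflowError):
    """Sample/population bookkeeping problems (missing popmap entries...)."""


class DataError(PopgenflowError):
    """Valid files but scientifically unusable input (n too small, no sites...)."""


class ConfigError(PopgenflowError):
    """Invalid pipeline or simulator configuration."""
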