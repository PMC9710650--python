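"""Exception hierarchy shared by all proteoflow modules."""


class ProteoflowError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ProteoflowError):
    """The input file does not conform to the expected table dialect."""


class ParseError(ProteoflowError):
    """A cell could not be parsed; the message carries row/column location."""


class DesignError(ProteoflowError):
    """Sample names cannot be assembled into a consistent analysis design."""


class NormalizationError(ProteoflowError):
    """A normalization step cannot be applied to the given matrix."""


class ConfigError(ProteoflowError):
    """A configuration value is unknown or inconsistent."""


class InsufficientDataError(ProteoflowError):
    """Too few observations for the requested statistic; callers may skip."""
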