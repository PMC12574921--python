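"""Exception hierarchy shared across the package."""


class LisnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LisnetError, ValueError):
    """A simulation or scoring configuration violates its invariants."""


class FormatError(LisnetError, ValueError):
    """An input file does not match any supported dialect."""


class MissingPredictionError(LisnetError, FileNotFoundError):
    """No parseable prediction is available for a requested pair."""


class UndefinedRatioError(LisnetError, ZeroDivisionError):
    """A ratio (fold change, normalisation) has a zero denominator."""


class UnusableImageError(LisnetError, ValueError):
    """An eye image or its masks cannot be measured (e.g. empty mask)."""
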