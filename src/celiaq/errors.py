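"""Exception families used across the pipeline.

Each family maps to a distinct nonzero CLI exit code (see :mod:`celiaq.cli`).
"""


class CeliaqError(Exception):
    """Base class for all package errors."""


class CategoryError(CeliaqError):
    """An unknown or malformed Marsh category / tissue class."""


class DimensionError(CeliaqError):
    """Requested geometry does not fit the canvas, or array shapes disagree."""


class FormatError(CeliaqError):
    """An input file or array is not in the expected format."""


class DependencyError(CeliaqError):
    """A required companion input (e.g. the class mask for cell lookup) is missing."""


class UndefinedFeatureError(CeliaqError):
    """A feature is undefined for this specimen (zero denominator); carries the feature name."""

    def __init__(self, feature: str, reason: str):
        self.feature = feature
        self.reason = reason
        super().__init__(f"feature '{feature}' undefined: {reason}")


class ScoringError(CeliaqError):
    """A feature required by the scoring model is missing; names the feature."""


class FitError(CeliaqError):
    """Regression cannot be fitted (too few rows, rank deficiency)."""


class InsufficientDataError(CeliaqError):
    """Too few observations for the requested statistic."""


class ConfigError(CeliaqError):
    """Configuration file is malformed or contains unknown keys."""


class IntegrityError(CeliaqError):
    """A packaged fixture is missing or fails its checksum."""


class UnclassifiedPixelError(CeliaqError):
    """Tint rules fail to cover some pixels; carries the offending pixel count."""

    def __init__(self, count: int):
        self.count = count
        super().__init__(f"{count} pixels not covered by any tint rule")
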