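"""Exception hierarchy shared across the pipeline stages."""


class SlideProteoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SlideProteoError):
    """Invalid simulation or pipeline configuration."""


class FormatError(SlideProteoError):
    """Malformed input file (missing columns, bad GMT line, ...)."""


class SampleLookupError(SlideProteoError, KeyError):
    """Requested sample is absent from a table or matrix."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return SlideProteoError.__str__(self)


class InsufficientDataError(SlideProteoError):
    """Too few observations for the requested statistic."""


class CalibrationError(SlideProteoError):
    """Standard curve is unusable (non-monotone, no root, ...)."""


class UndefinedMetricError(SlideProteoError):
    """Metric undefined for this input (zero total signal, constant data)."""


class NormalizationError(SlideProteoError):
    """A sample cannot be normalized (no positive values)."""


class DefinitionError(SlideProteoError):
    """A signature/complex definition cannot be applied to the matrix."""
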