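"""Exception hierarchy for langmap."""


class LangmapError(Exception):
    """Base class for all langmap-specific errors."""


class DegenerateRoiError(LangmapError):
    """Thresholding a network weight map produced an empty or merged ROI."""


class UndefinedCorrelationError(LangmapError):
    """Correlation requested against a constant (zero-variance) seed series."""


class FormatError(LangmapError):
    """A file could not be parsed in the expected format."""


class NumericalDegeneracyError(LangmapError):
    """A variance estimate degenerated to zero where a nonzero one is required."""
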