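"""Exception hierarchy for patternkit.

All domain errors derive from :class:`PatternKitError` so callers can catch
one base class; per-stage subclasses let pipelines report *why* a selection
failed (no period found, too few repeats, dead channel, ...).
"""


class PatternKitError(Exception):
    """Base class for all patternkit domain errors."""


class FormatError(PatternKitError):
    """Input file exists but its layout is not supported."""


class ParameterError(PatternKitError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateProfileError(PatternKitError):
    """Profile is constant: normalization (min=0, max=1) is undefined."""


class BoundsError(PatternKitError):
    """Selection (including its linewidth) leaves the image bounds."""


class EmptyResultError(PatternKitError):
    """An import or pooling step produced nothing usable."""


class NoPeriodError(PatternKitError):
    """Autocorrelation shows no secondary maximum: aperiodic input."""


class SegmentationError(PatternKitError):
    """Profile cannot be segmented into repeats (too short / too few)."""


class TooFewPatternsError(SegmentationError):
    """Fewer than two pattern repeats were found."""
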