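"""Exception hierarchy shared across the package."""


class RetmorphError(Exception):
    """Base class for all retmorph-specific errors."""


class FormatError(RetmorphError):
    """Unreadable or malformed input file."""


class AnnotationError(RetmorphError):
    """Invalid segment annotation (bad column, class, or coordinate)."""


class ParameterError(RetmorphError):
    """Parameter outside its documented domain."""


class SnapError(RetmorphError):
    """No skeleton pixel within the snapping radius of an endpoint."""


class NoPathError(RetmorphError):
    """Segment endpoints lie on disconnected skeleton components."""


class ContractError(RetmorphError):
    """A documented precondition was violated by the caller."""


class DiscDetectionError(RetmorphError):
    """Automatic optic-disc detection failed; manual ROI placement needed."""


class DegenerateDataError(RetmorphError):
    """Statistical routine received degenerate input (e.g. all-equal values)."""


class EmptySegmentationWarning(UserWarning):
    """Binarization produced an empty foreground."""


class QualityWarning(UserWarning):
    """A quality check (fit r², ROI clipping, curve fallback) was triggered."""
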