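"""Exception hierarchy shared across the pipeline stages."""


class RetperfError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RetperfError, ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class InvalidInputError(RetperfError, ValueError):
    """Input data violates a documented invariant (e.g. negative thickness)."""


class NoVesselError(RetperfError):
    """An intensity profile has no dip distinguishable from background noise."""


class AmbiguousProfileError(RetperfError):
    """A profile shows multiple substantial dips; the caliper cannot choose."""


class OutOfBoundsError(RetperfError):
    """A sampling window leaves the image raster."""


class EmptyAccountingError(RetperfError):
    """Flow aggregation was asked to run with no crossings at all."""


class InsufficientDataError(RetperfError, ValueError):
    """A statistical routine received fewer observations than it needs."""


class UndefinedCorrelationError(RetperfError):
    """Rank correlation on a constant vector is undefined."""


class DegenerateTableError(RetperfError, ValueError):
    """A contingency table has a zero margin."""


class InvalidGeometryError(RetperfError, ValueError):
    """Requested geometry does not fit the available raster extent."""


class InvalidSegmentationError(RetperfError, ValueError):
    """OCT boundary surfaces violate their depth ordering."""


class PipelineError(RetperfError):
    """A stage failed inside the orchestrated run; names stage and subject."""
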