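"""Exception types raised across the pipeline.

All are subclasses of :class:`PolarCellError` so callers can catch the
package's failures with a single except clause while batch-processing.
"""


class PolarCellError(Exception):
    """Base class for all polarcell errors."""


class InvalidSpec(PolarCellError):
    """A synthetic cell/pair specification violates its invariants."""


class EmptyCohort(PolarCellError):
    """A cohort of zero cells/pairs was requested."""


class EmptyInput(PolarCellError):
    """An operation received an empty image stack or value vector."""


class NoCellFound(PolarCellError):
    """Segmentation found no connected component above the minimum area."""


class NoBackgroundRegion(PolarCellError):
    """The cell mask covers the whole frame; background cannot be estimated."""


class DegenerateMask(PolarCellError):
    """Mask too small (< 3 px) for moments/orientation to be meaningful."""


class UndefinedDirection(PolarCellError):
    """Cluster direction requested for a channel with no surviving clusters."""


class UndefinedAngle(PolarCellError):
    """Polarization angle requested when either channel is nonpolar."""


class NotAPair(PolarCellError):
    """Fewer than two qualifying components in a paired-daughter image."""


class AmbiguousPair(PolarCellError):
    """More than two components above the minimum area in a doublet image."""


class UndefinedRatio(PolarCellError):
    """Sister ratio undefined because one daughter has zero total signal."""


class InsufficientReplicates(PolarCellError):
    """A t test needs at least two replicates per group."""


class LabelError(PolarCellError):
    """A call carries an unknown condition/replicate label."""
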