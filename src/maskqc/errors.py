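"""Exception hierarchy for maskqc.

Every error raised deliberately by the package derives from :class:`MaskQCError`
so callers (and the CLI) can distinguish configuration problems (exit code 2)
from data problems (exit code 3).
"""


class MaskQCError(Exception):
    """Base class for all maskqc errors."""


class ConfigError(MaskQCError):
    """Invalid parameter, feature list, or mismatched model/vector layout."""


class DataError(MaskQCError):
    """Base class for errors caused by the input data rather than the caller."""


class EmptyMaskError(DataError):
    """A mask with no foreground voxels where foreground is required."""


class GridMismatchError(DataError):
    """Two masks compared on different grids (shape or spacing)."""


class InsufficientDataError(DataError):
    """Too few samples to fit or summarize (scaler, baseline, confusion table)."""


class DegenerateClusteringError(DataError):
    """Clustering cannot proceed: too few or near-identical feature vectors."""
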