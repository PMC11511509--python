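"""Exception hierarchy.

Data-quality problems (bad files, occlusions, failed sync) are distinguished
from configuration problems so the CLI can map them to different exit codes.
"""


class SpinekinError(Exception):
    """Base class for all package errors."""


class ConfigError(SpinekinError):
    """Invalid or inconsistent configuration."""


class DataError(SpinekinError):
    """Base class for data-quality problems."""


class InvalidInputError(DataError):
    """Numerically invalid input (zero-norm quaternion, non-finite values)."""


class DegenerateFrameError(DataError):
    """Axes collinear / rank-deficient: no right-handed frame can be built."""


class MissingFrameError(DataError):
    """A marker-cluster frame cannot be used (occluded marker)."""


class MissingDataError(DataError):
    """A whole window or stream is unavailable."""


class NotStaticError(DataError):
    """A window assumed static contains motion above threshold."""


class CalibrationTooSmallError(DataError):
    """Functional-alignment repetition has insufficient angular excursion."""


class InsufficientStaticError(DataError):
    """Trial too short to supply the static normalization frames."""


class SegmentationFailureError(DataError):
    """Repetition segmentation found too few distinct repetitions."""


class TooFewRepetitionsError(DataError):
    """Fewer than the minimum usable repetitions for a segment movement."""


class SyncFailureError(DataError):
    """No stomp acceleration peak found for time synchronization."""


class AmbiguousSyncError(DataError):
    """Multiple comparable acceleration peaks; stomp cannot be identified."""


class DataFormatError(DataError):
    """Malformed input file (bad header, bad row, timestamp regression)."""
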