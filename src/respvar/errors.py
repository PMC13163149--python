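"""Exception hierarchy for the respvar pipeline.

Every stage raises a subclass of :class:`RespvarError`, so callers can
catch pipeline failures without masking programming errors.
"""


class RespvarError(Exception):
    """Base class for all respvar errors."""


class ParameterError(RespvarError, ValueError):
    """An operation was called with an invalid parameter value."""


class RecordingFormatError(RespvarError, ValueError):
    """A recording file does not conform to the ``time,ax,ay,az`` contract."""


class TooShortError(RespvarError, ValueError):
    """A recording or breath table is shorter than the requested window."""


class SegmentationError(RespvarError, RuntimeError):
    """Breath segmentation failed (e.g. no extrema found)."""


class UndefinedMetricError(RespvarError, ValueError):
    """A variability metric is undefined for the given series (e.g. CV at mean 0)."""


class ProfileError(RespvarError, ValueError):
    """An RV profile cannot be computed (too few breaths)."""


class AdjustmentError(RespvarError, RuntimeError):
    """Confounder adjustment failed for a metric (e.g. rank-deficient design)."""


class InsufficientDataError(RespvarError, ValueError):
    """Not enough labelled subjects to build a model matrix."""


class StratificationError(RespvarError, ValueError):
    """A train/validation partition cannot be stratified (single class)."""


class MissingFeatureError(RespvarError, KeyError):
    """A prediction was requested without all required feature values."""


class StageError(RespvarError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
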