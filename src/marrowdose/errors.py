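"""Exception hierarchy for the marrowdose pipeline.

Every stage raises a subclass of :class:`MarrowDoseError` so the CLI can
surface the failing stage and offending input without a traceback.
"""


class MarrowDoseError(Exception):
    """Base class for all marrowdose errors."""


class ParameterError(MarrowDoseError):
    """A configuration parameter is outside its valid range."""


class SchemaError(MarrowDoseError):
    """An image sidecar or config file is missing a required field."""


class PairingError(MarrowDoseError):
    """Anterior/posterior images cannot be combined (shape/time mismatch)."""


class CalibrationError(MarrowDoseError):
    """Calibration series is invalid or the mono-exponential fit failed."""


class SegmentationError(MarrowDoseError):
    """Whole-body or compartment segmentation failed."""


class GeometryError(MarrowDoseError):
    """Patient geometry is inconsistent (non-positive thickness, mass overflow)."""


class KineticsError(MarrowDoseError):
    """Time-activity curve fitting failed beyond all fallbacks."""


class DegenerateInputError(MarrowDoseError):
    """Statistical input has zero variance or is otherwise degenerate."""


class PipelineError(MarrowDoseError):
    """A multi-stage run cannot proceed (too few usable time points, ...)."""
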