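"""Exception hierarchy for the echolv pipeline.

Frame-level segmentation problems are recoverable (the sequence driver flags
the frame and continues); everything else aborts the operation that raised it.
"""


class EcholvError(Exception):
    """Base class for all echolv errors."""


class ValidationError(EcholvError, ValueError):
    """Input violates a documented precondition or type invariant."""


class FormatError(EcholvError, ValueError):
    """A file on disk does not conform to the expected format."""


class ConfigurationError(EcholvError, ValueError):
    """Missing or inconsistent configuration/metadata."""


class SegmentationError(EcholvError, RuntimeError):
    """A frame could not be segmented (leakage, empty cavity, ...)."""


class TrackingError(EcholvError, RuntimeError):
    """The adaptive barrier could not be updated from the previous frame."""


class UndefinedMetricError(EcholvError, ValueError):
    """An agreement metric is undefined for the given inputs (e.g. zero variance)."""
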