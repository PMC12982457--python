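"""Exception hierarchy for parkfuse."""


class ParkfuseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ParkfuseError):
    """Invalid configuration or hyperparameter."""


class SizingError(ParkfuseError):
    """Requested spiral does not fit the image canvas."""


class EmptyRecordingError(ParkfuseError):
    """A generator or segmenter received / would produce an empty signal."""


class AliasingError(ParkfuseError):
    """Fundamental frequency at or above Nyquist."""


class CohortOverlapError(ParkfuseError):
    """Subject ids overlap across modality cohorts."""


class TraceError(ParkfuseError):
    """Stroke trace extraction failed (blank or disconnected stroke)."""


class DivergenceError(ParkfuseError):
    """Training produced a non-finite loss."""


class DegenerateClusteringError(ParkfuseError):
    """Clustering input admits no valid silhouette (e.g. identical points)."""


class LeakageError(ParkfuseError):
    """A transform fitted on one partition was applied inconsistently."""
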