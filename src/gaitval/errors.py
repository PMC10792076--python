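"""Exception hierarchy.

Data-quality problems (bad signals, failed detections) and configuration
problems (infeasible parameters) are kept distinct so that callers — and the
command line, which maps them to exit codes 1 and 2 — can tell them apart.
"""


class GaitvalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitvalError):
    """Infeasible or inconsistent configuration (bad ranges, bad filter spec...)."""


class DataError(GaitvalError):
    """Malformed or degenerate input data."""


class EventDetectionError(DataError):
    """No usable gait events could be detected in a signal."""


class MissingMarkerError(DataError):
    """A required marker trajectory is absent from a recording."""

    def __init__(self, marker: str):
        self.marker = marker
        super().__init__(f"required marker {marker!r} is missing")


class CapabilityError(GaitvalError):
    """The requested quantity is not computable from this data source.

    Raised e.g. when step length is requested from the single-camera 2D path:
    the contralateral heel strike cannot be identified from one sagittal
    camera, so contralateral-dependent parameters are refused rather than
    silently approximated.
    """


class UndefinedStatisticError(GaitvalError):
    """A statistic is mathematically undefined for this input (e.g. ICC with
    zero between-subject variance). Surfaced as an error, never a silent 0."""
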