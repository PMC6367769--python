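"""Exception hierarchy.

Validation problems (bad files, bad configuration) are kept distinct from
numeric/geometric failures so the CLI can map them to different exit codes.
"""


class CprKinematError(Exception):
    """Base class for all package errors."""


class ValidationError(CprKinematError, ValueError):
    """Malformed input: bad file, bad column, bad configuration value."""


class GeometryError(CprKinematError, ValueError):
    """The configured body chain cannot reach the floor and the chest."""


class SynchronizationError(CprKinematError, RuntimeError):
    """The two measurement streams do not co-vary; no lag can be estimated."""


class DegenerateTrajectoryError(CprKinematError, ValueError):
    """A trajectory is too short or rank-deficient for an ellipse fit."""
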