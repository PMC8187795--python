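"""Exception hierarchy shared across camfuse modules."""


class CamfuseError(Exception):
    """Base class for all camfuse errors."""


class DegenerateProjectionError(CamfuseError):
    """A point maps to the plane at infinity (projective denominator ~ 0)."""


class DegenerateGeometryError(CamfuseError):
    """A point configuration is rank-deficient (e.g. collinear correspondences)."""


class SingularMatrixError(CamfuseError):
    """A homography matrix is singular and cannot be inverted or normalized."""


class NoRuleFiredError(CamfuseError):
    """No fuzzy rule produced a nonzero activation; the aggregate is identically zero."""


class NoDetectionError(CamfuseError):
    """A camera contributed no detections to a frame."""


class ConfigError(CamfuseError):
    """A configuration file or object violates its invariants."""
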