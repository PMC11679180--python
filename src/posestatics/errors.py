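"""Exception hierarchy for the analysis pipeline."""


class PoseStaticsError(Exception):
    """Base class for all package errors."""


class ValidationError(PoseStaticsError, ValueError):
    """Invalid parameter value or violated type invariant."""


class ParseError(PoseStaticsError):
    """Malformed keypoint or configuration file."""


class InsufficientKeypointsError(PoseStaticsError):
    """A required keypoint is missing or below the confidence threshold."""


class NoSupportError(PoseStaticsError):
    """No foot is in contact with the ground."""


class DegenerateSegmentError(PoseStaticsError):
    """Segment endpoints coincide; no axis can be defined."""


class DegenerateStanceError(PoseStaticsError):
    """Both ground contacts share the same x-coordinate."""


class OutOfBaseError(PoseStaticsError):
    """Centre of mass lies outside the base of support; no static solution
    exists with unilateral (push-only) ground contact."""


class InfeasibleSceneError(PoseStaticsError):
    """Requested synthetic scene parameters have no plausible geometry."""


class WiringError(PoseStaticsError):
    """Free bodies or joint loads from different limbs were chained."""
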