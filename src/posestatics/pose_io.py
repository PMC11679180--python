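"""Reading BODY_25 keypoint files and calibrating them to the world frame.

The world frame is metric: x along the facing direction, y up, ground at
y = 0.  Keypoint files store pixel coordinates with a y-down axis, as
emitted by common markerless pose estimators (25 keypoints per person,
flat x/y/confidence triplets).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np

from .anthropometry import AnthropometricModel
from .errors import (
    DegenerateSegmentError,
    InsufficientKeypointsError,
    NoSupportError,
    ParseError,
    ValidationError,
)
from .geometry import Point2, as_point

logger = logging.getLogger(__name__)

# BODY_25 keypoint indices (0-based)
NOSE = 0
NECK = 1
MID_HIP = 8
R_HIP, R_KNEE, R_ANKLE = 9, 10, 11
L_HIP, L_KNEE, L_ANKLE = 12, 13, 14
L_BIG_TOE, L_HEEL = 19, 21
R_BIG_TOE, R_HEEL = 22, 24

N_KEYPOINTS = 25

#: per-side (hip, knee, ankle, toe, heel) index tuples
RIGHT_LEG = (R_HIP, R_KNEE, R_ANKLE, R_BIG_TOE, R_HEEL)
LEFT_LEG = (L_HIP, L_KNEE, L_ANKLE, L_BIG_TOE, L_HEEL)


@dataclass(frozen=True)
class RawPose:
    """One person's uncalibrated keypoints in pixel coordinates (y down)."""

    keypoints: np.ndarray  # (25, 3): x, y, confidence
    source_id: str = ""

    def __post_init__(self):
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValidationError(
                f"expected ({N_KEYPOINTS}, 3) keypoints, got {kp.shape}"
            )
        conf = kp[:, 2]
        if np.any(conf < 0) or np.any(conf > 1):
            raise ValidationError("confidences must lie in [0, 1]")
        object.__setattr__(self, "keypoints", kp)

    def point(self, index: int) -> Point2:
        return self.keypoints[index, :2].copy()

    def confidence(self, index: int) -> float:
        return float(self.keypoints[index, 2])

    @property
    def mean_confidence(self) -> float:
        return float(self.keypoints[:, 2].mean())


@dataclass(frozen=True)
class Leg:
    """Calibrated metric keypoints of one lower limb."""

    hip: Point2
    knee: Point2
    ankle: Point2
    heel: Point2
    toe: Point2

    def __post_init__(self):
        for name in ("hip", "knee", "ankle", "heel", "toe"):
            object.__setattr__(self, name, as_point(getattr(self, name)))
        for a, b in (("hip", "knee"), ("knee", "ankle"), ("ankle", "toe")):
            if np.allclose(getattr(self, a), getattr(self, b), atol=1e-12):
                raise DegenerateSegmentError(f"{a} and {b} coincide")

    def foot_extent_x(self) -> tuple:
        xs = (self.heel[0], self.toe[0])
        return (min(xs), max(xs))

    def translated(self, v) -> "Leg":
        v = as_point(v)
        return Leg(*(getattr(self, n) + v for n in ("hip", "knee", "ankle", "heel", "toe")))


SUPPORT_STATES = ("double", "single_hind", "single_front")


@dataclass(frozen=True)
class Posture:
    """Calibrated sagittal posture: both legs, HAT anchor, support state."""

    hind: Leg
    front: Leg
    trunk_anchor: Point2
    support_state: str
    facing_sign: int = 1

    def __post_init__(self):
        object.__setattr__(self, "trunk_anchor", as_point(self.trunk_anchor))
        if self.support_state not in SUPPORT_STATES:
            raise ValidationError(f"unknown support_state {self.support_state!r}")
        if self.facing_sign not in (1, -1):
            raise ValidationError("facing_sign must be +1 or -1")

    def leg(self, side: str) -> Leg:
        if side == "hind":
            return self.hind
        if side == "front":
            return self.front
        raise KeyError(f"unknown side {side!r}")

    def grounded_sides(self) -> tuple:
        if self.support_state == "double":
            return ("hind", "front")
        return ("hind",) if self.support_state == "single_hind" else ("front",)


@dataclass(frozen=True)
class CalibrationConfig:
    """Pixel-to-world calibration options."""

    min_confidence: float = 0.3
    ground_tolerance_m: float = 0.02
    scale_m_per_px: Optional[float] = None  # None: estimate from shank length
    facing_sign: int = 1
    force_support: str = "auto"  # auto | double | single_hind | single_front

    def __post_init__(self):
        if self.force_support not in ("auto",) + SUPPORT_STATES:
            raise ValidationError(f"unknown force_support {self.force_support!r}")


def read_pose_file(path) -> List[RawPose]:
    """Read a BODY_25 keypoint JSON file; one RawPose per detected person.

    A file with zero people yields an empty list, not an error.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except FileNotFoundError:
        raise
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse pose file {path}: {exc}") from exc
    if not isinstance(data, dict) or "people" not in data:
        raise ParseError(f"pose file {path} lacks a 'people' array")
    poses = []
    for i, person in enumerate(data["people"]):
        flat = person.get("pose_keypoints_2d")
        if flat is None:
            raise ParseError(f"person {i} lacks 'pose_keypoints_2d'")
        flat = np.asarray(flat, dtype=float)
        if flat.size != N_KEYPOINTS * 3:
            raise ParseError(
                f"person {i}: expected {N_KEYPOINTS * 3} numbers, got {flat.size}"
            )
        poses.append(
            RawPose(keypoints=flat.reshape(N_KEYPOINTS, 3), source_id=f"{path.name}#{i}")
        )
    return poses


def select_person(poses: List[RawPose]) -> RawPose:
    """Pick the person with the highest mean keypoint confidence."""
    if not poses:
        raise InsufficientKeypointsError("no people detected in pose file")
    best = max(poses, key=lambda p: p.mean_confidence)
    if len(poses) > 1:
        logger.info(
            "selected %s (mean confidence %.3f) among %d people",
            best.source_id, best.mean_confidence, len(poses),
        )
    return best


def estimate_scale(raw: RawPose, model: AnthropometricModel) -> float:
    """Meters per pixel from the knee-ankle distance of each valid leg.

    Averages over the legs whose knee and ankle confidences are non-zero.
    """
    shank_len = model.segment("shank").length
    scales = []
    for knee, ankle in ((R_KNEE, R_ANKLE), (L_KNEE, L_ANKLE)):
        if raw.confidence(knee) > 0 and raw.confidence(ankle) > 0:
            dist = float(np.linalg.norm(raw.point(knee) - raw.point(ankle)))
            if dist <= 1e-12:
                raise DegenerateSegmentError("knee and ankle keypoints coincide")
            scales.append(shank_len / dist)
    if not scales:
        raise InsufficientKeypointsError("no leg with valid knee and ankle keypoints")
    return float(np.mean(scales))


def _require(raw: RawPose, indices, min_confidence: float):
    missing = [i for i in indices if raw.confidence(i) < min_confidence]
    if missing:
        raise InsufficientKeypointsError(
            f"keypoints {missing} below confidence {min_confidence}"
        )


def calibrate(
    raw: RawPose,
    model: AnthropometricModel,
    config: CalibrationConfig = CalibrationConfig(),
) -> Posture:
    """Convert pixel keypoints into a metric, y-up, ground-at-zero Posture.

    Applies a single isotropic scale (estimated from shank length unless
    overridden), flips the y axis, shifts the ground line so the lowest
    foot contact point maps to y = 0, labels legs hind/front by x-order
    against ``facing_sign``, and infers the support state (a foot is
    grounded when both heel and toe lie within ``ground_tolerance_m`` of
    the ground line).
    """
    required = list(RIGHT_LEG) + list(LEFT_LEG)
    _require(raw, required, config.min_confidence)

    scale = config.scale_m_per_px
    if scale is None:
        scale = estimate_scale(raw, model)
    if not scale > 0:
        raise ValidationError("scale must be > 0")

    def world(idx: int) -> Point2:
        p = raw.point(idx)
        return np.array([p[0] * scale, -p[1] * scale])

    legs = {}
    for label, (hip, knee, ankle, toe, heel) in (
        ("right", RIGHT_LEG),
        ("left", LEFT_LEG),
    ):
        legs[label] = Leg(
            hip=world(hip), knee=world(knee), ankle=world(ankle),
            heel=world(heel), toe=world(toe),
        )

    # ground line: lowest heel/toe point across both feet
    ground = min(
        min(leg.heel[1], leg.toe[1]) for leg in legs.values()
    )
    shift = np.array([0.0, -ground])
    legs = {k: leg.translated(shift) for k, leg in legs.items()}

    # HAT anchor: midpoint of neck and mid-hip, with graceful fallbacks
    if raw.confidence(MID_HIP) >= config.min_confidence:
        mid_hip = world(MID_HIP) + shift
    else:
        mid_hip = 0.5 * (legs["right"].hip + legs["left"].hip)
    if raw.confidence(NECK) >= config.min_confidence:
        neck = world(NECK) + shift
        trunk_anchor = 0.5 * (neck + mid_hip)
    else:
        trunk_anchor = mid_hip + np.array([0.0, 0.25 * model.stature])
        logger.info("neck keypoint missing; trunk anchor placed above mid-hip")

    # hind/front assignment: hind is behind along the facing direction
    sign = config.facing_sign
    if sign * legs["right"].ankle[0] <= sign * legs["left"].ankle[0]:
        hind, front = legs["right"], legs["left"]
    else:
        hind, front = legs["left"], legs["right"]

    tol = config.ground_tolerance_m

    def grounded(leg: Leg) -> bool:
        return abs(leg.heel[1]) <= tol and abs(leg.toe[1]) <= tol

    if config.force_support != "auto":
        support = config.force_support
        # tolerate small foot-height discrepancies, but a clearly airborne
        # foot cannot be declared grounded
        airborne_limit = max(10.0 * tol, 0.1)
        need = {"double": ("hind", "front"), "single_hind": ("hind",),
                "single_front": ("front",)}[support]
        for name, leg in (("hind", hind), ("front", front)):
            if name in need and min(leg.heel[1], leg.toe[1]) > airborne_limit:
                raise NoSupportError(
                    f"{name} foot is {min(leg.heel[1], leg.toe[1]):.2f} m off "
                    f"the ground; cannot force support_state={support!r}"
                )
    else:
        g_hind, g_front = grounded(hind), grounded(front)
        if g_hind and g_front:
            support = "double"
        elif g_hind:
            support = "single_hind"
        elif g_front:
            support = "single_front"
        else:
            raise NoSupportError("both feet are off the ground")

    return Posture(
        hind=hind, front=front, trunk_anchor=trunk_anchor,
        support_state=support, facing_sign=sign,
    )
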