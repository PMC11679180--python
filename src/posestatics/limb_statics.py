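"""Distal-to-proximal free-body recursion: joint loads at ankle, knee, hip.

Each lower-limb segment is isolated as a rigid free body.  Solving the
foot yields the ankle load; the ankle load re-enters the shank negated
(action-reaction), whose balance yields the knee load; likewise thigh ->
hip.  A ``JointLoad`` holds the force and scalar moment the proximal
segment exerts on the *distal* segment at the joint, in the world frame,
moments CCW-positive.

Every balance is written as "net force and net moment of all loads on the
free body equal zero", with moments taken about the segment CoM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .anthropometry import AnthropometricModel, segment_com_point, segment_weight
from .errors import ValidationError, WiringError
from .geometry import Point2, as_point, cross2
from .grf_solver import GroundContact
from .pose_io import Posture

JOINTS = ("ankle", "knee", "hip")


@dataclass(frozen=True)
class JointLoad:
    """Force and moment on the distal segment at one joint."""

    joint: str
    force: Point2  # (Fx, Fy), N
    moment: float  # N m, CCW-positive
    side: str = ""

    def __post_init__(self):
        if self.joint not in JOINTS:
            raise ValidationError(f"unknown joint {self.joint!r}")
        object.__setattr__(self, "force", as_point(self.force))
        if not (np.all(np.isfinite(self.force)) and np.isfinite(self.moment)):
            raise ValidationError(f"{self.joint}: non-finite joint load")


@dataclass(frozen=True)
class SegmentFreeBody:
    """One isolated segment with its geometry, weight, and external load."""

    name: str  # foot | shank | thigh
    proximal_joint: Point2
    distal_joint: Point2
    com: Point2
    weight: float  # N, acting at com, downward
    external: Optional[GroundContact] = None
    side: str = ""

    def __post_init__(self):
        for attr in ("proximal_joint", "distal_joint", "com"):
            object.__setattr__(self, attr, as_point(getattr(self, attr)))
        if self.weight < 0:
            raise ValidationError(f"{self.name}: weight must be >= 0")


@dataclass(frozen=True)
class LimbSolution:
    """Joint loads of one limb, distal to proximal, plus residuals."""

    side: str
    ankle: JointLoad
    knee: JointLoad
    hip: JointLoad
    equilibrium_residuals: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def load(self, joint: str) -> JointLoad:
        return getattr(self, joint)


def _weight_vec(fb: SegmentFreeBody) -> np.ndarray:
    return np.array([0.0, -fb.weight])


def _segment_residual(loads, moments, about) -> Tuple[float, float]:
    """Net |force| and |moment| of a load set — internal sanity check."""
    f = np.zeros(2)
    m = 0.0
    for force, point in loads:
        f += force
        m += cross2(np.asarray(point) - about, force)
    m += sum(moments)
    return float(np.linalg.norm(f)), abs(m)


def solve_foot(fb: SegmentFreeBody) -> JointLoad:
    """Balance the foot: GRF (if grounded) + weight + ankle load = 0."""
    ext_f = fb.external.grf if fb.external is not None else np.zeros(2)
    w = _weight_vec(fb)
    force = -(ext_f + w)
    # moment about the foot CoM; weight has zero arm there
    moment = -cross2(fb.proximal_joint - fb.com, force)
    if fb.external is not None:
        moment -= cross2(fb.external.point - fb.com, ext_f)
    return JointLoad(joint="ankle", force=force, moment=moment, side=fb.side)


def _solve_proximal(
    fb: SegmentFreeBody, distal_load: JointLoad, joint: str
) -> JointLoad:
    """Shared shank/thigh balance: distal load enters negated."""
    if distal_load.side and fb.side and distal_load.side != fb.side:
        raise WiringError(
            f"{joint}: free body is {fb.side!r} but distal load is {distal_load.side!r}"
        )
    w = _weight_vec(fb)
    force = distal_load.force - w  # F_prox - F_distal - W = 0
    moment = (
        distal_load.moment
        - cross2(fb.proximal_joint - fb.com, force)
        + cross2(fb.distal_joint - fb.com, distal_load.force)
    )
    return JointLoad(joint=joint, force=force, moment=moment, side=fb.side)


def solve_shank(fb: SegmentFreeBody, ankle_load: JointLoad) -> JointLoad:
    if ankle_load.joint != "ankle":
        raise WiringError("solve_shank expects an ankle load")
    return _solve_proximal(fb, ankle_load, "knee")


def solve_thigh(fb: SegmentFreeBody, knee_load: JointLoad) -> JointLoad:
    if knee_load.joint != "knee":
        raise WiringError("solve_thigh expects a knee load")
    return _solve_proximal(fb, knee_load, "hip")


def build_free_bodies(
    posture: Posture,
    side: str,
    grf: Optional[GroundContact],
    model: AnthropometricModel,
) -> Dict[str, SegmentFreeBody]:
    """Assemble foot/shank/thigh free bodies for one limb.

    Segment axes (proximal -> distal): foot ankle->toe, shank knee->ankle,
    thigh hip->knee.  The heel enters only the contact geometry.
    """
    leg = posture.leg(side)
    axes = {
        "foot": (leg.ankle, leg.toe),
        "shank": (leg.knee, leg.ankle),
        "thigh": (leg.hip, leg.knee),
    }
    bodies = {}
    for name, (proximal, distal) in axes.items():
        spec = model.segment(name)
        bodies[name] = SegmentFreeBody(
            name=name,
            proximal_joint=proximal,
            distal_joint=distal,
            com=segment_com_point(proximal, distal, spec.com_fraction),
            weight=segment_weight(model, name),
            external=grf if name == "foot" else None,
            side=side,
        )
    return bodies


def solve_limb(
    posture: Posture,
    side: str,
    grf: Optional[GroundContact],
    model: AnthropometricModel,
) -> LimbSolution:
    """Chain foot -> shank -> thigh and report equilibrium residuals."""
    grounded = side in posture.grounded_sides()
    if grounded and grf is None:
        raise ValidationError(f"{side} leg is grounded but no GRF was supplied")
    if not grounded and grf is not None:
        raise ValidationError(f"{side} leg is a swing leg but a GRF was supplied")

    fbs = build_free_bodies(posture, side, grf, model)
    ankle = solve_foot(fbs["foot"])
    knee = solve_shank(fbs["shank"], ankle)
    hip = solve_thigh(fbs["thigh"], knee)

    residuals = {}
    foot = fbs["foot"]
    loads = [(ankle.force, foot.proximal_joint), (_weight_vec(foot), foot.com)]
    if foot.external is not None:
        loads.append((foot.external.grf, foot.external.point))
    residuals["foot"] = _segment_residual(loads, [ankle.moment], foot.com)

    for name, distal_load, prox_load in (
        ("shank", ankle, knee),
        ("thigh", knee, hip),
    ):
        fb = fbs[name]
        loads = [
            (prox_load.force, fb.proximal_joint),
            (-distal_load.force, fb.distal_joint),
            (_weight_vec(fb), fb.com),
        ]
        residuals[name] = _segment_residual(
            loads, [prox_load.moment, -distal_load.moment], fb.com
        )

    return LimbSolution(
        side=side, ankle=ankle, knee=knee, hip=hip,
        equilibrium_residuals=residuals,
    )
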