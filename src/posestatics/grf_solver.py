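"""Whole-body static equilibrium: per-foot ground reaction forces.

Double support splits the body weight between the two contacts by the
lever arms of the CoM; friction loads the feet with equal and opposite
horizontal components (Coulomb, coefficient ``model.friction_coefficient``).
Single support places the centre of pressure directly under the CoM and
carries the full body weight with no net horizontal force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .anthropometry import AnthropometricModel
from .com_model import ComResult
from .errors import (
    DegenerateStanceError,
    OutOfBaseError,
    ValidationError,
)
from .geometry import Point2, as_point
from .pose_io import Leg, Posture

CONTACT_MODES = ("heel", "midfoot", "toe")


@dataclass(frozen=True)
class GroundContact:
    """A foot-ground contact point (y = 0) and the GRF acting there."""

    point: Point2
    grf: Point2  # (GRFx, GRFy), N

    def __post_init__(self):
        object.__setattr__(self, "point", as_point(self.point))
        object.__setattr__(self, "grf", as_point(self.grf))
        if abs(self.point[1]) > 1e-6:
            raise ValidationError("contact point must lie on the ground (y = 0)")
        if self.grf[1] < -1e-12:
            raise ValidationError("vertical GRF must be non-negative")


@dataclass(frozen=True)
class GRFSolution:
    """Per-foot ground reactions plus the lever-arm bookkeeping."""

    hind: Optional[GroundContact]
    front: Optional[GroundContact]
    L1: float  # |com.x - hind contact x|, m
    L2: float  # |front contact x - com.x|, m
    ptotal: float  # N
    hind_share: float  # hind vertical GRF / ptotal

    def contacts(self):
        out = []
        if self.hind is not None:
            out.append(("hind", self.hind))
        if self.front is not None:
            out.append(("front", self.front))
        return out

    def contact_for(self, side: str) -> Optional[GroundContact]:
        return self.hind if side == "hind" else self.front


def contact_point(leg: Leg, mode: str = "midfoot") -> Point2:
    """Ground contact location for a grounded foot (on the y = 0 line)."""
    if mode not in CONTACT_MODES:
        raise ValidationError(f"unknown contact mode {mode!r}")
    if mode == "heel":
        x = leg.heel[0]
    elif mode == "toe":
        x = leg.toe[0]
    else:
        x = 0.5 * (leg.heel[0] + leg.toe[0])
    return np.array([x, 0.0])


def friction_components(grf_y: float, model: AnthropometricModel, sign: int) -> float:
    """Horizontal (friction) GRF component: sign * Co * grf_y."""
    if grf_y < 0:
        raise ValidationError("vertical GRF must be non-negative")
    if sign not in (1, -1):
        raise ValidationError("sign must be +1 or -1")
    return sign * model.friction_coefficient * grf_y


def solve_double_support(
    posture: Posture,
    com: ComResult,
    model: AnthropometricModel,
    contact: str = "midfoot",
) -> GRFSolution:
    """Split body weight between the two feet by CoM lever arms.

    Moment equilibrium about the front contact gives the hind vertical
    GRF; the front takes the remainder.  Friction puts ``+Co * GRFy`` on
    the hind foot along the facing direction and the mirrored negative on
    the front foot, so the net horizontal force is zero.
    """
    if posture.support_state != "double":
        raise ValidationError("solve_double_support requires double support")
    p_hind = contact_point(posture.hind, contact)
    p_front = contact_point(posture.front, contact)
    x1, x2 = p_hind[0], p_front[0]
    if abs(x2 - x1) < 1e-9:
        raise DegenerateStanceError("hind and front contacts share the same x")
    cx = com.com[0]
    lo, hi = min(x1, x2), max(x1, x2)
    if not lo - 1e-12 <= cx <= hi + 1e-12:
        raise OutOfBaseError(
            f"CoM x = {cx:.4f} m outside the base of support [{lo:.4f}, {hi:.4f}]"
        )

    ptotal = model.ptotal
    L1 = abs(cx - x1)
    L2 = abs(x2 - cx)
    grf_y1 = ptotal * L2 / (L1 + L2)
    grf_y2 = ptotal - grf_y1
    grf_x1 = friction_components(grf_y1, model, +1) * posture.facing_sign
    grf_x2 = -grf_x1

    return GRFSolution(
        hind=GroundContact(p_hind, np.array([grf_x1, grf_y1])),
        front=GroundContact(p_front, np.array([grf_x2, grf_y2])),
        L1=L1, L2=L2, ptotal=ptotal, hind_share=grf_y1 / ptotal,
    )


def solve_single_support(
    posture: Posture,
    com: ComResult,
    model: AnthropometricModel,
    contact: str = "midfoot",
) -> GRFSolution:
    """Full body weight on the stance foot, centre of pressure under the CoM.

    The contact x is set to the CoM x — the only statically admissible
    centre of pressure — and must lie within the stance foot's heel-toe
    extent.  The horizontal GRF is zero (single contact, ΣFx = 0).
    """
    if posture.support_state not in ("single_hind", "single_front"):
        raise ValidationError("solve_single_support requires single support")
    side = "hind" if posture.support_state == "single_hind" else "front"
    leg = posture.leg(side)
    lo, hi = leg.foot_extent_x()
    cx = com.com[0]
    if not lo - 1e-12 <= cx <= hi + 1e-12:
        raise OutOfBaseError(
            f"CoM x = {cx:.4f} m outside the stance foot extent [{lo:.4f}, {hi:.4f}]"
        )
    ptotal = model.ptotal
    stance = GroundContact(np.array([cx, 0.0]), np.array([0.0, ptotal]))
    hind = stance if side == "hind" else None
    front = stance if side == "front" else None
    return GRFSolution(
        hind=hind, front=front,
        L1=0.0, L2=0.0, ptotal=ptotal,
        hind_share=1.0 if side == "hind" else 0.0,
    )


def solve_grf(
    posture: Posture,
    com: ComResult,
    model: AnthropometricModel,
    contact: str = "midfoot",
) -> GRFSolution:
    """Dispatch on the posture's support state."""
    if posture.support_state == "double":
        return solve_double_support(posture, com, model, contact)
    return solve_single_support(posture, com, model, contact)
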