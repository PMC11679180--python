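"""Segmental and whole-body centre of mass.

The body is reduced to seven point masses: foot, shank, and thigh of each
leg at their segment CoM locations, plus a single head-arms-trunk lump at
the posture's trunk anchor.  The whole-body CoM is their mass-weighted
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .anthropometry import AnthropometricModel, segment_com_point
from .errors import ValidationError
from .geometry import Point2, as_point
from .pose_io import Leg, Posture


@dataclass(frozen=True)
class MassPoint:
    location: Point2
    mass: float  # kg
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "location", as_point(self.location))
        if not self.mass > 0:
            raise ValidationError(f"mass must be > 0, got {self.mass}")


@dataclass(frozen=True)
class ComResult:
    com: Point2
    total_mass: float
    contributions: List[MassPoint]

    def __post_init__(self):
        object.__setattr__(self, "com", as_point(self.com))


def _leg_mass_points(leg: Leg, model: AnthropometricModel, side: str) -> List[MassPoint]:
    # proximal -> distal axes: foot ankle->toe, shank knee->ankle, thigh hip->knee
    axes = {
        "foot": (leg.ankle, leg.toe),
        "shank": (leg.knee, leg.ankle),
        "thigh": (leg.hip, leg.knee),
    }
    points = []
    for name, (proximal, distal) in axes.items():
        spec = model.segment(name)
        loc = segment_com_point(proximal, distal, spec.com_fraction)
        points.append(
            MassPoint(loc, spec.mass_fraction * model.total_mass, f"{side}_{name}")
        )
    return points


def body_mass_points(posture: Posture, model: AnthropometricModel) -> List[MassPoint]:
    """Seven mass points: both legs' segments plus the HAT lump."""
    points = _leg_mass_points(posture.hind, model, "hind")
    points += _leg_mass_points(posture.front, model, "front")
    points.append(
        MassPoint(
            posture.trunk_anchor,
            model.residual_mass_fraction * model.total_mass,
            "hat",
        )
    )
    return points


def total_com(points: List[MassPoint]) -> ComResult:
    """Mass-weighted mean location of a set of point masses."""
    if not points:
        raise ValidationError("cannot compute CoM of an empty mass-point list")
    masses = np.array([p.mass for p in points])
    locations = np.array([p.location for p in points])
    total = float(masses.sum())
    com = (masses[:, None] * locations).sum(axis=0) / total
    return ComResult(com=com, total_mass=total, contributions=list(points))
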