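"""Independent brute-force equilibrium checks.

This module never calls the solvers: it only sums forces and moments of
already-computed load sets, so it can vouch for (or fail) any solution.
Tolerances are absolute — loads here are O(10^2-10^3) N and O(10^1) N m,
so 1e-8 leaves many orders of margin over float error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .anthropometry import AnthropometricModel, segment_com_point, segment_weight
from .geometry import Point2, as_point, cross2
from .grf_solver import GRFSolution
from .limb_statics import LimbSolution
from .pose_io import Posture

TOL_FORCE = 1e-8  # N
TOL_MOMENT = 1e-8  # N m


@dataclass(frozen=True)
class EquilibriumReport:
    body_id: str
    net_force: Point2
    about: Point2
    net_moment: float
    tol_force: float = TOL_FORCE
    tol_moment: float = TOL_MOMENT

    @property
    def passed(self) -> bool:
        return (
            float(np.linalg.norm(self.net_force)) < self.tol_force
            and abs(self.net_moment) < self.tol_moment
        )


def net_load(
    forces: Iterable[Tuple[Sequence[float], Sequence[float]]],
    moments: Iterable[float],
    about,
) -> Tuple[Point2, float]:
    """Net force and net moment about ``about`` of point forces + couples.

    ``forces`` is an iterable of (force vector, application point) pairs;
    ``moments`` an iterable of free scalar couples.
    """
    about = as_point(about)
    f_net = np.zeros(2)
    m_net = 0.0
    for force, point in forces:
        force = as_point(force)
        f_net += force
        m_net += cross2(as_point(point) - about, force)
    m_net += float(sum(moments))
    return f_net, m_net


def _report(body_id, forces, moments, about) -> EquilibriumReport:
    f, m = net_load(forces, moments, about)
    return EquilibriumReport(body_id=body_id, net_force=f, about=as_point(about),
                             net_moment=m)


def _leg_geometry(posture: Posture, model: AnthropometricModel, side: str):
    """Per-segment (proximal, distal, com, weight) recomputed from scratch."""
    leg = posture.leg(side)
    axes = {
        "foot": (leg.ankle, leg.toe),
        "shank": (leg.knee, leg.ankle),
        "thigh": (leg.hip, leg.knee),
    }
    out = {}
    for name, (proximal, distal) in axes.items():
        spec = model.segment(name)
        out[name] = (
            proximal,
            distal,
            segment_com_point(proximal, distal, spec.com_fraction),
            segment_weight(model, name),
        )
    return out


def check_scene(
    posture: Posture,
    model: AnthropometricModel,
    grf: GRFSolution,
    limbs: Sequence[LimbSolution],
) -> List[EquilibriumReport]:
    """One equilibrium report per solved segment plus one for the whole body.

    Failures are reported (``passed`` False), never raised.
    """
    reports: List[EquilibriumReport] = []

    for limb in limbs:
        geom = _leg_geometry(posture, model, limb.side)
        contact = grf.contact_for(limb.side)
        if limb.side not in posture.grounded_sides():
            contact = None

        # foot: ankle load + weight (+ GRF)
        prox, _, com, weight = geom["foot"]
        forces = [
            (limb.ankle.force, prox),
            ((0.0, -weight), com),
        ]
        if contact is not None:
            forces.append((contact.grf, contact.point))
        reports.append(
            _report(f"{limb.side}_foot", forces, [limb.ankle.moment], com)
        )

        # shank and thigh: proximal load + negated distal load + weight
        for name, distal_pt_joint, distal_load, prox_load in (
            ("shank", "ankle", limb.ankle, limb.knee),
            ("thigh", "knee", limb.knee, limb.hip),
        ):
            prox, dist, com, weight = geom[name]
            forces = [
                (prox_load.force, prox),
                (-distal_load.force, dist),
                ((0.0, -weight), com),
            ]
            reports.append(
                _report(
                    f"{limb.side}_{name}", forces,
                    [prox_load.moment, -distal_load.moment], com,
                )
            )

    # whole body: all ground reactions + total weight at the (recomputed) CoM
    masses, locations = [], []
    for side in ("hind", "front"):
        for _, _, com, weight in _leg_geometry(posture, model, side).values():
            masses.append(weight / model.g)
            locations.append(com)
    masses.append(model.residual_mass_fraction * model.total_mass)
    locations.append(posture.trunk_anchor)
    masses = np.array(masses)
    locations = np.array(locations)
    body_com = (masses[:, None] * locations).sum(axis=0) / masses.sum()

    forces = [((0.0, -model.ptotal), body_com)]
    for _, contact in grf.contacts():
        forces.append((contact.grf, contact.point))
    reports.append(_report("whole_body", forces, [], body_com))
    return reports
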