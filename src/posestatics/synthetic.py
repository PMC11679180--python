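"""Parameterized synthetic sagittal postures with known ground-truth loads.

Two stance families are built by forward/inverse kinematics from the
anthropometric segment lengths:

* ``readiness`` — double support, feet ``stance_width`` apart, hind knee
  flexed, trunk placed so the hind foot carries ``com_bias`` of the body
  weight (solved in closed form from the mass-point system).
* ``kick`` — single support on the hind (stance) leg, swing leg extended
  forward at abdomen height with the heel leading; trunk placed so the
  whole-body CoM sits over the stance midfoot.

Ground-truth joint loads are computed here by an independent formulation
(moment balances taken about each segment's proximal joint, not its CoM)
and verified against the brute-force equilibrium checker before a scene
is returned, so generation is self-validating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .anthropometry import AnthropometricModel, build_model, segment_com_point, segment_weight
from .com_model import body_mass_points, total_com
from .equilibrium import check_scene, net_load
from .errors import InfeasibleSceneError, ValidationError
from .geometry import Point2, cross2
from .grf_solver import GroundContact, GRFSolution, contact_point
from .limb_statics import JointLoad, LimbSolution
from .pose_io import (
    L_ANKLE, L_BIG_TOE, L_HEEL, L_HIP, L_KNEE,
    MID_HIP, N_KEYPOINTS, NECK,
    R_ANKLE, R_BIG_TOE, R_HEEL, R_HIP, R_KNEE,
    Leg, Posture,
)

PRESETS = ("readiness", "kick", "custom")

#: default hind-foot weight share for the readiness preset
DEFAULT_COM_BIAS = 674.5038 / 981.0

_ANKLE_HEIGHT = 0.08
_HEEL_BACKSET = 0.07
_TRUNK_RISE = 0.35  # trunk anchor height above the hip


@dataclass(frozen=True)
class SceneParams:
    preset: str = "readiness"
    stance_width: float = 0.55
    com_bias: float = DEFAULT_COM_BIAS
    joint_angles: Optional[Dict[str, Dict[str, float]]] = None
    seed: int = 0
    noise_sigma: float = 0.0  # px, at the default render scale
    contact: str = "midfoot"

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValidationError(f"unknown preset {self.preset!r}")
        if self.preset == "readiness":
            if not self.stance_width > 0:
                raise ValidationError("stance_width must be > 0")
            if not 0 < self.com_bias < 1:
                raise ValidationError("com_bias must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class SyntheticScene:
    params: SceneParams
    posture: Posture
    model: AnthropometricModel
    truth_grf: GRFSolution
    truth_limbs: Dict[str, LimbSolution]


def _ik_knee(hip: Point2, ankle: Point2, l_thigh: float, l_shank: float,
             bend_sign: int) -> Point2:
    """Two-link inverse kinematics; ``bend_sign`` picks the elbow side."""
    d_vec = ankle - hip
    d = float(np.linalg.norm(d_vec))
    if not abs(l_thigh - l_shank) + 1e-9 < d < l_thigh + l_shank - 1e-9:
        raise InfeasibleSceneError(
            f"hip-ankle distance {d:.3f} m unreachable with thigh {l_thigh} "
            f"and shank {l_shank}"
        )
    u = d_vec / d
    a = (l_thigh**2 - l_shank**2 + d**2) / (2 * d)
    h = math.sqrt(max(l_thigh**2 - a**2, 0.0))
    perp = np.array([-u[1], u[0]])
    return hip + a * u + bend_sign * h * perp


def _flat_foot(ankle_x: float, l_foot: float) -> Leg:
    """Grounded foot geometry (ankle above ground, heel and toe on it)."""
    toe_dx = math.sqrt(l_foot**2 - _ANKLE_HEIGHT**2)
    ankle = np.array([ankle_x, _ANKLE_HEIGHT])
    heel = np.array([ankle_x - _HEEL_BACKSET, 0.0])
    toe = np.array([ankle_x + toe_dx, 0.0])
    return ankle, heel, toe


def _solve_trunk_x(target_com_x: float, legs: Dict[str, Leg],
                   model: AnthropometricModel) -> float:
    """Closed-form HAT x placing the whole-body CoM at ``target_com_x``."""
    leg_sum = 0.0
    for leg in legs.values():
        for name, (proximal, distal) in (
            ("foot", (leg.ankle, leg.toe)),
            ("shank", (leg.knee, leg.ankle)),
            ("thigh", (leg.hip, leg.knee)),
        ):
            spec = model.segment(name)
            com = segment_com_point(proximal, distal, spec.com_fraction)
            leg_sum += spec.mass_fraction * model.total_mass * com[0]
    m_hat = model.residual_mass_fraction * model.total_mass
    x_hat = (target_com_x * model.total_mass - leg_sum) / m_hat

    xs = [p[0] for leg in legs.values()
          for p in (leg.hip, leg.knee, leg.ankle, leg.heel, leg.toe)]
    if not min(xs) - 0.5 <= x_hat <= max(xs) + 0.5:
        raise InfeasibleSceneError(
            f"required trunk x = {x_hat:.3f} m is implausibly far from the body"
        )
    return x_hat


def _readiness_posture(params: SceneParams, model: AnthropometricModel) -> Posture:
    l_foot = model.segment("foot").length
    l_shank = model.segment("shank").length
    l_thigh = model.segment("thigh").length

    hind_ankle, hind_heel, hind_toe = _flat_foot(0.0, l_foot)
    front_ankle, front_heel, front_toe = _flat_foot(params.stance_width, l_foot)

    hip = np.array([0.33 * params.stance_width, 0.85 * (l_shank + l_thigh)])
    hind_knee = _ik_knee(hip, hind_ankle, l_thigh, l_shank, +1)
    front_knee = _ik_knee(hip, front_ankle, l_thigh, l_shank, +1)

    legs = {
        "hind": Leg(hip, hind_knee, hind_ankle, hind_heel, hind_toe),
        "front": Leg(hip, front_knee, front_ankle, front_heel, front_toe),
    }
    x1 = contact_point(legs["hind"], params.contact)[0]
    x2 = contact_point(legs["front"], params.contact)[0]
    target = x1 + (1.0 - params.com_bias) * (x2 - x1)
    trunk = np.array([_solve_trunk_x(target, legs, model), hip[1] + _TRUNK_RISE])
    return Posture(hind=legs["hind"], front=legs["front"], trunk_anchor=trunk,
                   support_state="double", facing_sign=1)


def _kick_posture(params: SceneParams, model: AnthropometricModel) -> Posture:
    l_foot = model.segment("foot").length
    l_shank = model.segment("shank").length
    l_thigh = model.segment("thigh").length

    stance_ankle, stance_heel, stance_toe = _flat_foot(0.0, l_foot)
    hip = np.array([-0.05, 0.80 * (l_shank + l_thigh)])
    stance_knee = _ik_knee(hip, stance_ankle, l_thigh, l_shank, +1)
    stance = Leg(hip, stance_knee, stance_ankle, stance_heel, stance_toe)

    # swing leg: extended forward at abdomen height, dorsiflexed, heel leading
    swing_ankle = hip + np.array([0.77, -0.08])
    swing_knee = _ik_knee(hip, swing_ankle, l_thigh, l_shank, -1)
    ang = math.radians(75.0)
    swing_toe = swing_ankle + l_foot * np.array([math.cos(ang), math.sin(ang)])
    swing_heel = swing_ankle + np.array([0.09, -0.03])
    swing = Leg(hip, swing_knee, swing_ankle, swing_heel, swing_toe)

    legs = {"hind": stance, "front": swing}
    target = contact_point(stance, "midfoot")[0]
    trunk = np.array([_solve_trunk_x(target, legs, model), hip[1] + _TRUNK_RISE])
    return Posture(hind=stance, front=swing, trunk_anchor=trunk,
                   support_state="single_hind", facing_sign=1)


def _dir(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([math.cos(r), math.sin(r)])


def _custom_posture(params: SceneParams, model: AnthropometricModel) -> Posture:
    """Forward kinematics from per-leg hip/knee/ankle angles (degrees).

    Hip angle: thigh direction CCW from straight down (flexion forward
    positive).  Knee angle: flexion (shank rotated clockwise relative to
    the thigh).  Ankle angle: world direction of the ankle->toe axis.
    """
    if not params.joint_angles:
        raise ValidationError("custom preset requires joint_angles")
    l_foot = model.segment("foot").length
    l_shank = model.segment("shank").length
    l_thigh = model.segment("thigh").length
    hip = np.array([0.0, 0.0])
    legs = {}
    for side in ("hind", "front"):
        try:
            ang = params.joint_angles[side]
            th, kn, ak = ang["hip"], ang["knee"], ang["ankle"]
        except KeyError as exc:
            raise ValidationError(f"joint_angles missing entry: {exc}") from exc
        thigh_dir = _dir(-90.0 + th)
        knee = hip + l_thigh * thigh_dir
        shank_dir = _dir(-90.0 + th - kn)
        ankle = knee + l_shank * shank_dir
        toe = ankle + l_foot * _dir(ak)
        heel = ankle + 0.106 * _dir(ak - 110.0)
        legs[side] = Leg(hip, knee, ankle, heel, toe)

    # drop the scene onto the ground and detect support
    ground = min(min(l.heel[1], l.toe[1]) for l in legs.values())
    legs = {k: l.translated((0.0, -ground)) for k, l in legs.items()}
    tol = 0.02
    grounded = {
        k: abs(l.heel[1]) <= tol and abs(l.toe[1]) <= tol for k, l in legs.items()
    }
    if all(grounded.values()):
        support = "double"
    elif grounded["hind"]:
        support = "single_hind"
    elif grounded["front"]:
        support = "single_front"
    else:
        raise InfeasibleSceneError("custom angles leave both feet off the ground")

    if support == "double":
        x1 = contact_point(legs["hind"], params.contact)[0]
        x2 = contact_point(legs["front"], params.contact)[0]
        target = x1 + (1.0 - params.com_bias) * (x2 - x1)
    else:
        stance = legs["hind" if support == "single_hind" else "front"]
        target = contact_point(stance, "midfoot")[0]
    hip_y = legs["hind"].hip[1]
    trunk = np.array([_solve_trunk_x(target, legs, model), hip_y + _TRUNK_RISE])
    return Posture(hind=legs["hind"], front=legs["front"], trunk_anchor=trunk,
                   support_state=support, facing_sign=1)


# ---------------------------------------------------------------------------
# independent ground-truth solve (moment balances about proximal joints)

def _truth_grf(posture: Posture, model: AnthropometricModel,
               contact: str) -> GRFSolution:
    com = total_com(body_mass_points(posture, model)).com
    ptotal = model.ptotal
    if posture.support_state == "double":
        p1 = contact_point(posture.hind, contact)
        p2 = contact_point(posture.front, contact)
        if not min(p1[0], p2[0]) - 1e-12 <= com[0] <= max(p1[0], p2[0]) + 1e-12:
            raise InfeasibleSceneError("scene CoM outside the base of support")
        l1 = abs(com[0] - p1[0])
        l2 = abs(p2[0] - com[0])
        gy1 = ptotal * l2 / (l1 + l2)
        gy2 = ptotal - gy1
        gx1 = model.friction_coefficient * gy1 * posture.facing_sign
        return GRFSolution(
            hind=GroundContact(p1, np.array([gx1, gy1])),
            front=GroundContact(p2, np.array([-gx1, gy2])),
            L1=l1, L2=l2, ptotal=ptotal, hind_share=gy1 / ptotal,
        )
    side = "hind" if posture.support_state == "single_hind" else "front"
    leg = posture.leg(side)
    lo, hi = leg.foot_extent_x()
    if not lo - 1e-12 <= com[0] <= hi + 1e-12:
        raise InfeasibleSceneError("scene CoM outside the stance foot extent")
    stance = GroundContact(np.array([com[0], 0.0]), np.array([0.0, ptotal]))
    return GRFSolution(
        hind=stance if side == "hind" else None,
        front=stance if side == "front" else None,
        L1=0.0, L2=0.0, ptotal=ptotal,
        hind_share=1.0 if side == "hind" else 0.0,
    )


def _truth_limb(posture: Posture, side: str, contact: Optional[GroundContact],
                model: AnthropometricModel) -> LimbSolution:
    """Joint loads via moment balances about each proximal joint."""
    leg = posture.leg(side)
    axes = {
        "foot": (leg.ankle, leg.toe),
        "shank": (leg.knee, leg.ankle),
        "thigh": (leg.hip, leg.knee),
    }
    geom = {}
    for name, (proximal, distal) in axes.items():
        spec = model.segment(name)
        geom[name] = (
            proximal, distal,
            segment_com_point(proximal, distal, spec.com_fraction),
            segment_weight(model, name),
        )

    # foot, moments about the ankle
    ankle_pt, _, foot_com, p1 = geom["foot"]
    ext_f = contact.grf if contact is not None else np.zeros(2)
    f_ankle = -(ext_f + np.array([0.0, -p1]))
    m_ankle = -cross2(foot_com - ankle_pt, np.array([0.0, -p1]))
    if contact is not None:
        m_ankle -= cross2(contact.point - ankle_pt, ext_f)
    ankle = JointLoad("ankle", f_ankle, m_ankle, side=side)

    # shank, moments about the knee
    knee_pt, ankle_pt2, shank_com, p2 = geom["shank"]
    f_knee = f_ankle + np.array([0.0, p2])
    m_knee = (
        m_ankle
        + cross2(ankle_pt2 - knee_pt, f_ankle)
        - cross2(shank_com - knee_pt, np.array([0.0, -p2]))
    )
    knee = JointLoad("knee", f_knee, m_knee, side=side)

    # thigh, moments about the hip
    hip_pt, knee_pt2, thigh_com, p3 = geom["thigh"]
    f_hip = f_knee + np.array([0.0, p3])
    m_hip = (
        m_knee
        + cross2(knee_pt2 - hip_pt, f_knee)
        - cross2(thigh_com - hip_pt, np.array([0.0, -p3]))
    )
    hip = JointLoad("hip", f_hip, m_hip, side=side)

    residuals = {}
    forces = [(ankle.force, ankle_pt), ((0.0, -p1), foot_com)]
    if contact is not None:
        forces.append((contact.grf, contact.point))
    f, m = net_load(forces, [ankle.moment], foot_com)
    residuals["foot"] = (float(np.linalg.norm(f)), abs(m))
    for name, prox_load, dist_load in (("shank", knee, ankle), ("thigh", hip, knee)):
        prox, dist, com, weight = geom[name]
        f, m = net_load(
            [(prox_load.force, prox), (-dist_load.force, dist), ((0.0, -weight), com)],
            [prox_load.moment, -dist_load.moment], com,
        )
        residuals[name] = (float(np.linalg.norm(f)), abs(m))

    return LimbSolution(side=side, ankle=ankle, knee=knee, hip=hip,
                        equilibrium_residuals=residuals)


def _solve_truth(posture: Posture, model: AnthropometricModel, contact: str):
    grf = _truth_grf(posture, model, contact)
    limbs = {}
    for side in ("hind", "front"):
        c = grf.contact_for(side) if side in posture.grounded_sides() else None
        limbs[side] = _truth_limb(posture, side, c, model)
    reports = check_scene(posture, model, grf, list(limbs.values()))
    failed = [r.body_id for r in reports if not r.passed]
    if failed:  # pragma: no cover - generation is self-validating
        raise InfeasibleSceneError(f"generated truth fails equilibrium: {failed}")
    return grf, limbs


def _jitter_posture(posture: Posture, sigma_m: float, rng) -> Posture:
    """I.i.d. Gaussian jitter on every keypoint, then re-ground."""
    def j(p):
        return p + rng.normal(0.0, sigma_m, size=2) if sigma_m > 0 else p

    legs = {}
    for side in ("hind", "front"):
        leg = posture.leg(side)
        legs[side] = Leg(*(j(getattr(leg, n))
                           for n in ("hip", "knee", "ankle", "heel", "toe")))
    trunk = j(posture.trunk_anchor)
    grounded = [legs[s] for s in posture.grounded_sides()]
    ground = min(min(l.heel[1], l.toe[1]) for l in grounded)
    legs = {k: l.translated((0.0, -ground)) for k, l in legs.items()}
    trunk = trunk - np.array([0.0, ground])
    # grounded feet are snapped onto the ground line so contacts stay valid
    snapped = {}
    for side, leg in legs.items():
        if side in posture.grounded_sides():
            heel = np.array([leg.heel[0], 0.0])
            toe = np.array([leg.toe[0], 0.0])
            snapped[side] = Leg(leg.hip, leg.knee, leg.ankle, heel, toe)
        else:
            snapped[side] = leg
    return Posture(hind=snapped["hind"], front=snapped["front"],
                   trunk_anchor=trunk, support_state=posture.support_state,
                   facing_sign=posture.facing_sign)


DEFAULT_RENDER_PX_PER_M = 100.0


def generate(params: SceneParams,
             model: Optional[AnthropometricModel] = None) -> SyntheticScene:
    """Build a scene, solve its ground truth, and self-validate it."""
    if model is None:
        model = build_model(1.85, 100.0)
    if params.preset == "readiness":
        posture = _readiness_posture(params, model)
    elif params.preset == "kick":
        posture = _kick_posture(params, model)
    else:
        posture = _custom_posture(params, model)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        posture = _jitter_posture(
            posture, params.noise_sigma / DEFAULT_RENDER_PX_PER_M, rng
        )

    grf, limbs = _solve_truth(posture, model, params.contact)
    return SyntheticScene(params=params, posture=posture, model=model,
                          truth_grf=grf, truth_limbs=limbs)


def perturb(scene: SyntheticScene, sigma: float, seed: int) -> SyntheticScene:
    """Jitter keypoints by ``sigma`` px (at the default render scale) and
    recompute the ground truth for the perturbed geometry."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return scene
    rng = np.random.default_rng(seed)
    posture = _jitter_posture(scene.posture, sigma / DEFAULT_RENDER_PX_PER_M, rng)
    grf, limbs = _solve_truth(posture, scene.model, scene.params.contact)
    params = replace(scene.params, noise_sigma=sigma, seed=seed)
    return SyntheticScene(params=params, posture=posture, model=scene.model,
                          truth_grf=grf, truth_limbs=limbs)


def write_pose_file(scene: SyntheticScene, path,
                    render: float = DEFAULT_RENDER_PX_PER_M,
                    image_height: float = 1000.0) -> None:
    """Write the scene as a BODY_25 keypoint JSON file (pixels, y down).

    The hind leg maps to the right-side keypoints and the front leg to the
    left side.  Rendered points carry confidence 0.95; keypoints the scene
    does not model (head, arms, small toes) carry confidence 0.
    """
    if not render > 0:
        raise ValidationError("render must be > 0 px/m")
    kp = np.zeros((N_KEYPOINTS, 3))

    def put(index: int, p: Point2):
        kp[index] = [p[0] * render, image_height - p[1] * render, 0.95]

    hind, front = scene.posture.hind, scene.posture.front
    for leg, (i_hip, i_knee, i_ankle, i_toe, i_heel) in (
        (hind, (R_HIP, R_KNEE, R_ANKLE, R_BIG_TOE, R_HEEL)),
        (front, (L_HIP, L_KNEE, L_ANKLE, L_BIG_TOE, L_HEEL)),
    ):
        put(i_hip, leg.hip)
        put(i_knee, leg.knee)
        put(i_ankle, leg.ankle)
        put(i_toe, leg.toe)
        put(i_heel, leg.heel)
    mid_hip = 0.5 * (hind.hip + front.hip)
    put(MID_HIP, mid_hip)
    put(NECK, 2.0 * scene.posture.trunk_anchor - mid_hip)

    payload = {
        "version": 1.3,
        "people": [{"person_id": [-1], "pose_keypoints_2d": kp.ravel().tolist()}],
    }
    Path(path).write_text(json.dumps(payload))
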