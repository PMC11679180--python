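"""Full-pipeline analysis and the structured JSON/CSV report."""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .anthropometry import AnthropometricModel, build_model, load_model_config
from .com_model import ComResult, body_mass_points, total_com
from .equilibrium import EquilibriumReport, check_scene
from .errors import PoseStaticsError
from .grf_solver import GRFSolution, solve_grf
from .limb_statics import LimbSolution, solve_limb
from .pose_io import CalibrationConfig, Posture, calibrate, read_pose_file, select_person


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one analysis run produced, serializable to JSON."""

    model: AnthropometricModel
    posture: Posture
    com: ComResult
    grf: GRFSolution
    limbs: Dict[str, LimbSolution]
    equilibrium: List[EquilibriumReport]
    provenance: Dict[str, str]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.equilibrium)

    def to_dict(self) -> dict:
        def vec(v):
            return [float(v[0]), float(v[1])]

        def leg(l):
            return {n: vec(getattr(l, n)) for n in ("hip", "knee", "ankle", "heel", "toe")}

        def joint_load(jl):
            return {"joint": jl.joint, "force_N": vec(jl.force),
                    "moment_Nm": float(jl.moment)}

        def contact(c):
            if c is None:
                return None
            return {"point_m": vec(c.point), "grf_N": vec(c.grf)}

        stance_width = abs(
            self.posture.front.ankle[0] - self.posture.hind.ankle[0]
        )
        return {
            "package_version": self.provenance.get("package_version", ""),
            "provenance": self.provenance,
            "model": self.model.to_dict(),
            "posture": {
                "support_state": self.posture.support_state,
                "facing_sign": self.posture.facing_sign,
                "stance_width_m": float(stance_width),
                "trunk_anchor_m": vec(self.posture.trunk_anchor),
                "hind": leg(self.posture.hind),
                "front": leg(self.posture.front),
            },
            "com": {"com_m": vec(self.com.com), "total_mass_kg": float(self.com.total_mass)},
            "grf": {
                "hind": contact(self.grf.hind),
                "front": contact(self.grf.front),
                "L1_m": float(self.grf.L1),
                "L2_m": float(self.grf.L2),
                "ptotal_N": float(self.grf.ptotal),
                "hind_share": float(self.grf.hind_share),
                "hind_share_pct": round(100.0 * self.grf.hind_share, 2),
            },
            "limbs": {
                side: {
                    "ankle": joint_load(l.ankle),
                    "knee": joint_load(l.knee),
                    "hip": joint_load(l.hip),
                    "equilibrium_residuals": {
                        k: [float(a), float(b)]
                        for k, (a, b) in l.equilibrium_residuals.items()
                    },
                }
                for side, l in self.limbs.items()
            },
            "equilibrium": [
                {
                    "body_id": r.body_id,
                    "net_force_N": vec(r.net_force),
                    "net_moment_Nm": float(r.net_moment),
                    "about_m": vec(r.about),
                    "passed": bool(r.passed),
                }
                for r in self.equilibrium
            ],
            "passed": self.passed,
            "sign_convention": {
                "moments": "CCW-positive in the world frame",
                "facing_sign": self.posture.facing_sign,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def joint_loads_csv(self, path) -> None:
        """Flat CSV of joint loads: side, joint, Fx_N, Fy_N, M_Nm."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["side", "joint", "Fx_N", "Fy_N", "M_Nm"])
            for side, limb in self.limbs.items():
                for joint in ("ankle", "knee", "hip"):
                    jl = limb.load(joint)
                    writer.writerow(
                        [side, joint, repr(float(jl.force[0])),
                         repr(float(jl.force[1])), repr(float(jl.moment))]
                    )


def _config_hash(*paths) -> str:
    h = hashlib.sha256()
    for p in paths:
        if p is not None and Path(str(p)).exists():
            h.update(Path(str(p)).read_bytes())
    return h.hexdigest()[:16]


def analyze_posture(
    posture: Posture,
    model: AnthropometricModel,
    contact: str = "midfoot",
    provenance: Optional[Dict[str, str]] = None,
) -> AnalysisReport:
    """Run CoM -> GRF -> both limbs -> equilibrium check on a calibrated posture."""
    from . import __version__

    com = total_com(body_mass_points(posture, model))
    grf = solve_grf(posture, com, model, contact)
    limbs = {}
    for side in ("hind", "front"):
        c = grf.contact_for(side) if side in posture.grounded_sides() else None
        limbs[side] = solve_limb(posture, side, c, model)
    reports = check_scene(posture, model, grf, list(limbs.values()))
    prov = dict(provenance or {})
    prov.setdefault("package_version", __version__)
    return AnalysisReport(model=model, posture=posture, com=com, grf=grf,
                          limbs=limbs, equilibrium=reports, provenance=prov)


def analyze(
    pose_path,
    model_config: Union[AnthropometricModel, str, Path, None] = None,
    calibration: Optional[CalibrationConfig] = None,
    contact: str = "midfoot",
) -> AnalysisReport:
    """Full chain from a keypoint file to an AnalysisReport.

    ``model_config`` may be an AnthropometricModel, a path to a YAML/JSON
    configuration, or None for the default 1.85 m / 100 kg model.
    """
    if isinstance(model_config, AnthropometricModel):
        model = model_config
        config_path = None
    elif model_config is None:
        model = build_model(1.85, 100.0)
        config_path = None
    else:
        model = load_model_config(model_config)
        config_path = model_config
    calibration = calibration or CalibrationConfig()

    try:
        poses = read_pose_file(pose_path)
    except FileNotFoundError:
        raise
    except PoseStaticsError as exc:
        raise type(exc)(f"[read] {exc}") from exc
    try:
        raw = select_person(poses)
        posture = calibrate(raw, model, calibration)
    except PoseStaticsError as exc:
        raise type(exc)(
            f"[calibrate] {exc} (check keypoint confidences and ground tolerance)"
        ) from exc

    provenance = {
        "pose_path": str(pose_path),
        "source_id": raw.source_id,
        "config_hash": _config_hash(pose_path, config_path),
        "contact": contact,
    }
    try:
        return analyze_posture(posture, model, contact, provenance)
    except PoseStaticsError as exc:
        raise type(exc)(f"[solve] {exc}") from exc


def validate_report(path) -> List[str]:
    """Re-check a serialized report's internal consistency.

    Returns a list of problem descriptions (empty when the report is
    sound): finite numbers, vertical/horizontal GRF balance against
    ptotal, and the stored equilibrium verdicts.
    """
    data = json.loads(Path(path).read_text())
    problems: List[str] = []

    def walk(obj, crumb=""):
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(v, f"{crumb}.{k}")
        elif isinstance(obj, list):
            for i, v in enumerate(obj):
                walk(v, f"{crumb}[{i}]")
        elif isinstance(obj, float) and not np.isfinite(obj):
            problems.append(f"non-finite number at {crumb}")

    walk(data)

    grf = data.get("grf", {})
    ptotal = grf.get("ptotal_N")
    fy = fx = 0.0
    for side in ("hind", "front"):
        c = grf.get(side)
        if c:
            fx += c["grf_N"][0]
            fy += c["grf_N"][1]
    if ptotal is not None and abs(fy - ptotal) > 1e-6:
        problems.append(f"vertical GRFs sum to {fy}, expected {ptotal}")
    if abs(fx) > 1e-6:
        problems.append(f"horizontal GRFs sum to {fx}, expected 0")
    if not data.get("passed", False):
        problems.append("report is marked failed by its equilibrium checks")
    for rep in data.get("equilibrium", []):
        if not rep.get("passed"):
            problems.append(f"equilibrium failure on {rep.get('body_id')}")
    return problems
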