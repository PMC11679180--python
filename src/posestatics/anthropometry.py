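"""Anthropometric model of the lower limbs.

Segment lengths, mass fractions, and centre-of-mass fractions describe a
bilaterally symmetric lower-limb model; everything above the hips is lumped
into a single residual head-arms-trunk (HAT) mass.  Defaults describe a
1.85 m / 100 kg male athlete; lengths scale linearly with stature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .errors import DegenerateSegmentError, ValidationError
from .geometry import Point2, as_point

SEGMENT_NAMES = ("foot", "shank", "thigh")

#: default segment lengths (m) at the reference stature
DEFAULT_LENGTHS = {"foot": 0.24, "shank": 0.48, "thigh": 0.50}
#: segment mass as a fraction of total body mass
DEFAULT_MASS_FRACTIONS = {"foot": 0.017, "shank": 0.047, "thigh": 0.107}
#: segment CoM location as a fraction of length from the proximal end
DEFAULT_COM_FRACTIONS = {"foot": 0.434, "shank": 0.420, "thigh": 0.439}

REFERENCE_STATURE = 1.85
DEFAULT_GRAVITY = 9.81
DEFAULT_FRICTION = 0.3


@dataclass(frozen=True)
class SegmentSpec:
    """Scaled parameters of one lower-limb segment."""

    name: str
    length: float  # m
    mass_fraction: float  # of total body mass
    com_fraction: float  # of length, from the proximal end

    def __post_init__(self):
        if self.name not in SEGMENT_NAMES:
            raise ValidationError(f"unknown segment name {self.name!r}")
        if not self.length > 0:
            raise ValidationError(f"{self.name}: length must be > 0")
        if not 0 < self.mass_fraction < 1:
            raise ValidationError(f"{self.name}: mass_fraction must be in (0, 1)")
        if not 0 < self.com_fraction < 1:
            raise ValidationError(f"{self.name}: com_fraction must be in (0, 1)")


@dataclass(frozen=True)
class AnthropometricModel:
    """Whole-body parameter set used by every downstream solver.

    ``segments`` holds one spec per segment name; left and right limbs share
    it (bilateral symmetry).  ``residual_mass_fraction`` is the HAT lump:
    one minus twice the summed leg fractions.
    """

    stature: float  # m
    total_mass: float  # kg
    g: float = DEFAULT_GRAVITY  # m s^-2
    friction_coefficient: float = DEFAULT_FRICTION
    segments: Mapping[str, SegmentSpec] = field(default_factory=dict)

    def __post_init__(self):
        if not self.stature > 0:
            raise ValidationError("stature must be > 0")
        if not self.total_mass > 0:
            raise ValidationError("total_mass must be > 0")
        if not self.g > 0:
            raise ValidationError("g must be > 0")
        if not 0 <= self.friction_coefficient <= 1:
            warnings.warn(
                f"friction coefficient {self.friction_coefficient} outside [0, 1]",
                stacklevel=3,
            )
        missing = set(SEGMENT_NAMES) - set(self.segments)
        if missing:
            raise ValidationError(f"missing segment specs: {sorted(missing)}")
        if not 0 < self.residual_mass_fraction < 1:
            raise ValidationError(
                "leg mass fractions leave no residual head-arms-trunk mass "
                f"(residual fraction {self.residual_mass_fraction:.4f})"
            )

    @property
    def residual_mass_fraction(self) -> float:
        return 1.0 - 2.0 * sum(s.mass_fraction for s in self.segments.values())

    @property
    def ptotal(self) -> float:
        """Total body weight (N)."""
        return self.total_mass * self.g

    def segment(self, name: str) -> SegmentSpec:
        try:
            return self.segments[name]
        except KeyError:
            raise KeyError(f"unknown segment {name!r}") from None

    def to_dict(self) -> dict:
        return {
            "stature_m": self.stature,
            "mass_kg": self.total_mass,
            "g": self.g,
            "mu": self.friction_coefficient,
            "residual_mass_fraction": self.residual_mass_fraction,
            "segments": {
                n: {
                    "length_m": s.length,
                    "mass_fraction": s.mass_fraction,
                    "com_fraction": s.com_fraction,
                }
                for n, s in self.segments.items()
            },
        }


def build_model(
    stature: float,
    total_mass: float,
    overrides: Optional[Mapping[str, float]] = None,
) -> AnthropometricModel:
    """Build a scaled anthropometric model.

    Parameters
    ----------
    stature : float
        Body height in meters; segment lengths scale by stature / 1.85.
    total_mass : float
        Body mass in kilograms.
    overrides : mapping, optional
        Flat overrides: ``g``, ``mu``, and per-segment
        ``<name>_length``, ``<name>_mass_fraction``, ``<name>_com_fraction``.

    Returns
    -------
    AnthropometricModel
    """
    overrides = dict(overrides or {})
    g = float(overrides.pop("g", DEFAULT_GRAVITY))
    mu = float(overrides.pop("mu", DEFAULT_FRICTION))
    scale = stature / REFERENCE_STATURE if stature > 0 else 1.0

    segments = {}
    for name in SEGMENT_NAMES:
        length = float(
            overrides.pop(f"{name}_length", DEFAULT_LENGTHS[name] * scale)
        )
        mass_fraction = float(
            overrides.pop(f"{name}_mass_fraction", DEFAULT_MASS_FRACTIONS[name])
        )
        com_fraction = float(
            overrides.pop(f"{name}_com_fraction", DEFAULT_COM_FRACTIONS[name])
        )
        segments[name] = SegmentSpec(name, length, mass_fraction, com_fraction)
    if overrides:
        raise ValidationError(f"unknown override keys: {sorted(overrides)}")

    return AnthropometricModel(
        stature=float(stature),
        total_mass=float(total_mass),
        g=g,
        friction_coefficient=mu,
        segments=segments,
    )


def segment_weight(model: AnthropometricModel, name: str) -> float:
    """Weight of one segment (N): mass_fraction * total_mass * g."""
    spec = model.segment(name)
    return spec.mass_fraction * model.total_mass * model.g


def segment_com_point(proximal, distal, com_fraction: float) -> Point2:
    """Locate a segment CoM at ``com_fraction`` along proximal -> distal."""
    p = as_point(proximal)
    d = as_point(distal)
    if np.allclose(p, d, rtol=0.0, atol=1e-12):
        raise DegenerateSegmentError(
            f"segment endpoints coincide at {tuple(p)}"
        )
    return p + com_fraction * (d - p)


_CONFIG_KEYS = {"stature_m", "mass_kg", "mu", "g", "segments"}
_SEGMENT_KEYS = {"length_m", "mass_fraction", "com_fraction"}


def load_model_config(path) -> AnthropometricModel:
    """Read a YAML or JSON anthropometric configuration file.

    Recognized keys: ``stature_m`` (required), ``mass_kg`` (required),
    ``mu``, ``g``, and ``segments: {<name>: {length_m, mass_fraction,
    com_fraction}}`` overrides.
    """
    from .errors import ParseError

    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ParseError(f"cannot parse model config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"model config {path} must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ParseError(f"unknown model config keys: {sorted(unknown)}")
    for key in ("stature_m", "mass_kg"):
        if key not in data:
            raise ParseError(f"model config missing required key {key!r}")

    overrides: dict = {}
    for opt in ("mu", "g"):
        if opt in data:
            overrides[opt] = data[opt]
    seg_over = data.get("segments", {})
    if not isinstance(seg_over, dict):
        raise ParseError("'segments' must be a mapping")
    for name, spec in seg_over.items():
        if name not in SEGMENT_NAMES:
            raise ParseError(f"unknown segment {name!r} in config")
        unknown = set(spec) - _SEGMENT_KEYS
        if unknown:
            raise ParseError(f"unknown keys for segment {name}: {sorted(unknown)}")
        if "length_m" in spec:
            overrides[f"{name}_length"] = spec["length_m"]
        if "mass_fraction" in spec:
            overrides[f"{name}_mass_fraction"] = spec["mass_fraction"]
        if "com_fraction" in spec:
            overrides[f"{name}_com_fraction"] = spec["com_fraction"]

    return build_model(data["stature_m"], data["mass_kg"], overrides)
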