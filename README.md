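# posestatics

Static, sagittal-plane link-segment analysis of human postures from 2D
pose keypoints. Given a BODY_25 keypoint file (the 25-point x/y/confidence
layout emitted by common markerless pose estimators) and an anthropometric
configuration, the package:

1. calibrates pixel coordinates into a metric world frame (x along the
   facing direction, y up, ground at y = 0), estimating the scale from the
   knee–ankle distance;
2. reduces the body to seven point masses (foot/shank/thigh per leg at
   their segment centres of mass, plus a lumped head-arms-trunk mass) and
   computes the whole-body centre of mass;
3. solves whole-body static equilibrium for per-foot ground reaction
   forces — double support splits body weight by the CoM lever arms with
   Coulomb friction loading the feet in equal and opposite horizontal
   pairs; single support places the centre of pressure under the CoM;
4. runs a distal-to-proximal free-body recursion giving joint forces and
   scalar moments (CCW-positive) at the ankle, knee, and hip of each leg;
5. verifies every solved free body, and the whole body, with an
   independent brute-force equilibrium checker.

A synthetic scene generator provides two parameterized stance families —
a double-support "readiness" stance with a configurable hind-leg weight
share, and a single-support "kick" stance — with ground-truth loads solved
by an independent formulation and self-validated before use. It stands in
for image-derived keypoints in all tests.

The default anthropometric model is a 1.85 m / 100 kg athlete: segment
lengths 0.24 / 0.48 / 0.50 m (foot / shank / thigh), mass fractions
0.017 / 0.047 / 0.107, CoM fractions 0.434 / 0.420 / 0.439 from the
proximal end, friction coefficient 0.3, g = 9.81 m/s².

## CLI

```sh
# generate a synthetic scene (keypoint file + ground-truth report)
posestatics simulate --preset readiness --seed 7 --out-dir scratch/

# run the full pipeline on a keypoint file
posestatics analyze --pose scratch/readiness_seed7_keypoints.json \
    --out scratch/report.json --csv scratch/loads.csv \
    --contact midfoot --support auto

# re-check a serialized report's internal consistency
posestatics validate --report scratch/report.json
```

`analyze` accepts an optional `--config model.yaml` with keys
`stature_m`, `mass_kg`, `mu`, `g`, and per-segment overrides
(`segments: {thigh: {length_m: ...}}`). `--contact heel|midfoot|toe`
selects where each grounded foot's contact point sits in double support;
`--support` can force a support state when automatic detection is not
wanted (a clearly airborne foot is still rejected).

The JSON report contains the model echo, the calibrated posture, the CoM,
per-foot ground reactions with the hind-leg weight share, per-joint forces
and moments for both limbs, and the equilibrium check results.

## Python API

```python
import posestatics as ps

model = ps.build_model(1.85, 100.0)
scene = ps.generate(ps.SceneParams(preset="readiness", com_bias=0.68))
ps.write_pose_file(scene, "pose.json")
report = ps.analyze("pose.json", model)
print(report.grf.hind_share, report.limbs["hind"].knee.moment)
```

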