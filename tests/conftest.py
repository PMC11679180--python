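"""Shared fixtures and the test-local independent limb oracle.

The oracle here deliberately takes every moment balance about the
segment's *distal* joint — a third reference point, distinct from both the
package solver (segment CoM) and the synthetic generator's truth solve
(proximal joint) — so agreement between all three is a genuine
reference-point-independence check.
"""

import numpy as np
import pytest

from posestatics import (
    SceneParams,
    build_model,
    generate,
)
from posestatics.anthropometry import segment_com_point, segment_weight
from posestatics.geometry import cross2
from posestatics.limb_statics import JointLoad


@pytest.fixture(scope="session")
def default_model():
    return build_model(1.85, 100.0)


@pytest.fixture(scope="session")
def readiness_scene(default_model):
    return generate(SceneParams(preset="readiness"), default_model)


@pytest.fixture(scope="session")
def kick_scene(default_model):
    return generate(SceneParams(preset="kick"), default_model)


def oracle_limb_loads(posture, side, contact, model):
    """Independent distal-to-proximal recursion, moments about distal joints.

    Returns {"ankle": JointLoad, "knee": ..., "hip": ...} with the same
    action-reaction conventions as the package solver.
    """
    leg = posture.leg(side)
    axes = {
        "foot": (leg.ankle, leg.toe),
        "shank": (leg.knee, leg.ankle),
        "thigh": (leg.hip, leg.knee),
    }
    geom = {}
    for name, (prox, dist) in axes.items():
        spec = model.segment(name)
        geom[name] = (prox, dist, segment_com_point(prox, dist, spec.com_fraction),
                      segment_weight(model, name))

    down = lambda w: np.array([0.0, -w])

    # foot: unknowns F_ankle, M_ankle; moments about the toe (distal end)
    prox, dist, com, p1 = geom["foot"]
    ext_f = contact.grf if contact is not None else np.zeros(2)
    f_ankle = -(ext_f + down(p1))
    m_ankle = -cross2(prox - dist, f_ankle) - cross2(com - dist, down(p1))
    if contact is not None:
        m_ankle -= cross2(contact.point - dist, ext_f)
    loads = {"ankle": JointLoad("ankle", f_ankle, m_ankle, side=side)}

    for name, joint in (("shank", "knee"), ("thigh", "hip")):
        prox, dist, com, w = geom[name]
        distal_load = loads["ankle" if name == "shank" else "knee"]
        f = distal_load.force - down(w)
        # about the distal joint: the negated distal force has zero arm
        m = distal_load.moment - cross2(prox - dist, f) - cross2(com - dist, down(w))
        loads[joint] = JointLoad(joint, f, m, side=side)
    return loads


@pytest.fixture(scope="session")
def oracle_limb():
    return oracle_limb_loads
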