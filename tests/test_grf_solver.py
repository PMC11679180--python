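import numpy as np
import pytest

from posestatics import (
    ComResult,
    DegenerateStanceError,
    MassPoint,
    OutOfBaseError,
    SceneParams,
    ValidationError,
    body_mass_points,
    friction_components,
    generate,
    solve_double_support,
    solve_single_support,
    total_com,
)
from posestatics.grf_solver import contact_point


def com_at(x, y=1.0, mass=100.0):
    """ComResult pinned at an arbitrary point (for lever-arm tests)."""
    return ComResult(com=np.array([x, y]), total_mass=mass,
                     contributions=[MassPoint((x, y), mass)])


@pytest.fixture(scope="module")
def double_posture(readiness_scene):
    return readiness_scene.posture


@pytest.fixture(scope="module")
def contacts_x(double_posture):
    return (
        contact_point(double_posture.hind)[0],
        contact_point(double_posture.front)[0],
    )


class TestDoubleSupport:
    def test_symmetric_split(self, double_posture, default_model, contacts_x):
        x1, x2 = contacts_x
        sol = solve_double_support(
            double_posture, com_at(0.5 * (x1 + x2)), default_model
        )
        assert sol.hind.grf[1] == pytest.approx(490.5)
        assert sol.front.grf[1] == pytest.approx(490.5)

    def test_com_at_hind_contact_limit(self, double_posture, default_model, contacts_x):
        x1, _ = contacts_x
        sol = solve_double_support(double_posture, com_at(x1), default_model)
        assert sol.hind.grf[1] == pytest.approx(981.0)
        assert sol.front.grf[1] == pytest.approx(0.0, abs=1e-9)
        assert sol.hind_share == pytest.approx(1.0)

    def test_printed_friction_value(self, default_model):
        # Co = 0.3 applied to the hind vertical GRF of 674.5038 N
        assert friction_components(674.5038, default_model, +1) == pytest.approx(
            202.35114
        )
        assert round(friction_components(674.5038, default_model, +1), 2) == 202.35

    def test_readiness_solution_reproduces_printed_grf(
        self, readiness_scene, default_model
    ):
        com = total_com(body_mass_points(readiness_scene.posture, default_model))
        sol = solve_double_support(readiness_scene.posture, com, default_model)
        assert sol.hind.grf[1] == pytest.approx(674.5038, abs=1e-6)
        assert sol.front.grf[1] == pytest.approx(306.4962, abs=1e-6)
        assert sol.hind.grf[0] == pytest.approx(202.35114, abs=1e-6)
        assert sol.front.grf[0] == pytest.approx(-202.35114, abs=1e-6)

    def test_out_of_base(self, double_posture, default_model, contacts_x):
        x1, x2 = contacts_x
        with pytest.raises(OutOfBaseError):
            solve_double_support(double_posture, com_at(x2 + 0.05), default_model)
        with pytest.raises(OutOfBaseError):
            solve_double_support(double_posture, com_at(x1 - 0.05), default_model)

    def test_equilibrium_residuals(self, double_posture, default_model, contacts_x):
        """The three whole-system balances hold at the returned solution."""
        x1, x2 = contacts_x
        cx = x1 + 0.3 * (x2 - x1)
        sol = solve_double_support(double_posture, com_at(cx), default_model)
        gx1, gy1 = sol.hind.grf
        gx2, gy2 = sol.front.grf
        assert abs(gx1 + gx2) < 1e-9
        assert abs(gy1 + gy2 - sol.ptotal) < 1e-9
        # moment about the front contact (cross-check about the hind one too)
        assert abs(sol.ptotal * sol.L2 - gy1 * (sol.L1 + sol.L2)) < 1e-9
        assert abs(gy2 * (sol.L1 + sol.L2) - sol.ptotal * sol.L1) < 1e-9

    def test_monotone_decreasing_share(self, double_posture, default_model, contacts_x):
        x1, x2 = contacts_x
        shares = [
            solve_double_support(double_posture, com_at(x), default_model).hind_share
            for x in np.linspace(x1, x2, 50)
        ]
        assert all(a > b for a, b in zip(shares, shares[1:]))

    def test_translation_invariance(self, readiness_scene, default_model):
        from posestatics.pose_io import Posture

        p = readiness_scene.posture
        shift = np.array([13.7, 0.0])
        moved = Posture(
            hind=p.hind.translated(shift), front=p.front.translated(shift),
            trunk_anchor=p.trunk_anchor + shift,
            support_state=p.support_state, facing_sign=p.facing_sign,
        )
        com = total_com(body_mass_points(p, default_model))
        com_moved = total_com(body_mass_points(moved, default_model))
        a = solve_double_support(p, com, default_model)
        b = solve_double_support(moved, com_moved, default_model)
        np.testing.assert_allclose(a.hind.grf, b.hind.grf, atol=1e-9)
        np.testing.assert_allclose(
            b.hind.point, a.hind.point + shift, atol=1e-9
        )

    def test_narrow_stance_stays_bounded(self, default_model):
        scene = generate(SceneParams(preset="readiness", stance_width=0.08),
                         default_model)
        sol = scene.truth_grf
        assert np.isfinite(sol.hind.grf).all() and np.isfinite(sol.front.grf).all()
        assert sol.hind.grf[1] + sol.front.grf[1] == pytest.approx(981.0)
        assert 0.0 <= sol.hind_share <= 1.0

    def test_degenerate_stance(self, readiness_scene, default_model):
        from posestatics.pose_io import Posture

        p = readiness_scene.posture
        stacked = Posture(
            hind=p.hind, front=p.hind.translated((0.0, 0.0)),
            trunk_anchor=p.trunk_anchor,
            support_state="double", facing_sign=1,
        )
        with pytest.raises(DegenerateStanceError):
            solve_double_support(
                stacked, com_at(contact_point(p.hind)[0]), default_model
            )


class TestSingleSupport:
    def test_full_weight_no_friction(self, kick_scene, default_model):
        com = total_com(body_mass_points(kick_scene.posture, default_model))
        sol = solve_single_support(kick_scene.posture, com, default_model)
        assert sol.hind.grf[1] == pytest.approx(981.0)
        assert sol.hind.grf[0] == 0.0
        assert sol.front is None
        assert sol.hind_share == 1.0
        assert sol.L1 == 0.0

    def test_cop_under_com(self, kick_scene, default_model):
        com = total_com(body_mass_points(kick_scene.posture, default_model))
        sol = solve_single_support(kick_scene.posture, com, default_model)
        assert sol.hind.point[0] == pytest.approx(com.com[0])

    def test_com_beyond_toe(self, kick_scene, default_model):
        toe_x = kick_scene.posture.hind.toe[0]
        with pytest.raises(OutOfBaseError):
            solve_single_support(kick_scene.posture, com_at(toe_x + 0.05),
                                 default_model)


class TestFrictionComponents:
    def test_zero(self, default_model):
        assert friction_components(0.0, default_model, +1) == 0.0

    def test_frictionless(self):
        from posestatics import build_model

        model = build_model(1.85, 100.0, {"mu": 0.0})
        assert friction_components(100.0, model, +1) == 0.0

    def test_sign(self, default_model):
        assert friction_components(100.0, default_model, -1) == pytest.approx(-30.0)

    def test_negative_grf_rejected(self, default_model):
        with pytest.raises(ValidationError):
            friction_components(-1.0, default_model, +1)
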