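"""Per-particle force evaluators against hand-computed oracles, lift-table
lookups and qualitative lift-model structure."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from centrisim import flow as F
from centrisim import forces as Fo

UM = 1e-6


@pytest.fixture(scope="module")
def frame2000():
    return F.RotatingFrame.from_rpm(2000)


class TestStokesDrag:
    def test_hand_value(self, fluid):
        # 3 pi * 1e-3 * 1e-5 * 1e-2 = 9.42478e-10 N
        f = Fo.stokes_drag(fluid, Fo.Particle(10 * UM), [0.01, 0, 0])
        assert np.linalg.norm(f) == pytest.approx(9.42478e-10, rel=1e-6)

    def test_zero_relative_velocity(self, fluid):
        f = Fo.stokes_drag(fluid, Fo.Particle(10 * UM), [0, 0, 0])
        np.testing.assert_allclose(f, 0.0)

    def test_parallel_to_relative_velocity(self, fluid):
        v = np.array([0.3, -0.4, 0.1])
        f = Fo.stokes_drag(fluid, Fo.Particle(15 * UM), v)
        cross = np.cross(f, v)
        np.testing.assert_allclose(cross, 0.0, atol=1e-20)


class TestCentrifugal:
    def test_hand_value(self, fluid, frame2000):
        f = Fo.centrifugal_force(
            Fo.Particle(20 * UM), fluid, frame2000, [0.03, 0, 0]
        )
        assert np.linalg.norm(f) == pytest.approx(2.75611e-10, rel=1e-6)
        assert f[0] > 0  # outward for denser-than-fluid particles

    def test_neutral_buoyancy(self, fluid, frame2000):
        p = Fo.Particle(20 * UM, density=fluid.density)
        f = Fo.centrifugal_force(p, fluid, frame2000, [0.03, 0, 0])
        np.testing.assert_allclose(f, 0.0)

    def test_quadratic_in_omega(self, fluid):
        p = Fo.Particle(15 * UM)
        f1 = Fo.centrifugal_force(
            p, fluid, F.RotatingFrame.from_rpm(1000), [0.03, 0, 0]
        )
        f2 = Fo.centrifugal_force(
            p, fluid, F.RotatingFrame.from_rpm(2000), [0.03, 0, 0]
        )
        assert np.linalg.norm(f2) == pytest.approx(
            4 * np.linalg.norm(f1), rel=1e-9
        )


class TestCoriolis:
    def test_hand_value(self, fluid, frame2000):
        f = Fo.coriolis_force(
            Fo.Particle(20 * UM), fluid, frame2000, [0.1, 0, 0]
        )
        assert np.linalg.norm(f) == pytest.approx(8.77298e-12, rel=1e-6)

    def test_velocity_parallel_to_axis(self, fluid, frame2000):
        f = Fo.coriolis_force(
            Fo.Particle(20 * UM), fluid, frame2000, [0, 0, 0.5]
        )
        np.testing.assert_allclose(f, 0.0)

    def test_always_perpendicular_to_velocity(self, fluid, frame2000):
        v = np.array([0.2, 0.1, 0.0])
        f = Fo.coriolis_force(Fo.Particle(12 * UM), fluid, frame2000, v)
        assert abs(np.dot(f, v)) < 1e-25


class TestDeanDrag:
    def test_hand_value(self, fluid):
        f = Fo.dean_drag(fluid, Fo.Particle(20 * UM), [0.01, 0, 0])
        assert np.linalg.norm(f) == pytest.approx(1.88496e-9, rel=1e-6)

    def test_identical_to_stokes_form(self, fluid):
        p = Fo.Particle(17 * UM)
        u = np.array([0.003, -0.001, 0.0])
        np.testing.assert_allclose(
            Fo.dean_drag(fluid, p, u), Fo.stokes_drag(fluid, p, u)
        )


class TestLiftModel:
    @pytest.mark.parametrize(
        "ar, c1, c2",
        [(1, 0.056, 0.03), (2, 0.021, 0.018), (4, 0.023, 0.127),
         (6, 0.068, 0.135)],
    )
    def test_tabulated_coefficients_exact(self, lift_model, ar, c1, c2):
        assert lift_model.coefficients(ar) == (c1, c2)

    def test_interpolation_between_rows(self, lift_model):
        c1, c2 = lift_model.coefficients(3.0)
        assert c1 == pytest.approx((0.021 + 0.023) / 2)
        assert c2 == pytest.approx((0.018 + 0.127) / 2)

    def test_out_of_range_clamps_with_warning(self, lift_model):
        with pytest.warns(UserWarning):
            c = lift_model.coefficients(8.0)
        assert c == lift_model.coefficients(6.0)

    def test_zero_lift_on_symmetric_centerline(self, lift_model, fluid):
        loc = Fo.parabolic_local_flow(
            0.5, 0.5, 50 * UM, [0.0, 1.0, 0.0]
        )
        f = lift_model.force(fluid, Fo.Particle(20 * UM), loc, 1.0)
        assert np.linalg.norm(f) < 1e-18

    def test_wall_repulsion_points_into_channel(self, lift_model, fluid):
        p = Fo.Particle(10 * UM)
        for ar in (1.0, 2.0, 4.0, 6.0):
            near_lo = Fo.parabolic_local_flow(0.03, 0.5, 100 * UM,
                                              [0, 1, 0])
            near_hi = Fo.parabolic_local_flow(0.97, 0.5, 100 * UM,
                                              [0, 1, 0])
            assert lift_model.force(fluid, p, near_lo, ar)[1] > 0
            assert lift_model.force(fluid, p, near_hi, ar)[1] < 0

    def test_equilibria_structure_on_parabolic_profile(self, lift_model):
        """Stable off-center equilibria exist between s = 0.1 and 0.25 for
        every tabulated aspect ratio (the qualitative content of the
        weighting-function curves)."""
        s = np.linspace(0.02, 0.5, 400)
        for ar in (1.0, 2.0, 4.0, 6.0):
            cl = lift_model.lift_coefficient(ar, s, 4 * (1 - 2 * s), -8.0)
            sign_change = np.nonzero(np.diff(np.sign(cl)))[0]
            assert len(sign_change) >= 1
            s_star = s[sign_change[0]]
            assert 0.1 < s_star < 0.25

    def test_square_channel_equilibrium_at_point_two(self, lift_model):
        s = np.linspace(0.15, 0.25, 2001)
        cl = lift_model.lift_coefficient(1.0, s, 4 * (1 - 2 * s), -8.0)
        root = s[np.argmin(np.abs(cl))]
        assert root == pytest.approx(0.2, abs=0.005)

    def test_quartic_diameter_scaling(self, lift_model, fluid):
        loc = Fo.parabolic_local_flow(0.3, 0.5, 50 * UM, [0, 1, 0])
        f1 = lift_model.force(fluid, Fo.Particle(10 * UM), loc, 1.0)
        f2 = lift_model.force(fluid, Fo.Particle(20 * UM), loc, 1.0)
        assert np.linalg.norm(f2) == pytest.approx(
            16 * np.linalg.norm(f1), rel=1e-9
        )

    def test_lift_map_symmetric_on_symmetric_profile(self, lift_model, fluid):
        """The cross-section lift field of a symmetric profile is odd under
        reflection through the mid-plane and vanishes on the axis."""
        p = Fo.Particle(20 * UM)
        s = np.linspace(0.05, 0.45, 9)
        f_lo = [
            lift_model.force(
                fluid, p, Fo.parabolic_local_flow(si, 0.5, 50 * UM, [0, 1, 0]),
                1.0,
            )[1]
            for si in s
        ]
        f_hi = [
            lift_model.force(
                fluid, p,
                Fo.parabolic_local_flow(1 - si, 0.5, 50 * UM, [0, 1, 0]),
                1.0,
            )[1]
            for si in s
        ]
        np.testing.assert_allclose(f_lo, -np.array(f_hi), rtol=2e-4,
                                   atol=1e-18)

    def test_invalid_wall_coordinate_rejected(self):
        with pytest.raises(ValueError):
            Fo.parabolic_local_flow(1.2, 0.5, 50 * UM, [0, 1, 0])

    def test_loaders_roundtrip(self, tmp_path, lift_model):
        import numpy as np

        s = np.linspace(0.01, 0.99, 99)
        g = np.column_stack(
            [s, Fo.surrogate_g1(s), Fo.surrogate_g2(s)]
        )
        c = np.array([[1, 0.056, 0.03], [2, 0.021, 0.018],
                      [4, 0.023, 0.127], [6, 0.068, 0.135]])
        gp = tmp_path / "g.tsv"
        cp = tmp_path / "c.tsv"
        np.savetxt(gp, g)
        np.savetxt(cp, c)
        model = Fo.LiftModel.from_tables(gp, cp)
        assert model.coefficients(4.0) == (0.023, 0.127)
        assert model.g1(0.2) == pytest.approx(Fo.surrogate_g1(0.2), rel=1e-6)


class TestForcePurity:
    @given(scale=st.floats(0.5, 4.0))
    def test_density_scaling_of_body_forces(self, scale):
        """Scaling all densities by k scales centrifugal and Coriolis
        outputs by k (dimensional-audit property)."""
        fl1 = F.Fluid(density=1000.0)
        fl2 = F.Fluid(density=1000.0 * scale)
        p1 = Fo.Particle(20 * UM, density=1050.0)
        p2 = Fo.Particle(20 * UM, density=1050.0 * scale)
        fr = F.RotatingFrame.from_rpm(1500)
        f1 = Fo.centrifugal_force(p1, fl1, fr, [0.03, 0, 0])
        f2 = Fo.centrifugal_force(p2, fl2, fr, [0.03, 0, 0])
        np.testing.assert_allclose(f2, scale * f1, rtol=1e-12)
        c1 = Fo.coriolis_force(p1, fl1, fr, [0.1, 0, 0])
        c2 = Fo.coriolis_force(p2, fl2, fr, [0.1, 0, 0])
        np.testing.assert_allclose(c2, scale * c1, rtol=1e-12)

    def test_evaluators_are_pure(self, fluid, lift_model, frame2000):
        p = Fo.Particle(15 * UM)
        loc = Fo.parabolic_local_flow(0.3, 0.4, 50 * UM, [0, 1, 0])
        a = lift_model.force(fluid, p, loc, 1.0)
        b = lift_model.force(fluid, p, loc, 1.0)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(
            Fo.centrifugal_force(p, fluid, frame2000, [0.03, 0, 0]),
            Fo.centrifugal_force(p, fluid, frame2000, [0.03, 0, 0]),
        )


class TestForceRatioReport:
    def test_neutral_density_zeroes_ratios(self, fluid, frame2000, lift_model):
        p = Fo.Particle(20 * UM, density=fluid.density)
        loc = Fo.parabolic_local_flow(0.3, 0.6, 50 * UM, [0, 1, 0])
        rep = Fo.force_ratio_report(
            p, fluid, frame2000, loc, [0.03, 0, 0], [0.1, 0, 0],
            model=lift_model,
        )
        assert rep["centrifugal_over_lift"] == 0.0
        assert rep["coriolis_over_lift"] == 0.0

    def test_rotation_velocity_group_near_unity(self, fluid, lift_model):
        """With the estimate U_max ~ r w (fluid velocity set by solid-body
        rotation), the centrifugal velocity group r w / U_max is unity."""
        frame = F.RotatingFrame(100.0)
        r = 0.03
        u_max = r * frame.omega
        loc = Fo.parabolic_local_flow(0.3, u_max, 50 * UM, [0, 1, 0])
        rep = Fo.force_ratio_report(
            Fo.Particle(20 * UM), fluid, frame, loc, [r, 0, 0],
            [u_max, 0, 0], model=lift_model,
        )
        assert rep["centrifugal_velocity_group"] == pytest.approx(1.0)
        assert rep["coriolis_velocity_group"] == pytest.approx(1.0)
        assert math.isfinite(rep["centrifugal_over_lift"])
        assert not rep["lift_is_zero"]

    def test_zero_lift_flagged_infinite(self, fluid, frame2000, lift_model):
        loc = Fo.parabolic_local_flow(0.5, 0.6, 50 * UM, [0, 1, 0])
        rep = Fo.force_ratio_report(
            Fo.Particle(20 * UM), fluid, frame2000, loc, [0.03, 0, 0],
            [0.1, 0, 0], model=lift_model,
        )
        assert rep["lift_is_zero"]
        assert rep["centrifugal_over_lift"] == math.inf

    def test_groups_dimensionless_under_rescaling(self, fluid, lift_model):
        """The nondimensional groups are invariant when all lengths scale by
        k and all rates by 1/k (so velocities are unchanged)."""
        k = 3.0
        fr1 = F.RotatingFrame(120.0)
        fr2 = F.RotatingFrame(120.0 / k)
        loc1 = Fo.parabolic_local_flow(0.3, 0.5, 50 * UM, [0, 1, 0])
        loc2 = Fo.parabolic_local_flow(0.3, 0.5, 50 * UM * k, [0, 1, 0])
        p1 = Fo.Particle(10 * UM)
        p2 = Fo.Particle(10 * UM * k)
        r1 = Fo.force_ratio_report(
            p1, fluid, fr1, loc1, [0.03, 0, 0], [0.1, 0, 0],
            model=lift_model,
        )
        r2 = Fo.force_ratio_report(
            p2, fluid, fr2, loc2, [0.03 * k, 0, 0], [0.1, 0, 0],
            model=lift_model,
        )
        for key in ("density_group", "rotation_group",
                    "centrifugal_velocity_group", "coriolis_velocity_group"):
            assert r1[key] == pytest.approx(r2[key], rel=1e-12)
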