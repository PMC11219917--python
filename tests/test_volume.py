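"""Slab primitives, stacking methods, and the spherical-cap correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from ocuvol import (
    CapSpec,
    RadiusProfile,
    VolumeEstimate,
    cap_volume,
    cylinder_slab,
    estimate_stack,
    estimate_volume,
    frustum_slab,
    pixel_count_volume,
    stack_volume,
)


def profile_from_radii(radii, gaps):
    """Helper: areas consistent with the circle approximation."""
    return RadiusProfile(
        radii=tuple(radii),
        gaps=tuple(gaps),
        areas=tuple(math.pi * r * r for r in radii),
    )


def quad_solid_of_revolution(r_lo, r_hi, h):
    """Independent oracle: integrate pi*r(x)^2 for the linear radius profile."""
    val, _ = quad(lambda x: math.pi * (r_lo + (r_hi - r_lo) * x / h) ** 2, 0.0, h)
    return val


class TestSlabs:
    @pytest.mark.parametrize(
        ("r_lo", "r_hi", "h", "expected"),
        [
            (1.0, 1.0, 2.0, math.pi * 2.0),        # equal radii -> cylinder
            (1.0, 0.0, 3.0, math.pi),              # apex case -> (1/3) pi r^2 h
            (1.0, 2.0, 3.0, 7.0 * math.pi),        # frozen from the quadrature oracle
        ],
    )
    def test_frustum_known_values(self, r_lo, r_hi, h, expected):
        assert frustum_slab(r_lo, r_hi, h) == pytest.approx(expected, rel=1e-12)

    @given(
        r_lo=st.floats(0.0, 20.0),
        r_hi=st.floats(0.0, 20.0),
        h=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_frustum_matches_quadrature_and_is_symmetric(self, r_lo, r_hi, h):
        v = frustum_slab(r_lo, r_hi, h)
        assert v == pytest.approx(quad_solid_of_revolution(r_lo, r_hi, h), rel=1e-9, abs=1e-12)
        # symmetric up to summation order (1 ulp)
        assert v == pytest.approx(frustum_slab(r_hi, r_lo, h), rel=1e-14, abs=1e-300)

    def test_frustum_monotone_in_each_argument(self):
        base = frustum_slab(1.0, 2.0, 1.0)
        assert frustum_slab(1.5, 2.0, 1.0) > base
        assert frustum_slab(1.0, 2.5, 1.0) > base
        assert frustum_slab(1.0, 2.0, 1.5) > base

    @pytest.mark.parametrize(
        ("r", "h", "expected"),
        [(1.0, 1.0, math.pi), (0.0, 1.0, 0.0), (2.0, 3.0, 12.0 * math.pi)],
    )
    def test_cylinder_known_values(self, r, h, expected):
        assert cylinder_slab(r, h) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1.0, 1.0, 1.0), (1.0, -1.0, 1.0), (1.0, 1.0, 0.0)])
    def test_negative_or_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            frustum_slab(*bad)


class TestCap:
    def test_hemisphere_and_empty_range(self):
        m = 3.0
        assert cap_volume(CapSpec(m=m, x1=0.0)) == pytest.approx(2 / 3 * math.pi * m**3)
        assert cap_volume(CapSpec(m=m, x1=m)) == 0.0

    def test_known_cap(self):
        # frozen from adaptive quadrature of pi*(m^2 - x^2) over [8, 12]
        assert cap_volume(CapSpec(m=12.0, x1=8.0)) == pytest.approx(
            math.pi * 512.0 / 3.0, rel=1e-12
        )

    def test_closed_form_equals_quadrature_on_random_grid(self, rng):
        for _ in range(100):
            m = rng.uniform(0.5, 20.0)
            x1 = rng.uniform(0.0, m)
            expected, _ = quad(lambda x: math.pi * (m**2 - x**2), x1, m)
            assert cap_volume(CapSpec(m=m, x1=x1)) == pytest.approx(expected, rel=1e-9)

    def test_x1_beyond_m_rejected(self):
        with pytest.raises(ValueError):
            CapSpec(m=1.0, x1=1.5)


class TestStacking:
    def test_constant_profile_makes_methods_agree(self):
        p = profile_from_radii([2.0] * 5, [1.5] * 4)
        expected = 4 * math.pi * 4.0 * 1.5
        assert stack_volume(p, "cylinder") == pytest.approx(expected)
        assert stack_volume(p, "cone") == pytest.approx(expected)
        assert pixel_count_volume(p) == pytest.approx(expected)

    def test_two_slice_profile_against_slab_oracles(self):
        p = profile_from_radii([1.0, 2.0], [3.0])
        assert stack_volume(p, "cylinder") == pytest.approx(3 * math.pi)
        assert stack_volume(p, "cone") == pytest.approx(7 * math.pi)

    def test_cone_vs_trapezoid_identity_on_sphere_profile(self):
        # per-slab identity: cone - trapezoid-in-area = -(pi*h/6) * (dr)^2
        h = 1.0
        zs = np.arange(-11.5, 12.0, h)
        radii = np.sqrt(np.clip(144.0 - zs**2, 0, None))
        p = profile_from_radii(radii, [h] * (len(radii) - 1))
        cone = stack_volume(p, "cone")
        trap = sum(
            math.pi * h * (radii[i] ** 2 + radii[i + 1] ** 2) / 2.0
            for i in range(len(radii) - 1)
        )
        correction = -(math.pi * h / 6.0) * sum(np.diff(radii) ** 2)
        assert cone - trap == pytest.approx(correction, rel=1e-9)

    def test_pixel_count_equals_cylinder_when_radii_derive_from_areas(self):
        # r = sqrt(S/pi) makes pi*r^2 == S exactly, so the two baselines coincide
        rng = np.random.default_rng(5)
        areas = rng.uniform(10.0, 200.0, size=9)
        radii = np.sqrt(areas / math.pi)
        p = RadiusProfile(tuple(radii), (1.0,) * 8, tuple(areas))
        assert pixel_count_volume(p) == pytest.approx(stack_volume(p, "cylinder"), rel=1e-12)

    def test_pixel_count_uses_raw_areas_not_circle_fit(self):
        # decoupled areas (non-circular sections) separate the two baselines
        p = RadiusProfile((1.0, 1.0), (2.0,), (25.0, 25.0))
        assert pixel_count_volume(p) == pytest.approx(50.0)
        assert stack_volume(p, "cylinder") == pytest.approx(2 * math.pi)

    def test_single_slice_profile_rejected(self):
        p = RadiusProfile((1.0,), (), (math.pi,))
        with pytest.raises(ValueError):
            stack_volume(p, "cylinder")
        with pytest.raises(ValueError):
            pixel_count_volume(p)


class TestEstimateVolume:
    def test_total_is_exactly_mid_plus_caps(self, excluded_sphere_stack):
        stack, _ = excluded_sphere_stack
        for method, cap_mode in [
            ("pixel_count", "none"), ("cylinder", "none"),
            ("cone", "none"), ("cone", "literal"), ("cone", "geometric"),
        ]:
            est, _, _ = estimate_stack(stack, method, cap_mode)
            assert est.total == est.mid_volume + math.fsum(est.cap_volumes)

    def test_degenerate_caps_when_terminal_radii_near_zero(self):
        # sphere profile sampled down to tiny terminal radii: caps ~ 0
        zs = np.arange(-11.99, 12.0, 0.25)
        radii = np.sqrt(np.clip(144.0 - zs**2, 0, None))
        p = profile_from_radii(radii, [0.25] * (len(radii) - 1))
        est = estimate_volume(p, "cone", "geometric")
        assert est.cap_volume < 0.01 * est.total
        assert est.total == pytest.approx(stack_volume(p, "cone"), rel=0.01)

    def test_sphere_recovery_with_exclusion(self, excluded_sphere_stack):
        stack, true_mm3 = excluded_sphere_stack
        cone, _, _ = estimate_stack(stack, "cone", "geometric")
        cyl, _, _ = estimate_stack(stack, "cylinder", "none")
        assert cone.total == pytest.approx(true_mm3, rel=0.03)
        assert abs(cone.total - true_mm3) < abs(cyl.total - true_mm3)
        # cylinder stacking underestimates a convex body; caps recover the ends
        assert cyl.total < cone.total

    def test_literal_mode_uses_min_radius_as_shared_bound(self):
        p = profile_from_radii([3.0, 5.0, 4.0], [1.0, 1.0])
        est = estimate_volume(p, "cone", "literal")
        expected_cap = cap_volume(CapSpec(m=5.0, x1=3.0, mode="literal"))
        assert est.cap_volumes == (expected_cap, expected_cap)

    def test_geometric_mode_uses_per_end_terminal_radii(self):
        p = profile_from_radii([3.0, 5.0, 4.0], [1.0, 1.0])
        est = estimate_volume(p, "cone", "geometric")
        x1_lo = math.sqrt(25.0 - 9.0)
        x1_hi = math.sqrt(25.0 - 16.0)
        assert est.cap_volumes[0] == pytest.approx(cap_volume(CapSpec(m=5.0, x1=x1_lo)))
        assert est.cap_volumes[1] == pytest.approx(cap_volume(CapSpec(m=5.0, x1=x1_hi)))

    def test_flat_profile_warns_and_caps_as_hemispheres(self, caplog):
        p = profile_from_radii([2.0, 2.0], [1.0])
        with caplog.at_level("WARNING", logger="ocuvol"):
            est = estimate_volume(p, "cone", "geometric")
        assert "flat radius profile" in caplog.text
        assert est.cap_volume == pytest.approx(2 * (2 / 3) * math.pi * 8.0)

    def test_caps_require_cone_method(self):
        p = profile_from_radii([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            estimate_volume(p, "cylinder", "geometric")

    def test_all_zero_profile_rejected(self):
        p = RadiusProfile((0.0, 0.0), (1.0,), (0.0, 0.0))
        with pytest.raises(ValueError):
            estimate_volume(p, "cone", "none")

    def test_volume_estimate_conservation_enforced(self):
        with pytest.raises(ValueError):
            VolumeEstimate(method="cone", mid_volume=1.0, cap_volumes=(0.5,), total=2.0)
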