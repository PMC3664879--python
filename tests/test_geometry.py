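"""Geometry of radial-frequency contours: curvature, arcs, element placement."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from sampledshapes import (
    InfeasibleSpacingError,
    InvalidLayoutError,
    RFShapeSpec,
    apply_jitter,
    average_unsigned_curvature,
    contains_concavities,
    curvature_profile,
    find_inflections,
    layout_elements,
    perimeter,
    rf_radius,
    segment_arcs,
    signed_curvature,
    tangent_orientation,
)
from sampledshapes.geometry import arc_length, layout_from_spec, layout_to_csv, max_jitter_deg

TWO_PI = 2.0 * math.pi


def fd_curvature(shape, phi, h=1e-4):
    """Finite-difference curvature of the Cartesian contour (independent oracle)."""
    p = [shape.point(phi + k * h) for k in (-1, 0, 1)]
    d1 = (p[2] - p[0]) / (2 * h)
    d2 = (p[2] - 2 * p[1] + p[0]) / h**2
    num = d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0]
    return num / (d1[..., 0] ** 2 + d1[..., 1] ** 2) ** 1.5


shape_strategy = st.builds(
    RFShapeSpec,
    r0=st.floats(0.5, 10.0),
    amplitude=st.floats(0.0, 0.3),
    frequency=st.integers(0, 10),
    phase_deg=st.floats(0.0, 360.0),
)


class TestRadiusAndCurvature:
    def test_circle_radius_constant(self, circle):
        assert rf_radius(1.234, circle) == 2.7
        assert np.all(rf_radius(np.linspace(0, TWO_PI, 7), circle) == 2.7)

    def test_radius_at_modulation_extremes(self, rf4, rf8):
        # sin = +1 at phi = pi/(2N) for zero phase
        peak = rf_radius(math.pi / 8, rf4)
        assert peak == pytest.approx(2.7 * 1.18, abs=1e-12)
        trough = rf_radius(3 * math.pi / 16, rf8)
        assert trough == pytest.approx(2.7 * 0.9, abs=1e-12)

    def test_radius_periodicity(self, rf4):
        phi = np.linspace(0, TWO_PI, 13)
        np.testing.assert_allclose(
            rf_radius(phi, rf4), rf_radius(phi + TWO_PI / 4, rf4), atol=1e-12
        )

    def test_circle_curvature_is_inverse_radius(self, circle):
        phi = np.linspace(0, TWO_PI, 11)
        np.testing.assert_allclose(signed_curvature(phi, circle), 1 / 2.7, rtol=1e-14)

    def test_curvature_matches_finite_difference_oracle(self, rf4, rf8, circle):
        phi = np.linspace(0, TWO_PI, 4096, endpoint=False)
        for shape in (circle, rf4, rf8):
            exact = signed_curvature(phi, shape)
            # agreement to 1e-6 of the curvature scale (kappa passes through 0
            # at inflections, so a pure relative bound is ill-posed there)
            np.testing.assert_allclose(
                exact,
                fd_curvature(shape, phi),
                rtol=1e-6,
                atol=1e-6 * np.abs(exact).max(),
            )

    def test_curvature_zero_at_inflections(self, rf4):
        for phi in find_inflections(rf4):
            assert abs(signed_curvature(phi, rf4)) < 1e-10

    def test_radius_of_curvature_is_inverse_kappa(self, rf4):
        prof = curvature_profile(rf4)
        k = prof.kappa[np.abs(prof.kappa) > 1e-3]
        np.testing.assert_allclose(1.0 / np.abs(k), np.abs(1.0 / k))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shape=shape_strategy, frac=st.floats(0.0, 1.0))
    def test_curvature_oracle_property(self, shape, frac):
        phi = frac * TWO_PI
        assert signed_curvature(phi, shape) == pytest.approx(
            float(fd_curvature(shape, np.asarray(phi))), rel=1e-5, abs=1e-5
        )


class TestInflectionsAndArcs:
    def test_circle_has_no_inflections(self, circle):
        assert len(find_inflections(circle)) == 0

    @pytest.mark.parametrize("shape_name,count", [("rf4", 8), ("rf8", 16)])
    def test_high_amplitude_inflection_count(self, shapes, shape_name, count):
        assert len(find_inflections(shapes[shape_name])) == count

    def test_low_amplitude_shape_everywhere_convex(self):
        low = RFShapeSpec(r0=2.7, amplitude=0.03, frequency=4)
        assert not contains_concavities(low)
        assert len(find_inflections(low)) == 0
        assert len(segment_arcs(low)) == 1

    @pytest.mark.parametrize("shape_name,count", [("circle", 1), ("rf4", 8), ("rf8", 16)])
    def test_full_contour_arc_counts(self, shapes, shape_name, count):
        arcs = segment_arcs(shapes[shape_name])
        assert len(arcs) == count
        signs = [a.sign for a in arcs]
        if count > 1:
            assert all(s1 == -s2 for s1, s2 in zip(signs, signs[1:]))

    def test_arc_lengths_tile_the_perimeter(self, rf4, rf8, circle):
        for shape in (circle, rf4, rf8):
            total = sum(a.arc_length for a in segment_arcs(shape))
            assert total == pytest.approx(perimeter(shape), rel=1e-6)

    def test_half_span_of_rf4_contains_four_interior_arcs(self, rf4):
        arcs = segment_arcs(rf4, span=(0.0, math.pi))
        interior = [a for a in arcs if a.span > 1e-6]
        # half the shape: 4 full arcs plus partial end arcs
        assert 4 <= len(interior) <= 6
        total = sum(a.arc_length for a in arcs)
        assert total == pytest.approx(arc_length(rf4, 0.0, math.pi), rel=1e-9)

    def test_profile_extrema_signs(self, rf4, circle):
        prof = curvature_profile(rf4)
        assert prof.c_min < 0 < prof.c_max
        assert prof.c_abs_min < 5e-3  # grid sampling; exact zero sits at the inflection
        prof_c = curvature_profile(circle)
        assert prof_c.c_min == pytest.approx(prof_c.c_max)


class TestAverageCurvature:
    def test_circle_average_is_inverse_radius(self, circle):
        assert average_unsigned_curvature(circle) == pytest.approx(1 / 2.7, rel=1e-12)
        assert average_unsigned_curvature(circle, "polar") == pytest.approx(1 / 2.7)

    def test_average_matches_independent_quadrature(self, rf4):
        # piecewise smooth |kappa|: integrate per arc with adaptive quadrature
        infl = find_inflections(rf4)
        bounds = np.concatenate([infl, [infl[0] + TWO_PI]])
        num = den = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            num += quad(
                lambda p: abs(signed_curvature(p, rf4))
                * math.hypot(rf4.radius(p), rf4.radius_d1(p)),
                a,
                b,
            )[0]
            den += quad(lambda p: math.hypot(rf4.radius(p), rf4.radius_d1(p)), a, b)[0]
        assert average_unsigned_curvature(rf4) == pytest.approx(num / den, rel=1e-7)

    def test_regression_values_for_study_shapes(self, rf4, rf8):
        assert average_unsigned_curvature(rf4) == pytest.approx(0.6186, abs=2e-4)
        assert average_unsigned_curvature(rf8) == pytest.approx(1.1616, abs=2e-4)
        assert average_unsigned_curvature(rf4, "polar") == pytest.approx(0.6224, abs=2e-4)
        assert average_unsigned_curvature(rf8, "polar") == pytest.approx(1.2169, abs=2e-4)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        amplitude=st.floats(0.01, 0.3),
        frequency=st.integers(2, 8),
        scale=st.floats(0.2, 5.0),
    )
    def test_scale_invariance(self, amplitude, frequency, scale):
        a = RFShapeSpec(r0=2.7, amplitude=amplitude, frequency=frequency)
        b = RFShapeSpec(r0=2.7 * scale, amplitude=amplitude, frequency=frequency)
        assert average_unsigned_curvature(a) * a.r0 == pytest.approx(
            average_unsigned_curvature(b) * b.r0, rel=1e-10
        )


class TestPerimeter:
    def test_near_circle_perimeter_closed_form(self):
        # amplitude ~0 exercises the numeric table against 2*pi*r0
        near = RFShapeSpec(r0=2.7, amplitude=1e-12, frequency=4)
        assert perimeter(near) == pytest.approx(TWO_PI * 2.7, rel=1e-9)

    def test_modulation_lengthens_the_contour(self, circle, rf4, rf8):
        assert perimeter(circle) < perimeter(rf4) < perimeter(rf8)


class TestLayout:
    def test_five_elements_on_circle_mean_spacing(self, circle):
        layout = layout_elements(circle, 5)
        assert round(layout.mean_spacing, 1) == 3.2

    def test_equal_spacing_matches_chord_formula(self, circle):
        layout = layout_elements(circle, 25)
        expected = 2 * 2.7 * math.sin(math.pi / 25)
        assert layout.mean_spacing == pytest.approx(expected, rel=1e-9)

    def test_degenerate_layout_rejected(self, circle):
        with pytest.raises(InvalidLayoutError):
            layout_elements(circle, 1)

    def test_full_layout_equal_arc_intervals(self, rf4):
        layout = layout_elements(rf4, 9)
        s = [arc_length(rf4, layout.phi[0], p) for p in layout.phi]
        gaps = np.diff(s)
        np.testing.assert_allclose(gaps, perimeter(rf4) / 9, rtol=1e-6)

    def test_partial_walk_hits_target_chords(self, rf4):
        layout = layout_elements(rf4, 7, mode="partial", target_spacing=0.7)
        chords = np.hypot(*np.diff(layout.centers, axis=0).T)
        np.testing.assert_allclose(chords, 0.7, rtol=1e-8)
        assert not layout.closed
        assert 0 < layout.coverage < 1

    def test_partial_without_spacing_rejected(self, circle):
        with pytest.raises(InvalidLayoutError):
            layout_elements(circle, 7, mode="partial")

    def test_wrapping_walk_is_infeasible(self, circle):
        with pytest.raises(InfeasibleSpacingError):
            layout_elements(circle, 25, mode="partial", target_spacing=0.75)

    def test_spacing_beyond_diameter_is_infeasible(self, circle):
        with pytest.raises(InfeasibleSpacingError):
            layout_elements(circle, 3, mode="partial", target_spacing=6.0)

    def test_tangent_perpendicular_to_radius_on_circle(self, circle):
        for phi in (0.0, 1.0, 2.5):
            radial = math.degrees(phi) % 180.0
            tang = tangent_orientation(phi, circle)
            assert min(abs(tang - radial) % 180, 180 - abs(tang - radial) % 180) == pytest.approx(
                90.0, abs=1e-9
            )

    def test_tangent_fold_symmetry(self, circle, rf4):
        for shape in (circle, rf4):
            a = tangent_orientation(0.7, shape)
            b = tangent_orientation(0.7 + math.pi, shape)
            assert a == pytest.approx(b, abs=1e-9)

    def test_tangent_matches_numerical_derivative(self, rf4):
        h = 1e-7
        for phi in np.linspace(0, TWO_PI, 17):
            p0, p1 = rf4.point(phi - h), rf4.point(phi + h)
            ref = math.degrees(math.atan2(p1[1] - p0[1], p1[0] - p0[0])) % 180.0
            got = tangent_orientation(phi, rf4)
            diff = abs(got - ref) % 180.0
            assert min(diff, 180.0 - diff) < 1e-4


class _ZeroRand:
    def random(self, n=None):
        return np.zeros(n) if n is not None else 0.0


class TestJitter:
    @pytest.mark.parametrize("n,bound", [(7, 17.5714285714), (40, 0.6)])
    def test_jitter_bound_formula(self, n, bound):
        assert max_jitter_deg(n) == pytest.approx(bound, abs=1e-9)

    @pytest.mark.parametrize("n", [7, 40])
    def test_jitter_respects_bound(self, circle, rng, n):
        layout = layout_elements(circle, n)
        jittered = apply_jitter(layout, rng)
        delta = np.degrees(jittered.phi - layout.phi)
        assert np.all(delta >= 0)
        assert np.all(delta <= max_jitter_deg(n) + 1e-12)

    def test_zero_jitter_is_identity(self, circle):
        layout = layout_elements(circle, 7)
        jittered = apply_jitter(layout, _ZeroRand())
        np.testing.assert_array_equal(jittered.phi, layout.phi)
        np.testing.assert_array_equal(jittered.centers, layout.centers)

    def test_jitter_reproducible_bit_for_bit(self, rf4):
        layout = layout_elements(rf4, 13)
        a = apply_jitter(layout, np.random.default_rng(99))
        b = apply_jitter(layout, np.random.default_rng(99))
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_large_n_clamps_with_warning(self, circle):
        layout = layout_elements(circle, 60)
        with pytest.warns(UserWarning):
            jittered = apply_jitter(layout, np.random.default_rng(5))
        np.testing.assert_array_equal(jittered.phi, layout.phi)

    def test_ordering_preserved_for_dense_partial_layout(self, rf4):
        layout = layout_elements(rf4, 7, mode="partial", target_spacing=0.4)
        jittered = apply_jitter(layout, np.random.default_rng(3))
        assert np.all(np.diff(jittered.phi) > 0)


class TestSerialization:
    def test_shape_json_round_trip(self, rf4):
        assert RFShapeSpec.from_json(rf4.to_json()) == rf4

    def test_layout_from_spec_with_jitter_seed(self, tmp_path):
        spec = {
            "r0_deg": 2.7,
            "amplitude": 0.18,
            "radial_frequency": 4,
            "phase_deg": 0.0,
            "n_elements": 9,
            "mode": "full",
            "jitter_seed": 42,
        }
        a = layout_from_spec(spec)
        b = layout_from_spec(json.loads(json.dumps(spec)))
        np.testing.assert_array_equal(a.phi, b.phi)
        path = tmp_path / "layout.csv"
        layout_to_csv(a, path)
        header = path.read_text().splitlines()[0]
        assert header == "element_index,phi_deg,x_deg,y_deg,tangent_deg"
        assert len(path.read_text().splitlines()) == 10

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(ValueError):
            RFShapeSpec(r0=-1.0)
        with pytest.raises(ValueError):
            RFShapeSpec(r0=1.0, amplitude=-0.1)
        with pytest.raises(ValueError):
            RFShapeSpec(r0=1.0, frequency=-2)
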