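"""Geometry engine: closed-form examples, oracles, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (principal_angle, random_nested_section,
                      random_star_polygon, rasterized_moments, regular_ngon)
from skeletochron.contours import (AnnularSection, Contour, ContourError,
                                   cortical_area, enclosed_area, perimeter,
                                   principal_frame, radial_profile,
                                   region_centroid)

SQUARE = [[0, 0], [1, 0], [1, 1], [0, 1]]
TRIANGLE_345 = [[0, 0], [4, 0], [0, 3]]


class TestPerimeterAndArea:
    @pytest.mark.parametrize("vertices, expect_p, expect_a", [
        (SQUARE, 4.0, 1.0),
        (TRIANGLE_345, 12.0, 6.0),
    ])
    def test_closed_forms(self, vertices, expect_p, expect_a):
        c = Contour(vertices)
        assert perimeter(c) == pytest.approx(expect_p)
        assert enclosed_area(c) == pytest.approx(expect_a)

    def test_regular_100gon_matches_ngon_formulas(self):
        c = regular_ngon(100)
        assert perimeter(c) == pytest.approx(200 * math.sin(math.pi / 100),
                                             rel=1e-12)
        assert enclosed_area(c) == pytest.approx(
            50 * math.sin(2 * math.pi / 100), rel=1e-12)

    def test_orientation_independent(self):
        cw = Contour(list(reversed(SQUARE)))
        assert enclosed_area(cw) == pytest.approx(1.0)
        assert perimeter(cw) == pytest.approx(4.0)

    @pytest.mark.parametrize("vertices", [[[0, 0], [1, 1]],
                                          [[0, 0], [1, 0], [2, 0]]])
    def test_degenerate_contours_rejected(self, vertices):
        with pytest.raises(ContourError):
            Contour(vertices)

    def test_self_intersection_rejected(self):
        with pytest.raises(ContourError):
            Contour([[0, 0], [1, 1], [1, 0], [0, 1]])  # bow-tie

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), angle=st.floats(0, 2 * math.pi),
           tx=st.floats(-5, 5), ty=st.floats(-5, 5))
    def test_rigid_motion_invariance_and_isoperimetry(self, seed, angle,
                                                      tx, ty):
        rng = np.random.default_rng(seed)
        c = random_star_polygon(rng, radius=rng.uniform(0.5, 3.0))
        moved = c.transformed(rotation=angle, translation=(tx, ty))
        assert perimeter(moved) == pytest.approx(perimeter(c), rel=1e-9)
        assert enclosed_area(moved) == pytest.approx(enclosed_area(c),
                                                     rel=1e-9)
        assert perimeter(c) ** 2 >= 4 * math.pi * enclosed_area(c)


class TestCorticalArea:
    def test_square_annulus(self):
        outer = Contour([[-1, -1], [1, -1], [1, 1], [-1, 1]])
        inner = Contour([[-.5, -.5], [.5, -.5], [.5, .5], [-.5, .5]])
        assert cortical_area(AnnularSection(outer, inner)) == pytest.approx(3.0)

    def test_absent_inner_is_identity(self):
        assert cortical_area(AnnularSection(Contour(SQUARE))) == pytest.approx(1.0)

    def test_concentric_100gons(self):
        s = AnnularSection(regular_ngon(100, 2.0), regular_ngon(100, 1.0))
        assert cortical_area(s) == pytest.approx(
            150 * math.sin(2 * math.pi / 100), rel=1e-12)

    def test_additivity(self):
        rng = np.random.default_rng(5)
        s = random_nested_section(rng)
        assert (cortical_area(s) + enclosed_area(s.inner)
                == pytest.approx(enclosed_area(s.outer), rel=1e-12))

    def test_nesting_violation_rejected(self):
        with pytest.raises(ContourError):
            AnnularSection(Contour(SQUARE),
                           Contour([[5, 5], [6, 5], [6, 6], [5, 6]]))


class TestRegionCentroid:
    def test_concentric_squares_center(self):
        outer = Contour([[-2, -2], [2, -2], [2, 2], [-2, 2]])
        inner = Contour([[-1, -1], [1, -1], [1, 1], [-1, 1]])
        c = region_centroid(AnnularSection(outer, inner))
        assert c == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_offset_inner_composition_formula(self):
        outer = Contour([[-2, -2], [2, -2], [2, 2], [-2, 2]])
        inner = Contour([[.5, -.5], [1.5, -.5], [1.5, .5], [.5, .5]])
        c = region_centroid(AnnularSection(outer, inner))
        assert c == pytest.approx([-1 / 15, 0.0], abs=1e-12)

    def test_shapely_cross_check(self):
        # independent route: shapely's polygon-with-hole centroid
        rng = np.random.default_rng(11)
        s = random_nested_section(rng)
        from shapely.geometry import Polygon
        hole = Polygon(s.outer.vertices,
                       holes=[s.inner.vertices[::-1]])
        c = region_centroid(s)
        assert c == pytest.approx([hole.centroid.x, hole.centroid.y],
                                  abs=1e-9)


class TestPrincipalFrame:
    def test_rectangle_axes(self):
        rect = Contour([[-2, -1], [2, -1], [2, 1], [-2, 1]])
        f = principal_frame(AnnularSection(rect))
        assert abs(f.major_axis @ [1, 0]) == pytest.approx(1.0)
        assert abs(f.minor_axis @ [0, 1]) == pytest.approx(1.0)

    @pytest.mark.parametrize("deg", [30, 75, 120])
    def test_rotation_equivariance(self, deg):
        rect = Contour([[-2, -1], [2, -1], [2, 1], [-2, 1]])
        rot = rect.transformed(rotation=math.radians(deg))
        f = principal_frame(AnnularSection(rot))
        assert principal_angle(f.major_axis) == pytest.approx(
            math.radians(deg) % math.pi, abs=1e-9)

    def test_isotropic_tie_break_is_coordinate_frame(self):
        square = Contour([[-1, -1], [1, -1], [1, 1], [-1, 1]])
        f = principal_frame(AnnularSection(square))
        assert f.major_axis == pytest.approx([1.0, 0.0])
        assert f.minor_axis == pytest.approx([0.0, 1.0])

    def test_elliptical_annulus_major_axis(self):
        th = np.linspace(0, 2 * math.pi, 400, endpoint=False)
        outer = Contour(np.column_stack([3 * np.cos(th), np.sin(th)]))
        inner = Contour(np.column_stack([1.5 * np.cos(th), .5 * np.sin(th)]))
        f = principal_frame(AnnularSection(outer, inner))
        assert principal_angle(f.major_axis) == pytest.approx(0.0, abs=1e-6)

    def test_rasterization_oracle_agreement(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            s = random_nested_section(rng)
            f = principal_frame(s)
            area, cen, (ixx, iyy, ixy) = rasterized_moments(s)
            assert f.centroid == pytest.approx(cen, abs=1e-3)
            t = np.array([[iyy, ixy], [ixy, ixx]])
            w, vec = np.linalg.eigh(t)
            ref = vec[:, 1]
            diff = abs(principal_angle(f.major_axis) - principal_angle(ref))
            assert min(diff, math.pi - diff) < 1e-3


class TestRadialProfile:
    def test_circle_rays_equal_radius(self):
        c = regular_ngon(720, radius=2.0)
        f = principal_frame(AnnularSection(c))
        p = radial_profile(f, c)
        assert p.distances == pytest.approx((2, 2, 2, 2), rel=1e-4)
        assert p.mean == pytest.approx(2.0, rel=1e-4)

    def test_ellipse_rays_are_semiaxes(self):
        th = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        c = Contour(np.column_stack([3 * np.cos(th), np.sin(th)]))
        f = principal_frame(AnnularSection(c))
        p = radial_profile(f, c)
        assert sorted(p.distances) == pytest.approx([1, 1, 3, 3], rel=1e-4)
        assert p.mean == pytest.approx(2.0, rel=1e-4)

    def test_matches_brute_force_edge_scan(self):
        rng = np.random.default_rng(3)
        outer = random_star_polygon(rng, radius=2.0)
        inner = random_star_polygon(rng, radius=0.6)
        f = principal_frame(AnnularSection(outer, inner))
        p = radial_profile(f, outer)
        # brute force: intersect every edge segment with each ray
        for d, direction in zip(p.distances,
                                (f.major_axis, -f.major_axis,
                                 f.minor_axis, -f.minor_axis)):
            best = np.inf
            v = outer.vertices
            for i in range(len(v)):
                pq = (v[i], v[(i + 1) % len(v)])
                e = pq[1] - pq[0]
                A = np.column_stack([direction, -e])
                if abs(np.linalg.det(A)) < 1e-14:
                    continue
                t, u = np.linalg.solve(A, pq[0] - f.centroid)
                if t > 0 and 0 <= u < 1:
                    best = min(best, t)
            assert d == pytest.approx(best, rel=1e-12)

    def test_nested_contours_monotone_rays(self):
        rng = np.random.default_rng(8)
        s = random_nested_section(rng)
        f = principal_frame(s)
        p_in = radial_profile(f, s.inner)
        p_out = radial_profile(f, s.outer)
        assert all(a < b for a, b in zip(p_in.distances, p_out.distances))

    def test_centroid_outside_contour_errors(self):
        c = Contour(SQUARE)
        f = principal_frame(AnnularSection(
            Contour([[5, 5], [6, 5], [6, 6], [5, 6]])))
        with pytest.raises(ContourError):
            radial_profile(f, c)
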