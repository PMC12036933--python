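"""Contour normalization, size measures, Feret diameters, descriptors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somamorph.geometry import (
    InvalidContourError,
    area,
    descriptors,
    feret_max,
    feret_min,
    normalize_contour,
    perimeter,
    regular_polygon,
)
from .conftest import random_star_polygon

SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


class TestNormalize:
    def test_clockwise_input_is_reoriented(self):
        c = normalize_contour(SQUARE[::-1])
        assert area(c) == pytest.approx(1.0)
        # positive orientation: shoelace of stored vertices is positive
        v = c.vertices
        assert 0.5 * np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]) > 0

    def test_duplicate_closing_vertex_dropped(self):
        c = normalize_contour(SQUARE + [SQUARE[0]])
        assert len(c) == 4

    def test_consecutive_duplicates_dropped(self):
        c = normalize_contour([SQUARE[0], SQUARE[0], *SQUARE[1:]])
        assert len(c) == 4

    def test_bowtie_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(InvalidContourError):
            normalize_contour(bowtie)

    @pytest.mark.parametrize(
        "verts",
        [
            [(0, 0), (1, 1)],
            [(0, 0), (0, 0), (1, 1), (1, 1)],
            [(0, 0), (1, 0), (2, 0)],  # collinear: zero area
        ],
    )
    def test_degenerate_rejected(self, verts):
        with pytest.raises(InvalidContourError):
            normalize_contour(verts)


class TestSizeMeasures:
    def test_unit_square(self):
        c = normalize_contour(SQUARE)
        assert area(c) == pytest.approx(1.0)
        assert perimeter(c) == pytest.approx(4.0)

    def test_rectangle(self):
        c = normalize_contour([(0, 0), (2, 0), (2, 1), (0, 1)])
        assert area(c) == pytest.approx(2.0)

    def test_fine_polygon_approaches_circle(self):
        c = regular_polygon(10_000, radius=1.0)
        assert perimeter(c) == pytest.approx(2.0 * np.pi, rel=1e-6)
        assert area(c) == pytest.approx(np.pi, rel=1e-6)

    def test_area_matches_triangulation_oracle(self, rng):
        """Shoelace area equals the sum of fan-triangle areas (and shapely)."""
        for _ in range(30):
            c = random_star_polygon(rng)
            v = c.vertices
            tri = 0.0
            for i in range(1, len(v) - 1):
                a, b = v[i] - v[0], v[i + 1] - v[0]
                tri += 0.5 * (a[0] * b[1] - a[1] * b[0])
            assert area(c) == pytest.approx(abs(tri), rel=1e-12)
            assert area(c) == pytest.approx(c.to_shapely().area, rel=1e-12)

    def test_perimeter_matches_edge_oracle(self, rng):
        for _ in range(30):
            c = random_star_polygon(rng)
            v = c.vertices
            edges = sum(
                math.dist(v[i], v[(i + 1) % len(v)]) for i in range(len(v))
            )
            assert perimeter(c) == pytest.approx(edges, rel=1e-12)


class TestFeret:
    def test_unit_square(self):
        c = normalize_contour(SQUARE)
        assert feret_max(c) == pytest.approx(np.sqrt(2.0))
        assert feret_min(c) == pytest.approx(1.0)

    def test_rectangle_width(self):
        c = normalize_contour([(0, 0), (2, 0), (2, 1), (0, 1)])
        assert feret_min(c) == pytest.approx(1.0)
        assert feret_max(c) == pytest.approx(np.sqrt(5.0))

    def test_discretized_circle_diameter(self):
        c = regular_polygon(4096, radius=3.0)
        assert feret_max(c) == pytest.approx(6.0, rel=1e-5)
        assert feret_min(c) == pytest.approx(6.0, rel=1e-5)

    def test_calipers_equal_brute_force(self, rng):
        """Calipers Feret max equals the all-vertex-pairs maximum and Feret
        min equals the exhaustive per-hull-edge width minimum."""
        from scipy.spatial import ConvexHull
        from scipy.spatial.distance import pdist

        for _ in range(100):
            c = random_star_polygon(rng)
            assert feret_max(c) == pytest.approx(pdist(c.vertices).max(), abs=1e-10)
            hull = c.vertices[ConvexHull(c.vertices).vertices]
            h = len(hull)
            widths = []
            for i in range(h):
                e = hull[(i + 1) % h] - hull[i]
                d = np.abs(
                    e[0] * (hull[:, 1] - hull[i, 1]) - e[1] * (hull[:, 0] - hull[i, 0])
                ) / np.hypot(*e)
                widths.append(d.max())
            assert feret_min(c) == pytest.approx(min(widths), abs=1e-10)

    def test_min_feret_matches_angular_sweep(self, rng):
        """Width equals the projection-minimum over a fine two-stage angular
        sweep (coarse grid, then refinement around the argmin)."""
        for _ in range(5):
            c = random_star_polygon(rng, n_max=20)
            v = c.vertices
            n_ang = 100_000
            ang = np.linspace(0.0, np.pi, n_ang, endpoint=False)
            proj = v @ np.array([np.cos(ang), np.sin(ang)])
            w = proj.max(0) - proj.min(0)
            k = int(np.argmin(w))
            fine = np.linspace(ang[k] - 2 * np.pi / n_ang, ang[k] + 2 * np.pi / n_ang, 4001)
            projf = v @ np.array([np.cos(fine), np.sin(fine)])
            wmin = float((projf.max(0) - projf.min(0)).min())
            assert feret_min(c) == pytest.approx(wmin, rel=1e-6)


class TestDescriptors:
    def test_unit_square_closed_forms(self):
        m = descriptors(normalize_contour(SQUARE))
        assert m.area == pytest.approx(1.0)
        assert m.perimeter == pytest.approx(4.0)
        assert m.feret_max == pytest.approx(np.sqrt(2.0))
        assert m.feret_min == pytest.approx(1.0)
        assert m.aspect_ratio == pytest.approx(1.0 / np.sqrt(2.0))
        assert m.compactness == pytest.approx(np.sqrt(2.0 / np.pi))
        assert m.roundness == pytest.approx(2.0 / np.pi)
        assert m.shape_factor == pytest.approx(4.0)
        assert m.form_factor == pytest.approx(np.pi / 4.0)

    def test_circle_anchors(self):
        m = descriptors(regular_polygon(12_000, radius=5.5))
        assert round(m.shape_factor, 2) == 3.54
        assert m.shape_factor == pytest.approx(2.0 * np.sqrt(np.pi), rel=1e-4)
        for value in (m.form_factor, m.compactness, m.roundness, m.aspect_ratio):
            assert value == pytest.approx(1.0, abs=1e-3)

    def test_roundness_is_compactness_squared(self, rng):
        for _ in range(25):
            m = descriptors(random_star_polygon(rng))
            assert m.roundness == pytest.approx(m.compactness**2, rel=1e-9)

    def test_isoperimetric_bounds(self, rng):
        for _ in range(25):
            m = descriptors(random_star_polygon(rng))
            assert m.form_factor <= 1.0 + 1e-12
            assert m.shape_factor >= 2.0 * np.sqrt(np.pi) - 1e-12
            assert 0.0 < m.aspect_ratio <= 1.0
            assert 0.0 < m.compactness <= 1.0 + 1e-12
            assert m.feret_min <= m.feret_max

    @settings(max_examples=30, deadline=None)
    @given(
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
        angle=st.floats(0, 2 * np.pi),
        poly_seed=st.integers(0, 100),
    )
    def test_rigid_motion_invariance(self, dx, dy, angle, poly_seed):
        """All nine metrics are unchanged by translation + rotation."""
        c = random_star_polygon(np.random.default_rng(poly_seed))
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = type(c)(c.vertices @ rot.T + np.array([dx, dy]))
        m0, m1 = descriptors(c).as_dict(), descriptors(moved).as_dict()
        for k in m0:
            assert m1[k] == pytest.approx(m0[k], rel=1e-9, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.01, 100.0), poly_seed=st.integers(0, 100))
    def test_scale_covariance(self, scale, poly_seed):
        """Area scales by s², lengths by s, dimensionless descriptors fixed."""
        c = random_star_polygon(np.random.default_rng(poly_seed))
        scaled = type(c)(c.vertices * scale)
        m0, m1 = descriptors(c), descriptors(scaled)
        assert m1.area == pytest.approx(m0.area * scale**2, rel=1e-9)
        assert m1.perimeter == pytest.approx(m0.perimeter * scale, rel=1e-9)
        assert m1.feret_max == pytest.approx(m0.feret_max * scale, rel=1e-9)
        assert m1.feret_min == pytest.approx(m0.feret_min * scale, rel=1e-9)
        for k in ("aspect_ratio", "compactness", "roundness", "shape_factor", "form_factor"):
            assert getattr(m1, k) == pytest.approx(getattr(m0, k), rel=1e-9)

    def test_radial_noise_monotone_in_complexity(self):
        """High-frequency radial noise on a circle raises shape factor and
        lowers form factor, monotonically in amplitude (averaged over seeds)."""
        n = 512
        theta = 2.0 * np.pi * np.arange(n) / n
        amps = (0.0, 0.02, 0.05)
        mean_sf, mean_ff = [], []
        for amp in amps:
            sf, ff = [], []
            for seed in range(100):
                rng = np.random.default_rng(seed)
                r = 1.0 + amp * np.cos(25 * theta + rng.uniform(0, 2 * np.pi))
                c = normalize_contour(
                    np.column_stack([r * np.cos(theta), r * np.sin(theta)])
                )
                m = descriptors(c)
                sf.append(m.shape_factor)
                ff.append(m.form_factor)
            mean_sf.append(np.mean(sf))
            mean_ff.append(np.mean(ff))
        assert mean_sf[0] < mean_sf[1] < mean_sf[2]
        assert mean_ff[0] > mean_ff[1] > mean_ff[2]
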