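"""Contour tracing, turning curvature and bending energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from blossddnet.geometry import (
    Contour,
    bending_energy,
    edge_vectors,
    gt_boundary_map,
    trace_contours,
    turning_curvature,
)
from blossddnet.geometry import DegenerateContourError


SQUARE = Contour(np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=float))


class TestTraceContours:
    def test_empty_mask_yields_no_contours(self):
        assert trace_contours(np.zeros((5, 5), dtype=int)) == []

    def test_single_pixel_is_a_one_vertex_contour(self):
        m = np.zeros((3, 3), dtype=int)
        m[1, 1] = 1
        (c,) = trace_contours(m, min_length=1)
        assert c.m == 1
        assert c.vertices.tolist() == [[1.0, 1.0]]

    def test_solid_square_border_in_adjacency_order(self):
        # hand-derived Moore trace of a 3x3 solid square: its 8 border pixels
        m = np.zeros((5, 5), dtype=int)
        m[1:4, 1:4] = 1
        (c,) = trace_contours(m)
        expected = {(1, 1), (1, 2), (1, 3), (2, 3), (3, 3), (3, 2), (3, 1), (2, 1)}
        got = {tuple(int(x) for x in v) for v in c.vertices}
        assert got == expected
        assert c.m == 8
        # consecutive vertices are 8-adjacent, including the closing edge
        v = c.vertices
        steps = np.abs(np.roll(v, -1, axis=0) - v).max(axis=1)
        assert (steps == 1).all()

    def test_min_length_drops_short_contours(self):
        m = np.zeros((8, 8), dtype=int)
        m[1, 1] = 1  # single-pixel noise
        m[3:7, 3:7] = 1  # real component
        contours = trace_contours(m, min_length=8)
        assert len(contours) == 1
        assert contours[0].m >= 8

    def test_non_binary_input_names_offending_values(self):
        m = np.zeros((3, 3), dtype=int)
        m[0, 0] = 7
        with pytest.raises(ValueError, match="7"):
            trace_contours(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_traced_contour_encloses_rendered_polygon(self, seed):
        # oracle: flood fill of the rendered convex polygon
        rng = np.random.default_rng(seed)
        center = np.array([16.0, 16.0])
        angles = np.sort(rng.uniform(0, 2 * np.pi, 7))
        radii = rng.uniform(5, 10, 7)
        rows = center[0] + radii * np.sin(angles)
        cols = center[1] + radii * np.cos(angles)
        mask = np.zeros((32, 32), dtype=np.uint8)
        rr, cc = draw_polygon(rows, cols, shape=mask.shape)
        mask[rr, cc] = 1
        (c,) = trace_contours(mask)
        filled = np.zeros_like(mask)
        v = c.vertices.astype(int)
        filled[v[:, 0], v[:, 1]] = 1
        inner = mask & ~filled
        lab, n = ndimage.label(inner)
        fill = filled.copy()
        for i in range(1, n + 1):
            fill[lab == i] = 1  # every interior component is enclosed
        assert np.array_equal(fill, mask)


class TestEdgeVectors:
    def test_square_interior_vertex(self):
        v_prev, v_next = edge_vectors(SQUARE, 1)
        assert v_prev.tolist() == [0, 1]
        assert v_next.tolist() == [1, 0]

    def test_cyclic_wrap_at_first_vertex(self):
        v_prev, v_next = edge_vectors(SQUARE, 0)
        assert v_prev.tolist() == [-1, 0]
        assert v_next.tolist() == [0, 1]

    def test_closed_polygon_edges_telescope_to_zero(self):
        rng = np.random.default_rng(0)
        verts = rng.integers(-20, 20, size=(11, 2)).astype(float)
        verts = verts[np.any(np.diff(np.vstack([verts, verts[:1]]), axis=0) != 0, axis=1)]
        c = Contour(verts)
        total = np.sum([edge_vectors(c, i)[1] for i in range(c.m)], axis=0)
        assert np.allclose(total, 0.0)

    def test_degenerate_contour_rejected(self):
        c = Contour(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(DegenerateContourError):
            edge_vectors(c, 0)


class TestTurningCurvature:
    def test_collinear_gives_zero(self):
        c = Contour(np.array([[0, 0], [0, 1], [0, 2], [1, 2], [1, 0]], dtype=float))
        assert turning_curvature(c)[1] == pytest.approx(0.0, abs=1e-15)

    def test_right_angle_unit_edges_is_exactly_two(self):
        k = turning_curvature(SQUARE)
        assert np.allclose(k, 2.0)

    def test_regular_hexagon_matches_closed_form(self, regular_polygon):
        c = Contour(regular_polygon(6))
        assert np.allclose(turning_curvature(c), 2 * np.tan(np.pi / 6), atol=1e-12)

    def test_matches_angle_oracle_on_random_triples(self):
        # oracle: 2*tan(theta/2) with theta from the normalized dot product;
        # non-degenerate means bounded away from the reversal theta = pi,
        # where arccos itself loses the digits the comparison needs
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 10_000:
            pts = rng.integers(-50, 51, size=(3, 2)).astype(float)
            a, b = pts[1] - pts[0], pts[2] - pts[1]
            la, lb = np.linalg.norm(a), np.linalg.norm(b)
            if la == 0 or lb == 0:
                continue
            cosang = np.clip(np.dot(a, b) / (la * lb), -1.0, 1.0)
            theta = np.arccos(cosang)
            if theta > 3.0:
                continue
            c = Contour(np.vstack([pts, pts[0] + [97.0, -91.0]]))
            got = turning_curvature(c)[1]
            assert got == pytest.approx(2 * np.tan(theta / 2), abs=1e-9)
            checked += 1

    def test_reversal_capped_with_warning(self):
        c = Contour(np.array([[0, 0], [0, 2], [0, 1]], dtype=float))
        with pytest.warns(RuntimeWarning, match="capped"):
            k = turning_curvature(c)
        assert k.max() == pytest.approx(1e3)


class TestBendingEnergy:
    def test_unit_square_corners(self):
        prof = bending_energy(SQUARE)
        assert np.allclose(prof.be, 2.0)
        assert prof.mean_be == pytest.approx(2.0)
        assert prof.total_be == pytest.approx(8.0)

    def test_regular_mgon_matches_closed_form(self, regular_polygon):
        # total BE of a regular m-gon on a radius-R circle: m*tan^2(pi/m)/(R*sin(pi/m))
        m, big_r = 720, 50.0
        prof = bending_energy(Contour(regular_polygon(m, big_r)))
        closed_form = m * np.tan(np.pi / m) ** 2 / (big_r * np.sin(np.pi / m))
        assert prof.total_be == pytest.approx(closed_form, rel=1e-9)
        assert prof.total_be == pytest.approx(np.pi / big_r, rel=1e-4)

    def test_straight_runs_contribute_zero(self):
        c = Contour(
            np.array([[0, 0], [0, 5], [0, 10], [10, 10], [10, 0]], dtype=float)
        )
        assert bending_energy(c).be[1] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 7.25])
    def test_scaling_divides_be_by_scale(self, scale, regular_polygon):
        verts = regular_polygon(12, 5.0)
        base = bending_energy(Contour(verts)).be
        scaled = bending_energy(Contour(verts * scale)).be
        assert np.allclose(scaled, base / scale, rtol=1e-9)

    def test_rotation_translation_invariance(self, regular_polygon):
        rng = np.random.default_rng(3)
        verts = regular_polygon(9, 4.0) + rng.normal(0, 0.3, (9, 2))
        base = bending_energy(Contour(verts))
        ang = 0.77
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = verts @ rot.T + np.array([13.0, -4.5])
        prof = bending_energy(Contour(moved))
        assert np.allclose(prof.k, base.k, atol=1e-9)
        assert np.allclose(prof.be, base.be, atol=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        m=st.integers(5, 40),
        scale=st.floats(0.25, 20.0),
        angle=st.floats(0.0, 6.28),
        seed=st.integers(0, 2**16),
    )
    def test_similarity_transform_properties(self, m, scale, angle, seed):
        # k is invariant under rotation+translation+scaling; be scales as 1/s
        rng = np.random.default_rng(seed)
        theta = np.sort(rng.uniform(0, 2 * np.pi, m))
        if np.min(np.diff(theta, append=theta[0] + 2 * np.pi)) < 1e-3:
            return  # nearly duplicate vertices: outside the contract
        verts = np.column_stack([np.cos(theta), np.sin(theta)]) * 5.0
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = verts @ rot.T * scale + np.array([3.0, -8.0])
        base = bending_energy(Contour(verts))
        xformed = bending_energy(Contour(moved))
        assert np.allclose(xformed.k, base.k, atol=1e-8)
        assert np.allclose(xformed.be, base.be / scale, rtol=1e-6)

    def test_profile_bookkeeping(self, regular_polygon):
        prof = bending_energy(Contour(regular_polygon(10, 3.0)))
        assert prof.m == 10
        assert (prof.be >= 0).all()
        assert prof.mean_be == pytest.approx(prof.total_be / prof.m)


class TestGtBoundaryMap:
    def test_all_background_gives_all_zero(self):
        assert gt_boundary_map(np.zeros((6, 6), dtype=int), 1).sum() == 0

    def test_single_instance_border_pixels(self):
        # brute-force count: a 4x4 block has 12 border pixels
        lab = np.zeros((10, 10), dtype=int)
        lab[3:7, 3:7] = 1
        b = gt_boundary_map(lab, thickness=1)
        assert b.sum() == 12
        assert b[4:6, 4:6].sum() == 0  # interior stays clear

    def test_touching_instances_mark_both_sides(self):
        lab = np.zeros((6, 8), dtype=int)
        lab[1:5, 1:4] = 1
        lab[1:5, 4:7] = 2
        b = gt_boundary_map(lab, thickness=1)
        assert b[1:5, 3].all() and b[1:5, 4].all()

    def test_thickness_dilates(self):
        lab = np.zeros((12, 12), dtype=int)
        lab[3:9, 3:9] = 1
        assert gt_boundary_map(lab, 2).sum() > gt_boundary_map(lab, 1).sum()

    def test_invalid_thickness_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            gt_boundary_map(np.zeros((3, 3), dtype=int), 0)
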