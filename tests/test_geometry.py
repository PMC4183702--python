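"""Fan-beam geometry and the Siddon intersection-length projector."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, box

import fewviewct as fv
from fewviewct.geometry import _clip_to_box


class TestViewAngles:
    def test_four_views_hit_quadrant_axes(self):
        np.testing.assert_allclose(fv.view_angles(4), np.deg2rad([0, 90, 180, 270]))

    def test_forty_views_spaced_nine_degrees_full_circle(self):
        a = fv.view_angles(40)
        assert np.rad2deg(a[1] - a[0]) == pytest.approx(9.0)
        assert a[0] == 0.0 and a[-1] == pytest.approx(2 * np.pi * 39 / 40)

    def test_single_view_is_zero(self):
        np.testing.assert_array_equal(fv.view_angles(1), [0.0])

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            fv.view_angles(0)


class TestRaySegment:
    def test_central_bin_passes_through_axis(self, tiny_system):
        _, grid, geom = tiny_system
        for view in range(geom.n_views):
            p0, p1 = fv.ray_segment(geom, grid, view, geom.detector_bins // 2)
            d = p1 - p0
            dist = abs(d[0] * (-p0[1]) - d[1] * (-p0[0])) / np.hypot(*d)
            assert dist < 1e-12 * geom.source_to_axis

    def test_opposed_views_give_antiparallel_central_rays(self, tiny_system):
        _, grid, _ = tiny_system
        geom = fv.FanBeamGeometry(40.0, 11, 1.0, fv.view_angles(2))  # 0 and 180 deg
        a0, b0 = fv.ray_segment(geom, grid, 0, 5)
        a1, b1 = fv.ray_segment(geom, grid, 1, 5)
        d0 = (b0 - a0) / np.linalg.norm(b0 - a0)
        d1 = (b1 - a1) / np.linalg.norm(b1 - a1)
        np.testing.assert_allclose(d0, -d1, atol=1e-12)

    def test_detector_footprint_span(self):
        geom = fv.FanBeamGeometry(293.1, 1025, 0.05, fv.view_angles(1))
        off = geom.bin_offsets()
        assert off[-1] - off[0] == pytest.approx((1025 - 1) * 0.05)
        assert geom.detector_span == pytest.approx(1025 * 0.05)

    def test_out_of_range_indices_rejected(self, tiny_system):
        _, grid, geom = tiny_system
        with pytest.raises(IndexError):
            fv.ray_segment(geom, grid, geom.n_views, 0)
        with pytest.raises(IndexError):
            fv.ray_segment(geom, grid, 0, geom.detector_bins)


class TestSiddonTrace:
    def test_axis_aligned_ray_crosses_full_row(self):
        grid = fv.ImageGrid(np.zeros((8, 8)), 0.5)
        y = 0.75  # centre of row 2
        idx, ln = fv.siddon_trace(grid, (np.array([-10.0, y]), np.array([10.0, y])))
        assert len(idx) == 8
        np.testing.assert_allclose(ln, 0.5)
        np.testing.assert_array_equal(np.sort(idx) // 8, 2)

    def test_main_diagonal_of_two_by_two(self):
        h = 1.5
        grid = fv.ImageGrid(np.zeros((2, 2)), h)
        idx, ln = fv.siddon_trace(grid, (np.array([-5.0, 5.0]), np.array([5.0, -5.0])))
        assert sorted(idx) == [0, 3]
        np.testing.assert_allclose(ln, h * math.sqrt(2))

    def test_chord_conservation_against_analytic_clip(self, rng):
        grid = fv.ImageGrid(np.zeros((16, 16)), 0.7)
        half = grid.half_extent
        bbox = box(-half, -half, half, half)
        for _ in range(1000):
            ang = rng.uniform(0, 2 * np.pi)
            p0 = 30.0 * np.array([np.cos(ang), np.sin(ang)])
            target = rng.uniform(-half, half, size=2)
            p1 = p0 + 3.0 * (target - p0)
            chord = LineString([tuple(p0), tuple(p1)]).intersection(bbox).length
            _, ln = fv.siddon_trace(grid, (p0, p1))
            assert abs(ln.sum() - chord) < 1e-9 * max(chord, 1.0)

    def test_miss_gives_empty_row(self):
        grid = fv.ImageGrid(np.zeros((4, 4)), 1.0)
        idx, ln = fv.siddon_trace(grid, (np.array([-10.0, 10.0]), np.array([10.0, 10.0])))
        assert len(idx) == 0 and len(ln) == 0

    def test_degenerate_segment_rejected(self):
        grid = fv.ImageGrid(np.zeros((4, 4)), 1.0)
        with pytest.raises(ValueError):
            fv.siddon_trace(grid, (np.array([5.0, 5.0]), np.array([5.0, 5.0])))


def dense_oracle(geom, grid):
    """Independent dense system matrix via polygon clipping (shapely)."""
    n, h, half = grid.n, grid.pixel_size, grid.half_extent
    dense = np.zeros((geom.n_rays, n * n))
    for v in range(geom.n_views):
        for k in range(geom.detector_bins):
            p0, p1 = fv.ray_segment(geom, grid, v, k)
            line = LineString([tuple(p0), tuple(p1)])
            for r in range(n):
                for c in range(n):
                    cell = box(-half + c * h, half - (r + 1) * h,
                               -half + (c + 1) * h, half - r * h)
                    dense[v * geom.detector_bins + k, r * n + c] = line.intersection(cell).length
    return dense


class TestSystemMatrix:
    def test_matches_dense_polygon_clipping_oracle(self, tiny_system):
        A, grid, geom = tiny_system
        dense = dense_oracle(geom, grid)
        np.testing.assert_allclose(A.matrix.toarray(), dense, atol=1e-9)

    def test_row_and_col_sums_match_dense_recomputation(self, tiny_system):
        A, _, _ = tiny_system
        dense = A.matrix.toarray()
        np.testing.assert_allclose(A.row_sums, dense.sum(axis=1), atol=1e-12)
        np.testing.assert_allclose(A.col_sums, dense.sum(axis=0), atol=1e-12)

    def test_lengths_below_chord_bound(self, tiny_system):
        A, grid, _ = tiny_system
        assert A.matrix.data.max() <= grid.pixel_size * math.sqrt(2) + 1e-12

    def test_equals_stacked_siddon_rows(self):
        grid = fv.ImageGrid(np.zeros((4, 4)), 1.0)
        geom = fv.FanBeamGeometry(20.0, 3, 1.5, fv.view_angles(2))
        A = fv.build_system_matrix(geom, grid)
        for v in range(2):
            for k in range(3):
                idx, ln = fv.siddon_trace(grid, fv.ray_segment(geom, grid, v, k))
                row = A.matrix[v * 3 + k].toarray().ravel()
                expect = np.zeros(16)
                expect[idx] = ln
                np.testing.assert_allclose(row, expect, atol=1e-12)

    def test_paper_scale_ray_count(self):
        geom = fv.FanBeamGeometry(293.1, 1025, 0.05, fv.view_angles(40))
        assert geom.n_rays == 41_000

    def test_memory_guard(self):
        grid = fv.ImageGrid(np.zeros((64, 64)), 1.0)
        geom = fv.FanBeamGeometry(200.0, 64, 1.0, fv.view_angles(10))
        with pytest.raises(MemoryError):
            fv.build_system_matrix(geom, grid, nnz_cap=10)


class TestProjections:
    def test_zero_image_zero_sinogram(self, tiny_system):
        A, grid, _ = tiny_system
        assert np.all(fv.forward_project(A, grid).values == 0.0)

    def test_uniform_image_gives_chord_lengths(self, tiny_system):
        A, grid, _ = tiny_system
        c = 2.5
        p = fv.forward_project(A, grid.with_values(np.full((8, 8), c)))
        np.testing.assert_allclose(p.as_vector(), c * A.row_sums, rtol=1e-12)

    def test_matches_dense_matvec(self, tiny_system, rng):
        A, grid, _ = tiny_system
        f = rng.normal(size=64)
        np.testing.assert_allclose(
            fv.forward_project(A, f).as_vector(), A.matrix.toarray() @ f, rtol=1e-12
        )

    def test_adjoint_identity(self, tiny_system, rng):
        A, _, _ = tiny_system
        f = rng.normal(size=A.N)
        p = rng.normal(size=A.M)
        lhs = np.dot(A.matrix @ f, p)
        rhs = np.dot(f, fv.back_project(A, p).ravel())
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_single_ray_backprojection_support(self, tiny_system):
        A, grid, geom = tiny_system
        ray = geom.detector_bins // 2  # central ray of view 0
        p = np.zeros(A.M)
        p[ray] = 1.0
        bp = fv.back_project(A, p).ravel()
        idx, _ = fv.siddon_trace(grid, fv.ray_segment(geom, grid, 0, ray))
        assert set(np.flatnonzero(bp)) == set(idx)

    def test_shape_mismatch_rejected(self, tiny_system):
        A, _, _ = tiny_system
        with pytest.raises(ValueError):
            fv.forward_project(A, np.zeros(10))
        with pytest.raises(ValueError):
            fv.back_project(A, np.zeros(10))

    def test_rotation_consistency_of_centered_disc(self, disc_system):
        A, _, sino = disc_system
        # fourfold grid symmetry: profiles at 0/90/180/270 degrees coincide
        quarter = [v for v, a in enumerate(A.geometry.angles)
                   if np.isclose(a % (np.pi / 2), 0.0)]
        ref = sino.values[quarter[0]]
        for v in quarter[1:]:
            np.testing.assert_allclose(sino.values[v], ref, rtol=1e-10, atol=1e-10)
        # at arbitrary angles the pixelated disc matches to discretization level
        peak = sino.values.max()
        assert np.all(np.abs(sino.values.max(axis=1) - ref.max()) < 0.05 * peak)


def test_clip_to_box_misses_and_degenerate_directions():
    assert _clip_to_box(np.array([0.0, 10.0]), np.array([1.0, 0.0]), 2.0) is None
    got = _clip_to_box(np.array([0.0, -10.0]), np.array([0.0, 1.0]), 2.0)
    assert got == (8.0, 12.0)
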