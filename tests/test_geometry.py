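"""Hulls, pruning, calibrated reports, lofted surfaces, OFF export."""

import numpy as np
import pytest

import gcvol as g
from gcvol import SegmentationParams, segment
from gcvol.geometry import (
    build_surface,
    prune_outliers,
    read_off,
    report,
    slice_hull,
    write_off,
    SurfaceMesh,
)


def _cluster(vox, t_h=100, s_min=1):
    return segment(g.ImageStack(np.asarray(vox, np.uint8), spacing=(1, 1, 1)),
                   SegmentationParams(t_h, s_min))[0]


class TestSliceHull:
    def test_square_corners_plus_center(self):
        pts = np.array([[0, 0], [0, 4], [4, 0], [4, 4], [2, 2]])
        sc = slice_hull(pts)
        assert len(sc.hull_points) == 4
        assert sc.area_px == pytest.approx(16.0)
        # brute-force containment: every pixel inside or on the hull
        hull_set = {tuple(p) for p in sc.hull_points}
        assert {(2, 2)} - hull_set  # interior point not a vertex

    def test_triangle(self):
        sc = slice_hull(np.array([[0, 0], [0, 3], [3, 0]]))
        assert len(sc.hull_points) == 3
        assert sc.area_px == pytest.approx(4.5)

    def test_degenerate_single_pixel(self):
        sc = slice_hull(np.array([[5, 7]]))
        assert len(sc.hull_points) == 1
        assert sc.area_px == 1.0

    def test_degenerate_collinear(self):
        sc = slice_hull(np.array([[0, 0], [0, 1], [0, 2], [0, 3]]))
        assert len(sc.hull_points) == 2
        assert sc.area_px == 4.0  # pixel count

    def test_calibrated_area(self):
        sc = slice_hull(np.array([[0, 0], [0, 2], [2, 0], [2, 2]]),
                        pixel_size=(0.5, 0.5))
        assert sc.area_um2 == pytest.approx(4.0 * 0.25)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            slice_hull(np.empty((0, 2)))

    def test_hull_contains_all_cluster_pixels(self, noisy_gc):
        """Point-in-convex-polygon oracle: all member pixels inside or on the hull."""
        stack, _ = noisy_gc
        c = segment(stack, SegmentationParams(120, 50))[0]
        for n, region in c.slice_regions.items():
            verts = slice_hull(region, n).hull_points
            if len(verts) < 3:
                continue
            # orient CCW by signed area, then test every half-plane
            nxt = np.roll(verts, -1, axis=0)
            cross2 = lambda u, v: u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]  # noqa: E731
            if np.sum(cross2(verts, nxt)) < 0:
                verts, nxt = verts[::-1], np.roll(verts[::-1], -1, axis=0)
            edges = nxt - verts
            for p in np.asarray(region, float):
                assert np.all(cross2(edges, p[None, :] - verts) >= -1e-9)


class TestPruneOutliers:
    def _ring(self, n=20, r=10.0):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([10 + r * np.cos(ang), 10 + r * np.sin(ang)])

    @pytest.mark.parametrize("method", ["center", "pairwise"])
    def test_far_point_removed(self, method):
        pts = np.vstack([self._ring(), [[100.0, 100.0]]])
        out = prune_outliers(pts, method=method)
        assert len(out) == 20
        assert not np.any(np.all(out == [100.0, 100.0], axis=1))

    def test_clean_ring_unchanged(self):
        ring = self._ring()
        assert np.array_equal(prune_outliers(ring), ring)

    def test_two_points_unchanged(self):
        pts = np.array([[0.0, 0.0], [100.0, 100.0]])
        assert np.array_equal(prune_outliers(pts), pts)

    def test_removal_capped_at_20_percent(self):
        pts = np.vstack([self._ring(20), 60 + 3 * self._ring(10)])
        out = prune_outliers(pts)
        assert len(out) >= np.ceil(0.8 * len(pts))


class TestReport:
    def test_single_voxel_volume(self):
        vox = np.zeros((1, 3, 3))
        vox[0, 1, 1] = 200
        r = report(_cluster(vox), (0.5, 0.5, 1.43))
        assert r.volume_um3 == pytest.approx(0.3575)
        assert r.voxel_count == 1

    def test_cuboid_exact(self):
        vox = np.zeros((7, 12, 12))
        vox[1:6, 1:11, 1:11] = 200  # 10 x 10 x 5
        r = report(_cluster(vox), (1, 1, 1))
        assert r.volume_um3 == 500.0
        assert r.slice_span == (1, 5)
        assert r.bbox == ((1, 1, 1), (5, 10, 10))
        assert r.slice_areas[3] == 100

    def test_digital_ball_within_10pct_of_analytic(self):
        spec = g.PhantomSpec(shape=(24, 24, 24),
                             gc_list=[((11.5, 11.5, 11.5), (10, 10, 10), 200.0)],
                             noise_sigma=0.0)
        stack, truth = g.make_phantom(spec)
        c = segment(stack, SegmentationParams(150, 10))[0]
        r = report(c, (1, 1, 1))
        analytic = 4.0 / 3.0 * np.pi * 1000
        assert abs(r.volume_um3 - analytic) / analytic < 0.10
        assert r.voxel_count == truth.mask().sum()

    def test_volume_equals_slice_area_sum(self, noisy_gc):
        stack, _ = noisy_gc
        c = segment(stack, SegmentationParams(120, 50))[0]
        r = report(c, stack.spacing)
        dx, dy, dz = stack.spacing
        assert r.volume_um3 == pytest.approx(sum(r.slice_areas.values()) * dx * dy * dz)


class TestSurface:
    def test_two_slice_square_loft(self):
        vox = np.zeros((4, 8, 8))
        vox[1:3, 2:4, 2:4] = 200
        mesh = build_surface(_cluster(vox), (1, 1, 1))
        assert len(mesh.vertices) == 8
        assert mesh.euler_characteristic() == 2

    def test_single_slice_triangle_prism(self):
        vox = np.zeros((1, 8, 8))
        vox[0, 1, 1] = vox[0, 1, 2] = vox[0, 2, 1] = 200
        mesh = build_surface(_cluster(vox), (1, 1, 1))
        assert len(mesh.vertices) == 6
        assert mesh.euler_characteristic() == 2

    def test_phantom_cluster_watertight(self, noisy_gc):
        stack, _ = noisy_gc
        c = segment(stack, SegmentationParams(120, 50))[0]
        mesh = build_surface(c, (0.7, 0.7, 1.43))
        assert mesh.euler_characteristic() == 2
        # every z level of the cluster contributes vertices at its physical height
        zs = {round(v, 4) for v in mesh.vertices[:, 2]}
        assert len(zs) == c.slice_span[1] - c.slice_span[0] + 1


class TestOFF:
    def test_tetrahedron_counts_line(self, tmp_path):
        mesh = SurfaceMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
            faces=[[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]],
        )
        path = tmp_path / "tet.off"
        write_off(mesh, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "OFF"
        assert lines[1] == "4 4 6"

    def test_round_trip(self, tmp_path, noisy_gc):
        stack, _ = noisy_gc
        c = segment(stack, SegmentationParams(120, 50))[0]
        mesh = build_surface(c, stack.spacing)
        path = tmp_path / "gc.off"
        write_off(mesh, path)
        back = read_off(path)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
        assert back.faces == mesh.faces

    def test_empty_mesh_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_off(SurfaceMesh(vertices=np.empty((0, 3)), faces=[]), tmp_path / "e.off")
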