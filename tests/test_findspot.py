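"""Spot finding: flood-fill oracle equivalence, examples, invariants."""

import numpy as np
import pytest

import gcvol as g
from gcvol import ImageStack, SegmentationParams, halo_fraction, segment

from conftest import flood_fill_partition


def _stack(arr):
    return ImageStack(np.asarray(arr, dtype=np.uint8), spacing=(1, 1, 1))


def _partition(clusters):
    return {c.voxel_set for c in clusters}


class TestExamples:
    def test_all_zero_stack_gives_empty_list(self):
        s = _stack(np.zeros((4, 8, 8)))
        assert segment(s, SegmentationParams(1, 1)) == []

    def test_constant_cube_is_one_cluster(self):
        s = _stack(np.full((3, 3, 3), 255))
        cl = segment(s, SegmentationParams(100, 1))
        assert len(cl) == 1 and cl[0].size == 27

    def test_non_adjacent_voxels_are_two_clusters(self):
        vox = np.zeros((2, 4, 4))
        vox[0, 0, 0] = 200
        vox[1, 3, 3] = 200  # not 26-adjacent to (0,0,0)
        cl = segment(_stack(vox), SegmentationParams(100, 1))
        assert sorted(c.size for c in cl) == [1, 1]

    def test_smin_cut_removes_small_blob(self):
        vox = np.zeros((3, 5, 5))
        vox[1, 1:2, 0:5] = 200  # 5-voxel line
        assert segment(_stack(vox), SegmentationParams(100, 6)) == []
        assert len(segment(_stack(vox), SegmentationParams(100, 5))) == 1

    def test_diagonal_connectivity_modes(self):
        vox = np.zeros((1, 2, 2))
        vox[0, 0, 0] = vox[0, 1, 1] = 200  # touching only diagonally
        assert len(segment(_stack(vox), SegmentationParams(100, 1), connectivity=26)) == 1
        assert len(segment(_stack(vox), SegmentationParams(100, 1), connectivity=6)) == 2


@pytest.mark.parametrize("connectivity", [6, 26])
def test_oracle_equivalence_random_stacks(connectivity):
    """Cluster partitions match an independent BFS flood fill exactly."""
    rng = np.random.default_rng(1234)
    for trial in range(40):
        shape = tuple(rng.integers(2, (9, 17, 17)[i] if i else 9) for i in range(3))
        vox = (rng.random(shape) < 0.35) * rng.integers(1, 255, shape)
        s = _stack(vox)
        for s_min in (1, 2, 5):
            got = _partition(segment(s, SegmentationParams(1, s_min),
                                     connectivity=connectivity))
            want = flood_fill_partition(s.voxels, 1, s_min, connectivity)
            assert got == want


def test_threshold_monotonicity_and_conservation(noisy_gc):
    stack, _ = noisy_gc
    prev_union = None
    for t_h in (60, 90, 120, 180):
        clusters = segment(stack, SegmentationParams(t_h, 1))
        union = set()
        for c in clusters:
            union |= c.voxel_set
            # conservation: per-slice areas sum to the cluster size
            assert sum(c.slice_areas.values()) == c.size
            for n, region in c.slice_regions.items():
                assert len(region) == c.slice_areas[n]
                assert int(c.slice_histograms[n].sum()) == c.slice_areas[n]
        if prev_union is not None:
            assert union <= prev_union
        prev_union = union


def test_cluster_ordering_is_deterministic():
    vox = np.zeros((2, 8, 8))
    vox[:, 0:2, 0:2] = 200  # 8 voxels, first voxel (0,0,0)
    vox[:, 5:7, 5:7] = 200  # 8 voxels, first voxel (0,5,5)
    vox[1, 3, 7] = 200      # single voxel, not 26-adjacent to either block
    cl = segment(_stack(vox), SegmentationParams(100, 1))
    assert [c.size for c in cl] == [8, 8, 1]
    assert cl[0].coords[0].tolist() == [0, 0, 0]  # tie broken by smallest voxel
    assert [c.index for c in cl] == [1, 2, 3]


class TestHaloFraction:
    def _stack(self):
        vox = np.zeros((1, 10, 10), np.uint8)
        vox[0, :, 5:] = 200  # right half bright
        return ImageStack(vox)

    def test_boundary_values(self):
        s = self._stack()
        inner = [(4, 4)]
        dark = [(4, 4), (4, 0), (5, 0), (6, 0)]
        bright = [(4, 4), (4, 6), (5, 7), (6, 8)]
        assert halo_fraction(s, inner, dark, 100, 0).fraction == 0.0
        assert halo_fraction(s, inner, bright, 100, 0).fraction == 1.0

    def test_half_fraction_counted(self):
        s = self._stack()
        inner = [(0, 4)]
        outer = [(0, 4)] + [(y, x) for y in range(1, 6) for x in range(2, 10, 2)]
        st = halo_fraction(s, inner, outer, 100, 0)
        assert st.N_t == 20
        assert st.N_f == 10  # columns 6, 8 bright; 2, 4 dark
        assert st.fraction == 0.5

    def test_inner_must_be_subset(self):
        s = self._stack()
        with pytest.raises(ValueError):
            halo_fraction(s, [(0, 0), (9, 9)], [(0, 0)], 100, 0)

    def test_empty_annulus_by_convention_zero(self):
        s = self._stack()
        region = [(0, 0), (0, 1)]
        assert halo_fraction(s, region, region, 100, 0).fraction == 0.0
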