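"""Objective building blocks: D, A_jn, L_j, region matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gcvol as g
from gcvol import (
    ObjectiveConfig,
    SegmentationParams,
    area_similarity,
    bhattacharyya_distance,
    match_regions,
    objective,
    segment,
)
from gcvol.findspot import N_HISTOGRAM_BINS, SpotCluster


def _synthetic_cluster(slice_areas, hist_fill=5, index=1):
    """Build a SpotCluster with prescribed per-slice areas (histograms uniform)."""
    regions, areas, hists = {}, {}, {}
    coords = []
    for n, a in slice_areas.items():
        if a == 0:
            continue
        pix = np.array([[0, i] for i in range(a)])
        regions[n] = pix
        areas[n] = a
        h = np.zeros(N_HISTOGRAM_BINS, dtype=np.int64)
        h[hist_fill] = a
        hists[n] = h
        coords.extend([[n, 0, i] for i in range(a)])
    return SpotCluster(index=index, coords=np.array(coords),
                       slice_regions=regions, slice_areas=areas,
                       slice_histograms=hists)


class TestBhattacharyya:
    def test_identical_is_zero(self):
        h = np.array([1, 2, 3, 4.0])
        assert bhattacharyya_distance(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        assert bhattacharyya_distance([1, 0, 0], [0, 2, 5]) == 1.0

    def test_hand_value(self):
        # (0.5, 0.5) vs (1, 0): 1 - sqrt(0.5) ≈ 0.29289
        d = bhattacharyya_distance([0.5, 0.5], [1.0, 0.0])
        assert d == pytest.approx(1 - math.sqrt(0.5), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            bhattacharyya_distance([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            bhattacharyya_distance([0, 0], [0, 0])
        with pytest.raises(ValueError):
            bhattacharyya_distance([-1, 2], [1, 2])

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4),
           st.lists(st.floats(0, 100), min_size=4, max_size=4))
    @settings(max_examples=200, derandomize=True)
    def test_metric_like_properties(self, ha, hb):
        a, b = np.array(ha), np.array(hb)
        if a.sum() == 0 or b.sum() == 0:
            return
        d_ab = bhattacharyya_distance(a, b)
        assert 0.0 <= d_ab <= 1.0
        assert d_ab == pytest.approx(bhattacharyya_distance(b, a), abs=1e-12)
        # scale invariance of the normalized form
        assert d_ab == pytest.approx(bhattacharyya_distance(3 * a, b), abs=1e-9)


class TestAreaSimilarity:
    @pytest.mark.parametrize("a,b,want", [
        (50, 50, 1.0),
        (10, 0, 0.0),   # one-sided vanishing
        (0, 10, 0.0),
        (10, 30, 0.5),  # (40-20)/40
        (0, 0, 0.0),    # doubly degenerate, by convention
    ])
    def test_values(self, a, b, want):
        assert area_similarity(a, b) == pytest.approx(want)

    def test_symmetry_and_bounds_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a, b = rng.integers(0, 500, 2)
            s = area_similarity(a, b)
            assert s == area_similarity(b, a)
            assert 0.0 <= s <= 1.0
            if a == b and a > 0:
                assert s == 1.0


class TestObjective:
    def test_identical_pair_closed_form(self):
        """L(λ, λ) = N / (ε + βN) exactly, for N = 1..50 slices."""
        cfg = ObjectiveConfig()
        for n_slices in range(1, 51):
            c = _synthetic_cluster({n: 10 for n in range(n_slices)})
            val = objective((c, c), cfg)
            assert val == pytest.approx(n_slices / (cfg.epsilon + cfg.beta * n_slices),
                                        rel=1e-14)

    def test_vanishing_contour_doubles_objective(self):
        # areas (10, 10) vs (10, 0): D = (0, 1) -> (e^0 + e^alpha)/(eps + 1)
        ca = _synthetic_cluster({0: 10, 1: 10})
        cb = _synthetic_cluster({0: 10})
        cfg = ObjectiveConfig()
        val = objective((ca, cb), cfg)
        want = (1.0 + math.exp(cfg.alpha)) / (cfg.epsilon + 1.0)
        assert val == pytest.approx(want, rel=1e-12)
        assert val > 2 * objective((ca, ca), cfg) * 0.999

    def test_area_scale_invariance(self):
        ca = _synthetic_cluster({0: 10, 1: 20, 2: 15})
        cb = _synthetic_cluster({0: 12, 1: 18, 2: 15})
        ca2 = _synthetic_cluster({0: 20, 1: 40, 2: 30})
        cb2 = _synthetic_cluster({0: 24, 1: 36, 2: 30})
        assert objective((ca, cb)) == pytest.approx(objective((ca2, cb2)), rel=1e-12)

    def test_removing_a_slice_strictly_increases(self):
        ca = _synthetic_cluster({n: 25 for n in range(6)})
        cb = _synthetic_cluster({n: 25 for n in range(5)})  # slice 5 vanished
        assert objective((ca, cb)) > objective((ca, ca))

    def test_vanished_partner_is_heavily_penalized(self):
        ca = _synthetic_cluster({0: 30, 1: 40})
        cfg = ObjectiveConfig()
        val = objective((ca, None), cfg)
        assert val > 1.0 / cfg.epsilon  # denominator collapses to ε

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            objective((None, None))


class TestMatchRegions:
    def _segment(self, vox, t_h=100, s_min=1):
        return segment(g.ImageStack(np.asarray(vox, np.uint8)),
                       SegmentationParams(t_h, s_min))

    def test_identity_pairing(self, noisy_gc):
        stack, _ = noisy_gc
        seg_a = segment(stack, SegmentationParams(120, 50))
        pairs = match_regions(seg_a, seg_a)
        assert all(a is b for a, b in pairs)

    def test_nested_clusters_matched(self):
        vox = np.zeros((2, 12, 12))
        vox[:, 1:5, 1:5] = 120
        vox[:, 2:4, 2:4] = 220
        vox[:, 7:11, 7:11] = 130
        vox[:, 8:10, 8:10] = 230
        seg_lo = self._segment(vox, 100)   # two 4x4x2 blocks
        seg_hi = self._segment(vox, 200)   # two nested 2x2x2 blocks
        pairs = match_regions(seg_lo, seg_hi)
        assert len(pairs) == 2
        for a, b in pairs:
            assert b is not None
            assert b.voxel_set <= a.voxel_set

    def test_unmatched_cluster_paired_with_none(self):
        vox = np.zeros((1, 8, 8))
        vox[0, 0:2, 0:2] = 150
        vox[0, 5:7, 5:7] = 250
        seg_a = self._segment(vox, 100)  # both blobs
        seg_b = self._segment(vox, 200)  # only the bright blob
        pairs = match_regions(seg_a, seg_b)
        partners = {a.coords[0, 1]: b for a, b in pairs}
        assert partners[5] is not None
        assert partners[0] is None
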