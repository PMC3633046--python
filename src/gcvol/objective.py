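"""Self-tuning segmentation objective.

Choosing the global threshold t_h (and minimum spot size s_min) by eye is
error prone: too low and clusters balloon into tissue, too high and the dim
top/bottom slices of a GC are lost.  The objective implemented here scores
a parameter vector λ_t by comparing the segmentation it produces against
the segmentation at a neighbouring parameter value λ_t' (t_h' = t_h + 1 by
default): for the j-th GC,

    L_j(λ_t, λ_t') = Σ_n exp[α·D(H_jn(λ_t), H_jn(λ_t'))]
                     ───────────────────────────────────
                     ε + β·Σ_n A_jn(λ_t, λ_t')

where D is the Bhattacharyya distance between the per-slice pixel-tone
histograms and A_jn = (|a+a'| − |a−a'|)/|a+a'| compares the per-slice
areas.  A stable segmentation (identical regions at λ_t and λ_t') gives
D = 0, A = 1 and L_j ≈ 1/β; a contour that vanishes between neighbouring
parameter values drives A → 0 and L_j towards N/ε, a huge penalty.  The
optimal λ* minimises L_j — in a GC image the minimum sits where the border
locks onto the dark halo ring, because there the segmentation is
insensitive to the exact threshold.

Note on the distance: D is the standard Bhattacharyya form
``1 − Σ_k sqrt(Ĥa(k)·Ĥb(k))`` on unit-sum normalised histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .findspot import SpotCluster

__all__ = [
    "ObjectiveConfig",
    "bhattacharyya_distance",
    "area_similarity",
    "objective",
    "match_regions",
]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Constants of the objective.

    ``alpha`` weighs the histogram-difference term (default 0.001),
    ``beta`` the area-similarity sum (default 1.0), ``epsilon`` guards the
    division (default 1e-9) and ``neighbor_offset`` is the increment added
    to t_h to form the comparison parameter vector λ_t' (default +1).
    """

    alpha: float = 0.001
    beta: float = 1.0
    epsilon: float = 1e-9
    neighbor_offset: int = 1

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if int(self.neighbor_offset) == 0:
            raise ValueError("neighbor_offset must be a nonzero integer")


def bhattacharyya_distance(h_a: Sequence[float], h_b: Sequence[float]) -> float:
    """Bhattacharyya distance between two histograms, in [0, 1].

    Histograms are unit-sum normalised internally, so raw counts are fine.
    0 for identical normalised histograms, 1 for disjoint support;
    symmetric in its arguments.

    Raises
    ------
    ValueError
        On mismatched bin counts, negative entries, or an all-zero
        histogram (normalisation undefined).
    """
    a = np.asarray(h_a, dtype=np.float64)
    b = np.asarray(h_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("histograms must have the same number of bins")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("histogram entries must be non-negative")
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValueError("cannot normalise an all-zero histogram")
    bc = float(np.sqrt((a / sa) * (b / sb)).sum())
    return min(max(1.0 - bc, 0.0), 1.0)


def area_similarity(a: float, a_prime: float) -> float:
    """Area similarity A(a, a') = (|a + a'| − |a − a'|)/|a + a'|, in [0, 1].

    Symmetric; 1 iff the areas are equal (and nonzero), 0 when exactly one
    vanishes (the disappearing-contour case the objective punishes).  The
    doubly-degenerate A(0, 0) is defined as 0.
    """
    if a < 0 or a_prime < 0:
        raise ValueError("areas must be >= 0")
    s = a + a_prime
    if s == 0:
        return 0.0
    return (s - abs(a - a_prime)) / s


def objective(
    pair: tuple[SpotCluster | None, SpotCluster | None],
    config: ObjectiveConfig = ObjectiveConfig(),
) -> float:
    """Evaluate L_j for one matched cluster pair (segmentations at λ_t, λ_t').

    Either element may be ``None`` (the cluster vanished at that parameter
    value): its per-slice areas are all 0, each shared slice then
    contributes A = 0 and the maximal histogram distance D = 1.  Slices
    where both regions are empty are skipped.

    Raises
    ------
    ValueError
        If both elements are ``None`` (no slices at either λ).
    """
    ca, cb = pair
    if ca is None and cb is None:
        raise ValueError("empty cluster pair: no slices at either parameter value")
    areas_a = ca.slice_areas if ca is not None else {}
    areas_b = cb.slice_areas if cb is not None else {}
    hists_a = ca.slice_histograms if ca is not None else {}
    hists_b = cb.slice_histograms if cb is not None else {}

    num = 0.0
    den = 0.0
    for n in sorted(set(areas_a) | set(areas_b)):
        a = areas_a.get(n, 0)
        b = areas_b.get(n, 0)
        if a == 0 and b == 0:
            continue
        if a > 0 and b > 0:
            d = bhattacharyya_distance(hists_a[n], hists_b[n])
        else:
            d = 1.0
        num += float(np.exp(config.alpha * d))
        den += area_similarity(a, b)
    return num / (config.epsilon + config.beta * den)


def _overlap_count(ca: SpotCluster, cb: SpotCluster) -> int:
    return len(ca.voxel_set & cb.voxel_set)


def match_regions(
    seg_a: list[SpotCluster],
    seg_b: list[SpotCluster],
) -> list[tuple[SpotCluster, SpotCluster | None]]:
    """Pair clusters of two segmentations of the same stack.

    Greedy one-to-one matching by maximal voxel overlap (ties broken by
    cluster indices, so the result is deterministic).  Every cluster of
    ``seg_a`` appears exactly once; those with no overlapping partner in
    ``seg_b`` are paired with ``None`` — their areas count as 0 at λ_t',
    which is precisely how vanished regions get penalised.
    """
    candidates: list[tuple[int, int, int]] = []
    for i, ca in enumerate(seg_a):
        for k, cb in enumerate(seg_b):
            ov = _overlap_count(ca, cb)
            if ov > 0:
                candidates.append((ov, i, k))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    partner: dict[int, int] = {}
    used_b: set[int] = set()
    for ov, i, k in candidates:
        if i not in partner and k not in used_b:
            partner[i] = k
            used_b.add(k)
    return [(ca, seg_b[partner[i]] if i in partner else None) for i, ca in enumerate(seg_a)]
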