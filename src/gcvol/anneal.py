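"""Simulated-annealing search for the optimal segmentation parameters λ*.

The objective landscape over λ = (t_h, s_min) is nasty: piecewise constant
(segmentations only change when the threshold crosses an occupied intensity
level), riddled with enormous instability spikes where contours flicker
between λ_t and λ_t', and exactly flat inside stable bands.  A stochastic
global search handles the spikes; the flat ties are resolved by a final
deterministic refinement that prefers the most inclusive segmentation
(lowest t_h, then lowest s_min) among the minimisers — echoing the design
goal that λ should maximise the segmented areas while staying stable.

Every evaluation is cached, so the annealer revisiting a state is free and
two runs with the same seed are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .findspot import SegmentationParams, SpotCluster, segment
from .objective import ObjectiveConfig, match_regions, objective
from .stacks import ImageStack

__all__ = [
    "AnnealSettings",
    "AnnealState",
    "ObjectiveEvaluator",
    "OptimizationError",
    "optimize",
    "sweep_threshold",
]


class OptimizationError(RuntimeError):
    """Raised when no sampled λ produced any cluster at all."""


@dataclass(frozen=True)
class AnnealSettings:
    """Annealing schedule.

    Geometric cooling ``T_{k+1} = cooling * T_k`` starting from the initial
    objective spread around the seed; ``proposals_per_temp`` Metropolis
    proposals per temperature; stop when ``T < stop_frac * T0`` or after
    ``max_stagnant_temps`` temperatures without improvement.  Proposals
    perturb t_h by ±uniform{1..th_step_max} and scale s_min by a uniform
    factor in ``smin_factor_range`` (rounded), clipped to the bounds.
    """

    cooling: float = 0.95
    proposals_per_temp: int = 20
    stop_frac: float = 1e-3
    max_stagnant_temps: int = 50
    th_step_max: int = 5
    smin_factor_range: tuple[float, float] = (0.8, 1.25)
    refine: bool = True


@dataclass
class AnnealState:
    """Result and trace of one optimisation run."""

    best_params: SegmentationParams
    best_value: float
    t0: float
    n_evaluations: int
    history: list[dict] = field(default_factory=list, repr=False)

    def trace(self) -> pd.DataFrame:
        """Optimisation trace: iteration, t_h, s_min, objective, temperature, accepted."""
        cols = ["iteration", "t_h", "s_min", "objective", "temperature", "accepted"]
        return pd.DataFrame(self.history, columns=cols)

    def to_csv(self, path) -> None:
        self.trace().to_csv(path, index=False, float_format="%.6g")


class ObjectiveEvaluator:
    """Cached evaluation of the total objective Σ_j L_j(λ_t, λ_t').

    Segmentations are cached per threshold (at the loosest admissible
    s_min, so any s_min above it is a cheap filter), matches are built with
    :func:`gcvol.objective.match_regions` and per-GC terms with
    :func:`gcvol.objective.objective`.  Returns ``inf`` when λ_t yields no
    cluster.
    """

    def __init__(
        self,
        stack: ImageStack,
        config: ObjectiveConfig = ObjectiveConfig(),
        connectivity: int = 26,
        s_floor: int = 1,
    ) -> None:
        self.stack = stack
        self.config = config
        self.connectivity = connectivity
        self.s_floor = max(1, int(s_floor))
        self._seg_cache: dict[int, list[SpotCluster]] = {}
        self._value_cache: dict[tuple[int, int], float] = {}
        self.n_evaluations = 0

    def segmentation(self, t_h: int) -> list[SpotCluster]:
        t_h = int(t_h)
        if t_h not in self._seg_cache:
            self._seg_cache[t_h] = segment(
                self.stack,
                SegmentationParams(t_h=t_h, s_min=self.s_floor),
                connectivity=self.connectivity,
            )
        return self._seg_cache[t_h]

    def cluster_sizes(self, t_h: int) -> list[int]:
        return [c.size for c in self.segmentation(t_h)]

    def __call__(self, t_h: int, s_min: int) -> float:
        key = (int(t_h), int(s_min))
        if key in self._value_cache:
            return self._value_cache[key]
        if s_min < self.s_floor:
            raise ValueError(f"s_min {s_min} below evaluator floor {self.s_floor}")
        seg_a = [c for c in self.segmentation(t_h) if c.size >= s_min]
        if not seg_a:
            self._value_cache[key] = math.inf
            return math.inf
        t_prime = int(t_h) + self.config.neighbor_offset
        t_prime = max(0, min(t_prime, self.stack.dtype_max + 1))
        seg_b = [c for c in self.segmentation(t_prime) if c.size >= s_min]
        total = 0.0
        for pair in match_regions(seg_a, seg_b):
            total += objective(pair, self.config)
        self.n_evaluations += 1
        self._value_cache[key] = total
        return total


def _smin_candidates(ev: ObjectiveEvaluator, t_h: int, s_bounds: tuple[int, int]) -> list[int]:
    """Minimal s_min of every piece of the (piecewise-constant) s_min axis."""
    lo, hi = s_bounds
    sizes = set(ev.cluster_sizes(t_h))
    sizes |= set(ev.cluster_sizes(t_h + ev.config.neighbor_offset))
    cands = {lo} | {s + 1 for s in sizes if lo <= s + 1 <= hi}
    return sorted(cands)


_TIE_RTOL = 1e-12  # exact ties up to float noise
_WALK_RTOL = 1e-3  # micro-bumps bridged while walking inside the flat basin


def _basin_walk_down(
    ev: ObjectiveEvaluator,
    t_start: int,
    s: int,
    t_values: list[int],
    start_val: float,
) -> tuple[int, float]:
    """Walk t_h downward through the contiguous basin around ``t_start``.

    Continues while the objective stays within a small relative band of the
    running minimum (bridging one-pixel flicker bumps), and stops at the
    first instability wall.  Returns the lowest t attaining the walked
    minimum — the most inclusive threshold of the basin.  Never leaves the
    basin, so degenerate minima beyond the walls are not reachable from
    here (that is the annealer's job).
    """
    if t_start not in t_values:
        return t_start, start_val
    i = t_values.index(t_start)
    walk_min = start_val
    best_t = t_start
    while i > 0:
        v = ev(t_values[i - 1], s)
        if not math.isfinite(v) or v > walk_min * (1.0 + _WALK_RTOL):
            break
        i -= 1
        if v <= walk_min * (1.0 + _TIE_RTOL):
            if v < walk_min:
                walk_min = v
            best_t = t_values[i]
    return best_t, walk_min


def _refine(
    ev: ObjectiveEvaluator,
    best: tuple[int, int],
    best_val: float,
    t_values: list[int],
    s_bounds: tuple[int, int],
    s_values: list[int] | None,
) -> tuple[tuple[int, int], float]:
    """Deterministic local tie-breaking around the annealing optimum.

    The flat minimum basin is resolved to a canonical representative:
    prefer the loosest admissible s_min whenever it ties the optimum, then
    the lowest t_h reachable inside the basin, i.e. the most inclusive
    stable segmentation.  Only equal-value (tie) moves in s_min and
    basin-internal moves in t_h are taken, so the refinement never changes
    which basin the answer lives in.
    """
    t_best, s_best = best
    # anchor: if the loosest s_min ties the optimum at the current t, adopt it —
    # this makes the result independent of where the walk entered the basin
    s_lo = s_values[0] if s_values is not None else s_bounds[0]
    if s_lo < s_best:
        v = ev(t_best, s_lo)
        if math.isfinite(v) and v <= best_val * (1.0 + _TIE_RTOL):
            s_best = s_lo
            best_val = min(best_val, v)
    for _ in range(4):
        prev = (t_best, s_best, best_val)
        t_best, best_val = _basin_walk_down(ev, t_best, s_best, t_values, best_val)
        # spot-size axis is piecewise constant in s_min; probe the minimal
        # s_min of each piece and accept the lowest one that ties the optimum
        cands = s_values if s_values is not None else _smin_candidates(ev, t_best, s_bounds)
        for s in cands:
            if s >= s_best:
                break
            v = ev(t_best, s)
            if math.isfinite(v) and v <= best_val * (1.0 + _TIE_RTOL):
                s_best = s
                best_val = min(best_val, v)
                break
        if (t_best, s_best, best_val) == prev:
            break
    return (t_best, s_best), best_val


def optimize(
    stack: ImageStack,
    seed_params: SegmentationParams,
    config: ObjectiveConfig = ObjectiveConfig(),
    anneal: AnnealSettings = AnnealSettings(),
    rng_seed: int = 0,
    *,
    connectivity: int = 26,
    t_bounds: tuple[int, int] | None = None,
    s_bounds: tuple[int, int] | None = None,
    th_candidates: list[int] | None = None,
    smin_candidates: list[int] | None = None,
    evaluator: ObjectiveEvaluator | None = None,
) -> tuple[SegmentationParams, AnnealState]:
    """Find λ* = argmin Σ_j L_j(λ_t, λ_t') by simulated annealing.

    The user-supplied ``seed_params`` start the walk (the landscape's huge
    instability barriers make the search effectively local, so the seed
    should sit in the bright regime of the image, as a user eyeballing the
    stack would pick).  ``t_bounds`` / ``s_bounds`` clip the walk;
    ``th_candidates`` / ``smin_candidates`` restrict it to an explicit grid
    instead.  Deterministic for a fixed ``rng_seed``.

    Returns the optimal parameters and an :class:`AnnealState` whose
    history supports convergence plots.

    Raises
    ------
    OptimizationError
        If no sampled λ produced any cluster.
    """
    rng = np.random.default_rng(rng_seed)
    grid_mode = th_candidates is not None
    if grid_mode:
        th_candidates = sorted(int(t) for t in th_candidates)
        smin_candidates = sorted(int(s) for s in (smin_candidates or [seed_params.s_min]))
        t_bounds = (th_candidates[0], th_candidates[-1])
        s_bounds = (smin_candidates[0], smin_candidates[-1])
    else:
        if t_bounds is None:
            t_bounds = (0, stack.dtype_max)
        if s_bounds is None:
            s_bounds = (1, stack.voxels.size)
    ev = evaluator or ObjectiveEvaluator(
        stack, config, connectivity=connectivity, s_floor=s_bounds[0]
    )

    def clip_t(t: int) -> int:
        return max(t_bounds[0], min(int(t), t_bounds[1]))

    def clip_s(s: int) -> int:
        return max(s_bounds[0], min(int(s), s_bounds[1]))

    if grid_mode:
        ti = min(range(len(th_candidates)), key=lambda i: abs(th_candidates[i] - seed_params.t_h))
        si = min(range(len(smin_candidates)), key=lambda i: abs(smin_candidates[i] - seed_params.s_min))
        cur = (th_candidates[ti], smin_candidates[si])
    else:
        cur = (clip_t(seed_params.t_h), clip_s(seed_params.s_min))

    history: list[dict] = []
    it = 0

    def propose(state: tuple[int, int]) -> tuple[int, int]:
        if grid_mode:
            i = th_candidates.index(state[0])
            k = smin_candidates.index(state[1])
            step = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
            i = max(0, min(i + step, len(th_candidates) - 1))
            if len(smin_candidates) > 1 and rng.random() < 0.5:
                k = max(0, min(k + (1 if rng.random() < 0.5 else -1), len(smin_candidates) - 1))
            return th_candidates[i], smin_candidates[k]
        t, s = state
        dt = int(rng.integers(1, anneal.th_step_max + 1)) * (1 if rng.random() < 0.5 else -1)
        f = rng.uniform(*anneal.smin_factor_range)
        return clip_t(t + dt), clip_s(int(round(s * f)))

    cur_val = ev(*cur)
    # initial temperature from the local objective spread around the seed
    probe_vals = [cur_val] + [ev(*propose(cur)) for _ in range(8)]
    finite = [v for v in probe_vals if math.isfinite(v)]
    spread = (max(finite) - min(finite)) if finite else 0.0
    t0 = spread if spread > 0 else max(1e-3, 1e-3 * abs(finite[0]) if finite else 1.0)

    best, best_val = cur, cur_val
    temp = t0
    stagnant = 0
    while temp >= anneal.stop_frac * t0 and stagnant < anneal.max_stagnant_temps:
        improved = False
        for _ in range(anneal.proposals_per_temp):
            cand = propose(cur)
            cand_val = ev(*cand)
            delta = cand_val - cur_val
            if delta <= 0 or (math.isfinite(delta) and rng.random() < math.exp(-delta / temp)):
                accepted = True
                cur, cur_val = cand, cand_val
                if cur_val < best_val:
                    best, best_val = cur, cur_val
                    improved = True
            else:
                accepted = False
            history.append(
                {
                    "iteration": it,
                    "t_h": cand[0],
                    "s_min": cand[1],
                    "objective": cand_val,
                    "temperature": temp,
                    "accepted": accepted,
                }
            )
            it += 1
        stagnant = 0 if improved else stagnant + 1
        temp *= anneal.cooling

    if not math.isfinite(best_val):
        raise OptimizationError(
            "no cluster found at any sampled λ; check the seed threshold and s_min"
        )

    if anneal.refine:
        t_values = th_candidates if grid_mode else list(range(t_bounds[0], t_bounds[1] + 1))
        best, best_val = _refine(
            ev, best, best_val, t_values, s_bounds, smin_candidates if grid_mode else None
        )

    params = SegmentationParams(t_h=best[0], s_min=best[1])
    state = AnnealState(
        best_params=params,
        best_value=best_val,
        t0=t0,
        n_evaluations=ev.n_evaluations,
        history=history,
    )
    return params, state


def sweep_threshold(
    stack: ImageStack,
    s_min: int,
    t_range: tuple[int, int],
    config: ObjectiveConfig = ObjectiveConfig(),
    connectivity: int = 26,
    evaluator: ObjectiveEvaluator | None = None,
) -> pd.DataFrame:
    """1-D cut of the objective landscape: Σ_j L_j versus t_h at fixed s_min.

    Returns a DataFrame with columns ``t_h`` and ``objective`` (``inf``
    where no cluster survives) for plotting the characteristic sharp
    minimum of the landscape.
    """
    ev = evaluator or ObjectiveEvaluator(stack, config, connectivity=connectivity)
    rows = [{"t_h": t, "objective": ev(t, s_min)} for t in range(t_range[0], t_range[1] + 1)]
    return pd.DataFrame(rows)
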