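"""3D spot finding: threshold, grow, cut.

The segmentation step admits every voxel with intensity >= ``t_h`` (the
global threshold), groups admitted voxels into maximal connected components
across all directions xyz (26-connectivity by default, so diagonal
neighbours on the same and adjacent slices count), and discards components
smaller than ``s_min`` voxels — the minimum spot size, a final cut on the
contiguous 3D volume.  Each surviving component (a GC candidate) is
decomposed into per-slice regions gamma_jn with pixel areas a_jn and
pixel-tone histograms H_jn, which are the raw material of the
parameter-selection objective in :mod:`gcvol.objective`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .stacks import ImageStack

__all__ = [
    "SegmentationParams",
    "SpotCluster",
    "HaloStats",
    "segment",
    "halo_fraction",
    "label_volume",
    "intensity_bin_edges",
    "N_HISTOGRAM_BINS",
]

#: Number of intensity bins for per-slice histograms.  64 bins over the
#: dtype range keep the Bhattacharyya distance stable on small regions.
N_HISTOGRAM_BINS = 64


@dataclass(frozen=True)
class SegmentationParams:
    """λ = (t_h, s_min): global intensity threshold and minimum spot size."""

    t_h: int
    s_min: int

    def __post_init__(self) -> None:
        if self.t_h < 0:
            raise ValueError("t_h must be >= 0")
        if self.s_min < 1:
            raise ValueError("s_min must be >= 1")


@dataclass
class HaloStats:
    """Fraction of above-threshold pixels in an annular region.

    ``fraction = N_f / N_t`` with the convention 0 when the annulus is
    empty.  High values flag segmentation borders that have leaked past the
    dark halo ring into bright tissue.
    """

    N_f: int
    N_t: int

    @property
    def fraction(self) -> float:
        return self.N_f / self.N_t if self.N_t else 0.0


@dataclass
class SpotCluster:
    """One contiguous segmented 3D region (a GC candidate).

    Attributes
    ----------
    index:
        1-based cluster id ``j`` (clusters are ordered largest-first).
    coords:
        ``(N, 3)`` integer array of member voxels as ``(z, y, x)`` rows.
    slice_regions:
        Map slice index ``n`` → ``(N_n, 2)`` array of ``(y, x)`` pixels
        (the region gamma_jn).
    slice_areas:
        Map ``n`` → pixel count ``a_jn``.
    slice_histograms:
        Map ``n`` → length-64 intensity histogram (raw counts) of the
        pixels of gamma_jn.
    """

    index: int
    coords: np.ndarray
    slice_regions: dict[int, np.ndarray] = field(repr=False)
    slice_areas: dict[int, int] = field(repr=False)
    slice_histograms: dict[int, np.ndarray] = field(repr=False)

    @property
    def size(self) -> int:
        return int(self.coords.shape[0])

    @property
    def slice_span(self) -> tuple[int, int]:
        zs = sorted(self.slice_areas)
        return zs[0], zs[-1]

    @cached_property
    def voxel_set(self) -> frozenset[tuple[int, int, int]]:
        return frozenset(map(tuple, self.coords.tolist()))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def intensity_bin_edges(dtype_max: int, n_bins: int = N_HISTOGRAM_BINS) -> np.ndarray:
    """Bin edges spanning [0, dtype_max + 1) in ``n_bins`` equal bins."""
    return np.linspace(0, dtype_max + 1, n_bins + 1)


def quantize(values: np.ndarray, dtype_max: int, n_bins: int = N_HISTOGRAM_BINS) -> np.ndarray:
    """Map intensities to histogram bin indices."""
    return (values.astype(np.int64) * n_bins) // (dtype_max + 1)


def segment(
    stack: ImageStack,
    params: SegmentationParams,
    connectivity: int = 26,
) -> list[SpotCluster]:
    """Extract all spot clusters of ``stack`` at λ = (t_h, s_min).

    Returns every maximal connected component of ``{voxels >= t_h}`` with
    at least ``s_min`` voxels, each carrying its per-slice decomposition.
    Clusters are pairwise disjoint and ordered largest-first, ties broken
    by the lexicographically smallest member voxel.  An empty list is a
    valid result.
    """
    mask = stack.voxels >= params.t_h
    labels, n_labels = ndimage.label(mask, structure=_structure(connectivity))
    if n_labels == 0:
        return []
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes[1:] >= params.s_min) + 1
    if keep.size == 0:
        return []

    flat = labels.ravel()
    fg = np.flatnonzero(flat)
    lab_fg = flat[fg]
    order = np.argsort(lab_fg, kind="stable")
    fg_sorted = fg[order]
    lab_sorted = lab_fg[order]
    starts = np.searchsorted(lab_sorted, np.arange(1, n_labels + 2))

    nz, ny, nx = stack.shape
    vals = stack.voxels.ravel()
    dmax = stack.dtype_max

    # order kept labels: size desc, then smallest flat index (== smallest (z,y,x))
    first_voxel = np.array([fg_sorted[starts[k - 1]] for k in keep])
    rank = sorted(range(keep.size), key=lambda i: (-sizes[keep[i]], first_voxel[i]))

    clusters: list[SpotCluster] = []
    for j, i in enumerate(rank, start=1):
        k = keep[i]
        idx = np.sort(fg_sorted[starts[k - 1] : starts[k]])
        z = idx // (ny * nx)
        rem = idx % (ny * nx)
        y = rem // nx
        x = rem % nx
        coords = np.column_stack([z, y, x]).astype(np.int64)
        bins = quantize(vals[idx], dmax)
        regions: dict[int, np.ndarray] = {}
        areas: dict[int, int] = {}
        hists: dict[int, np.ndarray] = {}
        # idx sorted => z sorted; split per slice
        zb = np.searchsorted(z, np.arange(z[0], z[-1] + 2))
        for zi, (a, b) in enumerate(zip(zb[:-1], zb[1:]), start=int(z[0])):
            if a == b:
                continue
            regions[zi] = coords[a:b, 1:]
            areas[zi] = int(b - a)
            hists[zi] = np.bincount(bins[a:b], minlength=N_HISTOGRAM_BINS).astype(np.int64)
        clusters.append(
            SpotCluster(
                index=j,
                coords=coords,
                slice_regions=regions,
                slice_areas=areas,
                slice_histograms=hists,
            )
        )
    return clusters


def _as_pixel_set(region: Iterable) -> set[tuple[int, int]]:
    if isinstance(region, np.ndarray):
        return set(map(tuple, region.tolist()))
    return {(int(y), int(x)) for y, x in region}


def halo_fraction(
    stack: ImageStack,
    inner: Iterable,
    outer: Iterable,
    t_h: int,
    n: int,
) -> HaloStats:
    """Diagnostic annulus statistic on slice ``n``.

    Counts the pixels of ``outer \\ inner`` whose intensity on slice ``n``
    is >= ``t_h`` (``N_f``) against the annulus size (``N_t``).  For a
    segmentation that stops at the dark halo ring, an annulus just outside
    the border should give a fraction near 0; values near 1 mean the border
    sits inside bright tissue.  ``inner`` must be a subset of ``outer``.
    """
    inner_s = _as_pixel_set(inner)
    outer_s = _as_pixel_set(outer)
    if not inner_s <= outer_s:
        raise ValueError("inner region must be a subset of the outer region")
    annulus = outer_s - inner_s
    plane = stack.voxels[n]
    n_f = sum(1 for (y, x) in annulus if plane[y, x] >= t_h)
    return HaloStats(N_f=n_f, N_t=len(annulus))


def label_volume(
    clusters: list[SpotCluster],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Render clusters as a 16-bit label stack (0 = background, j = cluster)."""
    out = np.zeros(shape, dtype=np.uint16)
    for c in clusters:
        out[c.coords[:, 0], c.coords[:, 1], c.coords[:, 2]] = c.index
    return out


def write_label_volume(
    clusters: list[SpotCluster],
    stack: ImageStack,
    path: str | Path,
) -> None:
    """Export the cluster labels as a multi-page TIFF for inspection."""
    import tifffile

    tifffile.imwrite(Path(path), label_volume(clusters, stack.shape), photometric="minisblack")
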