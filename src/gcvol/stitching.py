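"""Mosaic assembly: phase-correlation registration, gain matching, blending.

Adjacent z-stack tiles acquired across a specimen overlap slightly and the
microscope stage position gives a coarse prior for each pairwise offset.
Registration refines that prior to the integer-pixel translation at the
peak of the Fourier phase-correlation surface, searched only within a
window around the prior.  Tiles are then placed on a canvas, exposure
differences are compensated with a single multiplicative gain per tile
(ratio of overlap-region means against the already-placed mosaic), and
overlap seams are hidden with a multiresolution (Laplacian-pyramid) blend.

Registration is per-stack: the offset is estimated on one representative
z-slice (the maximum-variance slice) and applied to all slices, consistent
with a rigid stage translation.  No subpixel refinement is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stacks import ImageStack, StackSet

__all__ = [
    "TilePair",
    "RegistrationResult",
    "MosaicLayout",
    "register_pair",
    "blend_mosaic",
    "DEFAULT_PEAK_FLOOR",
]

#: Phase-correlation peak height below which a registration is flagged
#: low-confidence (empirically, clean overlaps score well above this).
DEFAULT_PEAK_FLOOR = 0.03


@dataclass
class TilePair:
    """Two overlapping tiles with a stage-position prior.

    ``prior_offset`` is the expected ``(dy, dx)`` position of ``tile_b``
    relative to ``tile_a`` in pixels; ``search_window`` bounds the
    registration search to prior ± window on both axes.
    """

    tile_a: ImageStack
    tile_b: ImageStack
    prior_offset: tuple[int, int] = (0, 0)
    search_window: int = 20

    def __post_init__(self) -> None:
        if self.tile_a.spacing != self.tile_b.spacing:
            raise ValueError("tiles must share spacing")
        if self.tile_a.nz != self.tile_b.nz:
            raise ValueError("tiles must share the z dimension")


@dataclass
class RegistrationResult:
    """Integer offset of tile_b relative to tile_a and the peak quality."""

    offset: tuple[int, int]
    peak_score: float
    low_confidence: bool = False


@dataclass
class MosaicLayout:
    """Absolute tile placements plus per-tile gain factors."""

    positions: list[tuple[int, int]]
    gains: list[float] | None = None
    peak_scores: list[float] | None = None

    def canvas_shape(self, tiles: StackSet) -> tuple[int, int, int]:
        nz = tiles[0].nz
        h = max(p[0] + t.shape[1] for p, t in zip(self.positions, tiles))
        w = max(p[1] + t.shape[2] for p, t in zip(self.positions, tiles))
        return (nz, h, w)


def _best_slice(stack: ImageStack) -> int:
    """Representative slice for registration: the maximum-variance one."""
    var = stack.voxels.reshape(stack.nz, -1).var(axis=1)
    return int(np.argmax(var))


def register_pair(pair: TilePair, z_slice: int | None = None,
                  peak_floor: float = DEFAULT_PEAK_FLOOR) -> RegistrationResult:
    """Integer-pixel offset of tile_b relative to tile_a by phase correlation.

    The cross-power spectrum of the chosen z-slice is inverted and the peak
    is searched within ``prior ± search_window``; the peak height (1.0 for
    a perfect periodic match) is reported as ``peak_score`` and results
    below ``peak_floor`` are flagged ``low_confidence``.

    Raises
    ------
    ValueError
        If the guaranteed overlap within the search window is under 16 px.
    """
    a = pair.tile_a.voxels
    b = pair.tile_b.voxels
    H, W = a.shape[1], a.shape[2]
    py, px = pair.prior_offset
    win = pair.search_window
    if (H - abs(py) - win) < 16 or (W - abs(px) - win) < 16:
        raise ValueError("overlap region within the search window is below 16 px")

    z = _best_slice(pair.tile_a) if z_slice is None else int(z_slice)
    fa = np.fft.fft2(a[z].astype(np.float64))
    fb = np.fft.fft2(b[z].astype(np.float64))
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    cross /= np.where(mag > 0, mag, 1.0)
    surface = np.real(np.fft.ifft2(cross))

    best = None
    for dy in range(py - win, py + win + 1):
        row = surface[dy % surface.shape[0]]
        for dx in range(px - win, px + win + 1):
            score = row[dx % surface.shape[1]]
            key = (-score, dy, dx)
            if best is None or key < best:
                best = key
    score, dy, dx = -best[0], best[1], best[2]
    score = float(min(max(score, 0.0), 1.0))
    return RegistrationResult(
        offset=(dy, dx),
        peak_score=score,
        low_confidence=score < peak_floor,
    )


# ---------------------------------------------------------------------------
# pyramid blending
# ---------------------------------------------------------------------------

def _reduce(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, 1.0, mode="nearest")[::2, ::2]


def _expand(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    zy = shape[0] / img.shape[0]
    zx = shape[1] / img.shape[1]
    return ndimage.zoom(img, (zy, zx), order=1, mode="nearest", grid_mode=True)


def _blend_pyramid(a: np.ndarray, b: np.ndarray, mask: np.ndarray, depth: int) -> np.ndarray:
    """Multiresolution blend: result = b + M*(a - b) per Laplacian level.

    The ``b + M*(a-b)`` form is exact wherever ``a == b``, so filled or
    identical regions pass through unchanged regardless of the mask.
    """
    if depth < 1 or min(a.shape) < 4:
        return b + mask * (a - b)
    ga, gb, gm = [a], [b], [mask]
    for _ in range(depth):
        if min(ga[-1].shape) < 4:
            break
        ga.append(_reduce(ga[-1]))
        gb.append(_reduce(gb[-1]))
        gm.append(_reduce(gm[-1]))
    levels = len(ga)
    out = gb[-1] + gm[-1] * (ga[-1] - gb[-1])
    for i in range(levels - 2, -1, -1):
        la = ga[i] - _expand(ga[i + 1], ga[i].shape)
        lb = gb[i] - _expand(gb[i + 1], gb[i].shape)
        out = _expand(out, ga[i].shape) + lb + gm[i] * (la - lb)
    return out


def blend_mosaic(layout: MosaicLayout, tiles: StackSet) -> ImageStack:
    """Assemble tiles into one mosaic stack.

    Tiles are placed in order at ``layout.positions``.  Each tile is
    pre-scaled by its gain factor — supplied in the layout, or estimated
    as the ratio of overlap-region means against the mosaic built so far
    (the first tile is the exposure reference).  Overlap areas are blended
    with a Laplacian pyramid whose mask ramps across the overlap (distance-
    transform feathering); pyramid depth is ``floor(log2(overlap_width))``
    capped at 4, falling back to a plain linear blend for overlaps under
    16 px.  Pixels covered by a single tile equal their gain-scaled source
    exactly.

    Raises
    ------
    ValueError
        If the layout is inconsistent with the tiles.
    """
    if len(layout.positions) != len(tiles):
        raise ValueError("layout positions and tiles differ in count")
    if len(tiles) == 0:
        raise ValueError("no tiles to blend")
    nz, Hc, Wc = layout.canvas_shape(tiles)
    if min(p[0] for p in layout.positions) < 0 or min(p[1] for p in layout.positions) < 0:
        raise ValueError("layout positions must be non-negative")

    canvas = np.zeros((nz, Hc, Wc), dtype=np.float64)
    occ = np.zeros((Hc, Wc), dtype=bool)
    gains_out: list[float] = []

    for idx, (pos, tile) in enumerate(zip(layout.positions, tiles)):
        y0, x0 = pos
        h, w = tile.shape[1], tile.shape[2]
        sl = (slice(y0, y0 + h), slice(x0, x0 + w))
        region_occ = occ[sl]
        data = tile.voxels.astype(np.float64)

        if layout.gains is not None:
            gain = float(layout.gains[idx])
        elif region_occ.any():
            tile_mean = data[:, region_occ].mean()
            canvas_mean = canvas[:, sl[0], sl[1]][:, region_occ].mean()
            gain = canvas_mean / tile_mean if tile_mean > 0 else 1.0
        else:
            gain = 1.0
        gains_out.append(gain)
        data = data * gain

        if not region_occ.any():
            canvas[:, sl[0], sl[1]] = data
            occ[sl] = True
            continue

        # feathering mask on the canvas grid: 1 deep inside the new tile,
        # 0 deep inside the existing mosaic, ramping across the overlap
        foot = np.zeros((Hc, Wc), dtype=bool)
        foot[sl] = True
        dt_new = ndimage.distance_transform_edt(foot)
        dt_old = ndimage.distance_transform_edt(occ)
        with np.errstate(invalid="ignore"):
            m_full = dt_new / np.maximum(dt_new + dt_old, 1e-12)
        mask = m_full[sl].copy()
        mask[~region_occ] = 1.0

        overlap_rows = np.flatnonzero(region_occ.any(axis=1))
        overlap_cols = np.flatnonzero(region_occ.any(axis=0))
        ov_w = min(overlap_rows.size, overlap_cols.size)
        depth = 0 if ov_w < 16 else min(4, int(math.floor(math.log2(ov_w))))

        existing = canvas[:, sl[0], sl[1]]
        for z in range(nz):
            b = np.where(region_occ, existing[z], data[z])  # fill holes with tile values
            blended = _blend_pyramid(data[z], b, mask, depth)
            # blend only inside the overlap: single-coverage pixels stay exact
            canvas[z, sl[0], sl[1]] = np.where(region_occ, blended, data[z])
        occ[sl] = True

    if layout.gains is None:
        layout.gains = gains_out
    dtype = tiles[0].voxels.dtype
    hi = np.iinfo(dtype).max
    voxels = np.clip(np.rint(canvas), 0, hi).astype(dtype)
    return ImageStack(voxels=voxels, channel_label=tiles[0].channel_label,
                      spacing=tiles[0].spacing)
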