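"""Shared fixtures and independent oracles for the test suite."""

from collections import deque

import numpy as np
import pytest

import gcvol as g


# ---------------------------------------------------------------------------
# independent brute-force flood-fill oracle (never uses scipy labeling)
# ---------------------------------------------------------------------------

def _offsets(connectivity: int):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_partition(volume: np.ndarray, t_h: int, s_min: int, connectivity: int):
    """BFS flood fill over {voxels >= t_h}: the reference cluster partition.

    Returns a set of frozensets of (z, y, x) tuples, keeping only
    components with at least ``s_min`` voxels.
    """
    nz, ny, nx = volume.shape
    mask = volume >= t_h
    seen = np.zeros_like(mask)
    offs = _offsets(connectivity)
    comps = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                comp = []
                queue = deque([(z, y, x)])
                seen[z, y, x] = True
                while queue:
                    cz, cy, cx = queue.popleft()
                    comp.append((cz, cy, cx))
                    for dz, dy, dx in offs:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= pz < nz and 0 <= py < ny and 0 <= px < nx
                            and mask[pz, py, px] and not seen[pz, py, px]
                        ):
                            seen[pz, py, px] = True
                            queue.append((pz, py, px))
                if len(comp) >= s_min:
                    comps.add(frozenset(comp))
    return comps


def dice_coefficient(seg_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    inter = np.logical_and(seg_mask, truth_mask).sum()
    return 2.0 * inter / (seg_mask.sum() + truth_mask.sum())


def segmentation_mask(clusters, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for c in clusters:
        out[c.coords[:, 0], c.coords[:, 1], c.coords[:, 2]] = True
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def noisefree_gc():
    """Noise-free single-GC phantom: plateau 200, halo 10, background 80."""
    spec = g.single_gc_spec((12, 64, 64), noise_sigma=0.0, seed=0)
    return g.make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_gc():
    """Single-GC phantom with read noise sigma 5 (the study condition)."""
    spec = g.single_gc_spec((12, 64, 64), noise_sigma=5.0, seed=3)
    return g.make_phantom(spec)


@pytest.fixture(scope="session")
def tile_base():
    """A wide 2-GC stack used as the stitching source image."""
    spec = g.grid_spec((6, 96, 160), n_gc=2, noise_sigma=5.0, seed=11)
    return g.make_phantom(spec)[0]
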