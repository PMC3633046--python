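"""Synthetic germinal-center phantoms with ground truth.

A germinal center (GC) in a PNA-stained confocal stack appears as a bright,
roughly ellipsoidal blob with a near-homogeneous fluorescent plateau,
surrounded by a dark ring ("halo") of unlabeled follicular/T-zone cells,
all embedded in moderately bright tissue background.  The phantom generator
reproduces exactly that three-level structure plus additive Gaussian read
noise, and returns the analytic ground-truth label volume, so every
downstream stage of the pipeline can be tested without external data.

The generator works in voxel units; physical sizes come from the
:class:`~gcvol.stacks.ImageStack` spacing, which decouples the geometry
from the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stacks import ImageStack, DEFAULT_SPACING

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "make_tile_pair",
    "single_gc_spec",
    "grid_spec",
]


@dataclass
class PhantomSpec:
    """Recipe for a synthetic GC stack.

    ``gc_list`` entries are ``(center_zyx, semiaxes_zyx, plateau_intensity)``
    with centers and semi-axes in voxels.  Intensity ordering must encode
    the GC structure: ``plateau > background > halo >= 0``.
    """

    shape: tuple[int, int, int]
    gc_list: list[tuple[tuple[float, float, float], tuple[float, float, float], float]]
    halo_intensity: float = 10.0
    halo_thickness: float = 3.0
    background_intensity: float = 80.0
    noise_sigma: float = 5.0
    seed: int = 0
    dtype: np.dtype = field(default_factory=lambda: np.dtype(np.uint8))

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)  # type: ignore[assignment]
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be (nz, ny, nx) with all dims >= 1")
        for _, axes, plateau in self.gc_list:
            if any(a < 1 for a in axes):
                raise ValueError("ellipsoid semi-axes must be >= 1 voxel")
            if not plateau > self.background_intensity:
                raise ValueError("plateau intensity must exceed background")
        if not self.background_intensity > self.halo_intensity >= 0:
            raise ValueError("need plateau > background > halo >= 0")
        if self.halo_thickness < 0:
            raise ValueError("halo thickness must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class GroundTruth:
    """Analytic truth for a phantom: label volume and per-GC volumes.

    ``label_volume`` holds 0 for background and ``j >= 1`` for voxels whose
    centers lie inside the ellipsoid of ``gc_list[j-1]``.  ``true_volumes``
    are the continuous ellipsoid volumes 4/3*pi*a*b*c in µm³ (the voxel
    count times the voxel volume converges to this as resolution grows).
    """

    label_volume: np.ndarray
    true_volumes: list[float]

    def mask(self, j: int | None = None) -> np.ndarray:
        """Boolean foreground mask (of GC ``j``, or of all GCs)."""
        if j is None:
            return self.label_volume > 0
        return self.label_volume == j


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    axes: tuple[float, float, float],
) -> np.ndarray:
    """Voxels whose centers satisfy the implicit ellipsoid inequality."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(
    spec: PhantomSpec,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ImageStack, GroundTruth]:
    """Render a phantom stack and its ground truth.

    The volume starts at the background level, each GC's halo shell is
    painted dark, then the ellipsoid interior is painted at its plateau
    level; finally zero-mean Gaussian noise is added and the result is
    rounded and clipped to the dtype range.  Deterministic for a fixed
    ``spec.seed``.

    Raises
    ------
    ValueError
        If any two GCs (including their halo shells) overlap.
    """
    img = np.full(spec.shape, float(spec.background_intensity))
    labels = np.zeros(spec.shape, dtype=np.int32)
    occupied = np.zeros(spec.shape, dtype=bool)
    dx, dy, dz = spacing
    true_volumes: list[float] = []

    for j, (center, axes, plateau) in enumerate(spec.gc_list, start=1):
        outer_axes = tuple(a + spec.halo_thickness for a in axes)
        outer = _ellipsoid_mask(spec.shape, center, outer_axes)
        if np.any(outer & occupied):
            raise ValueError(f"GC {j} (including halo) overlaps a previous GC")
        occupied |= outer
        inner = _ellipsoid_mask(spec.shape, center, axes)
        img[outer & ~inner] = float(spec.halo_intensity)
        img[inner] = float(plateau)
        labels[inner] = j
        az, ay, ax = axes
        true_volumes.append(4.0 / 3.0 * np.pi * (az * dz) * (ay * dy) * (ax * dx))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    lo, hi = 0, np.iinfo(spec.dtype).max
    voxels = np.clip(np.rint(img), lo, hi).astype(spec.dtype)
    stack = ImageStack(voxels=voxels, channel_label="phantom", spacing=spacing)
    return stack, GroundTruth(label_volume=labels, true_volumes=true_volumes)


def single_gc_spec(
    shape: tuple[int, int, int] = (12, 64, 64),
    *,
    semiaxes: tuple[float, float, float] | None = None,
    plateau: float = 200.0,
    halo: float = 10.0,
    background: float = 80.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """A centred single-GC phantom recipe at the standard study intensities.

    Defaults emulate the acquisition regime the pipeline targets: bright
    plateau 200, dark halo 10, tissue background 80 on an 8-bit scale, read
    noise sigma 5.  The ellipsoid fills roughly half the field of view.
    """
    nz, ny, nx = shape
    if semiaxes is None:
        semiaxes = (max(nz / 3.0, 1.5), ny / 4.0, nx / 4.0)
    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    return PhantomSpec(
        shape=shape,
        gc_list=[(center, semiaxes, plateau)],
        halo_intensity=halo,
        background_intensity=background,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def grid_spec(
    shape: tuple[int, int, int],
    n_gc: int = 3,
    *,
    plateau: float = 200.0,
    halo: float = 10.0,
    background: float = 80.0,
    halo_thickness: float = 3.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """A phantom with ``n_gc`` disjoint GCs laid out on a horizontal grid.

    Ellipsoid sizes are chosen so each GC plus its halo fits its grid cell
    with margin; z extent is roughly half the stack depth, matching blobs
    that fade in and out of the imaged volume.
    """
    nz, ny, nx = shape
    cols = int(np.ceil(np.sqrt(n_gc)))
    rows = int(np.ceil(n_gc / cols))
    cw, ch = nx / cols, ny / rows
    az = max(nz / 4.0, 1.5)
    ay = max(min(ch / 2.0 - halo_thickness - 2.0, ch / 3.0), 1.5)
    ax = max(min(cw / 2.0 - halo_thickness - 2.0, cw / 3.0), 1.5)
    gcs = []
    for g in range(n_gc):
        r, c = divmod(g, cols)
        center = ((nz - 1) / 2.0, (r + 0.5) * ch, (c + 0.5) * cw)
        gcs.append((center, (az, ay, ax), plateau))
    return PhantomSpec(
        shape=shape,
        gc_list=gcs,
        halo_intensity=halo,
        background_intensity=background,
        halo_thickness=halo_thickness,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_tile_pair(
    base: ImageStack,
    shift: tuple[int, int],
    overlap: float = 0.25,
    gain: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, tuple[int, int]]:
    """Cut two horizontally adjacent, overlapping tiles out of ``base``.

    Tile A sits at the origin of ``base``; tile B nominally starts at
    ``x0 = round((1 - overlap) * W)`` (sharing an ``overlap``-fraction
    strip with A) and is additionally displaced by ``shift = (dy, dx)``.
    Tile B is multiplied by ``gain`` and, like A, gets independent Gaussian
    noise.  Returns ``(tile_a, tile_b, true_shift)`` where ``true_shift``
    is the *absolute* offset of B relative to A, i.e. ``(dy, x0 + dx)``;
    the nominal grid offset ``(0, x0)`` is the natural registration prior,
    so ``true_shift - (0, x0) == shift``.

    Raises
    ------
    ValueError
        If ``overlap`` is not in (0, 1) or the shifted tile no longer fits
        in the base canvas / no longer overlaps tile A.
    """
    if not 0.0 < overlap < 1.0:
        raise ValueError("overlap fraction must be in (0, 1)")
    nz, H, W = base.shape
    dy, dx = int(shift[0]), int(shift[1])
    # tile width such that two tiles with an `overlap` strip span the base,
    # with margin for the shift perturbation
    tw = int((W - abs(dx)) / (2.0 - overlap))
    x0 = int(round((1.0 - overlap) * tw))
    th = H - abs(dy)
    if tw < 8 or th < 8:
        raise ValueError("base image too small for the requested tiling")
    bx = x0 + dx
    if bx < 0 or bx + tw > W:
        raise ValueError("shift pushes tile B outside the base canvas")
    if bx >= tw:
        raise ValueError("overlap too small for the requested shift (tiles disjoint)")

    ay0 = max(0, -dy)
    by0 = max(0, dy)
    a = base.voxels[:, ay0 : ay0 + th, 0:tw].astype(np.float64)
    b = base.voxels[:, by0 : by0 + th, bx : bx + tw].astype(np.float64) * float(gain)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sigma, a.shape)
        b = b + rng.normal(0.0, noise_sigma, b.shape)

    hi = np.iinfo(base.voxels.dtype).max
    mk = lambda arr: ImageStack(  # noqa: E731
        voxels=np.clip(np.rint(arr), 0, hi).astype(base.voxels.dtype),
        channel_label=base.channel_label,
        spacing=base.spacing,
    )
    return mk(a), mk(b), (dy, x0 + dx)
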