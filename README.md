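# gcvol — germinal-center volume extraction from 3D fluorescence z-stacks

Germinal centers (GCs) are the transient structures in lymphoid organs
where B cells proliferate and mutate during an immune response.  In
PNA-stained confocal z-stacks a GC appears as a bright, roughly
ellipsoidal blob with a near-homogeneous fluorescent plateau, separated
from the moderately bright surrounding tissue by a pronounced **dark halo
ring** of unlabeled cells.  Quantifying GC volumes by hand — tracing
borders slice by slice across dozens of stacks — is slow and subjective.

`gcvol` automates the whole pipeline for immunologists working with such
stacks:

* **3D spot finding** — voxels with intensity ≥ a global threshold *t_h*
  are grown into maximal 26-connected clusters across all directions
  *xyz*; clusters smaller than the minimum spot size *s*<sub>min</sub>
  voxels are cut.
* **Self-tuning threshold selection** — the free parameters
  λ = (*t_h*, *s*<sub>min</sub>) are chosen automatically by minimising a
  stability objective.  For the *j*-th GC, with per-slice regions
  γ<sub>jn</sub>(λ), areas *a*<sub>jn</sub> and pixel-tone histograms
  *H*<sub>jn</sub>, comparing λ<sub>t</sub> against the neighbouring
  parameter value λ<sub>t′</sub> (*t_h*′ = *t_h* + 1):

      L_j(λt, λt') = Σ_n exp[ α·D(H_jn(λt), H_jn(λt')) ]
                     ─────────────────────────────────────
                     ε + β·Σ_n A_jn(λt, λt')

  where `D` is the Bhattacharyya histogram distance
  (1 − Σ<sub>k</sub> √(Ĥ<sub>a</sub>Ĥ<sub>b</sub>)) and
  `A_jn = (|a+a'| − |a−a'|)/|a+a'|` compares per-slice areas (defaults
  α = 0.001, β = 1.0, ε = 10⁻⁹).  A stable segmentation gives
  L<sub>j</sub> ≈ 1/β; a contour that vanishes between neighbouring
  thresholds drives A → 0 and L<sub>j</sub> → N/ε.  The minimum therefore
  sits where the border locks onto the dark halo, and λ* = argmin Σ L_j is
  found by seeded simulated annealing plus a deterministic tie-breaking
  refinement.
* **Quantification & surfaces** — per-GC voxel-count volumes in µm³,
  per-slice convex-hull borders with 2σ outlier pruning, and closed
  (watertight) lofted surface meshes exported in the Geomview OFF format.
* **Mosaic stitching** — Fourier phase-correlation registration of
  overlapping tiles around stage-position priors, per-tile exposure gain
  matching, and Laplacian-pyramid seam blending.
* **Synthetic phantoms** — a generator for GC phantoms with analytic
  ground truth, so the whole pipeline is testable end to end without
  microscope data.

## Worked example

`examples/03_auto_threshold.py` builds a noisy single-GC phantom
(plateau 200, halo 10, background 80, noise σ = 5 on an 8-bit scale) and
tunes λ from three different starting points:

```
sweep: min L = 1.000000 at t_h = 88, max L = 3.6e+10 (instability wall)
init (t_h=120, s_min=50) -> λ* = (89, 20), L* = 1.000000, 1135 evaluations
init (t_h=150, s_min=200) -> λ* = (89, 20), L* = 1.000000, 2113 evaluations
init (t_h=185, s_min=400) -> λ* = (89, 20), L* = 1.000000, 3054 evaluations
Dice against ground truth at λ*: 1.0000
```

The 1-D landscape cut has a single flat valley (L ≈ 1, one stable
cluster) bounded by ~10¹⁰ instability walls where noise clusters flicker
between *t_h* and *t_h* + 1; all three initialisations converge to the
identical λ*, and the tuned segmentation matches the analytic ground
truth voxel-for-voxel (Dice 1.0).  `examples/02_segment_and_quantify.py`
then prints calibrated volumes:

```
GC 1: 6474 voxels = 4536.3 µm³ (analytic 4508.3), slices 3..8, centroid (16.8, 33.6, 7.9) µm
```

The 0.6% gap against the analytic ellipsoid volume is lattice
discretisation, not segmentation error.

The same pipeline is scriptable from the shell:

```sh
gcvol phantom --out phantom.tif --shape 10,72,72 --n-gc 3 --seed 4
gcvol extract phantom.tif --th 150 --smin 30 --th-min 40 --smin-max 500 \
      --dx 0.7 --dy 0.7 --dz 1.43 --outdir out
gcvol sweep phantom.tif --smin 100 --out landscape.csv
gcvol stitch tile1.tif tile2.tif --priors "0,58" --outdir mosaic
```

`extract` writes `gc_report.csv` (one row per GC: voxels, volume in µm³,
slice span, bounding box, centroid), a 16-bit label TIFF, one OFF mesh
per GC, the optimisation trace and the resolved run config; reruns with
the same seed are byte-identical.

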