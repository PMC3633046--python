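# Methods

This note documents the models and algorithms implemented in `gcvol`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Image model and segmentation

A stack is a calibrated voxel grid `(z, y, x)` of non-negative integers
(8- or 16-bit), with voxel size `(dx, dy, dz)` in µm; a voxel spans a
physical box, so a cluster's volume is `count · dx·dy·dz`.  Typical
acquisitions are 512×512 pixels × ~30–35 slices at a 1.43 µm z-step,
which is the default calibration when a file carries no metadata.

Spot finding thresholds the stack at the global intensity *t_h*
(inclusive: a voxel is admitted iff intensity ≥ *t_h*, making *t_h* the
minimum admitted level) and labels maximal connected components.
Connectivity defaults to 26 (diagonal neighbours on the same and adjacent
slices count; 6-connectivity is available as an option).  Components with
fewer than *s*<sub>min</sub> voxels are discarded — a cut on the total 3D
voxel count, not per-slice area.  Labeling is delegated to
`scipy.ndimage.label` with the corresponding structuring element; the
test suite checks the partition against an independent brute-force BFS
flood fill on hundreds of random stacks, exactly.  Clusters are ordered
largest-first (ties: lexicographically smallest voxel) so results are
reproducible.

Each cluster carries its per-slice decomposition: regions γ<sub>jn</sub>,
areas *a*<sub>jn</sub> = |γ<sub>jn</sub>|, and per-slice intensity
histograms *H*<sub>jn</sub> with **64 bins spanning the dtype range**.
64 bins keep the Bhattacharyya distance stable on small regions; the
count is a constant of the implementation, and histograms are unit-sum
normalised only inside the distance.

## The stability objective

The free parameters λ = (*t_h*, *s*<sub>min</sub>) are scored by
comparing the segmentation at λ<sub>t</sub> with the segmentation at the
neighbouring value λ<sub>t′</sub>, where *t_h*′ = *t_h* +
`neighbor_offset` (default +1) and *s*<sub>min</sub> is shared:

    L_j = Σ_n exp[α·D(H_jn(λt), H_jn(λt′))] / (ε + β·Σ_n A_jn)

with defaults α = 0.001, β = 1.0, ε = 10⁻⁹.  `D` is implemented as the
standard Bhattacharyya form `1 − Σ_k √(Ĥa(k)·Ĥb(k))` on unit-normalised
histograms: 0 for identical histograms, 1 for disjoint support,
symmetric.  `A(a, a′) = (|a+a′| − |a−a′|)/|a+a′|` equals
`2·min(a,a′)/(a+a′)`: 1 at equal areas, 0 when exactly one vanishes;
`A(0,0)` is defined as 0 and slices empty on both sides are skipped.  A
slice whose region exists on one side only contributes the maximal
distance D = 1 and A = 0 — the vanishing-contour penalty that dominates
the landscape (`L → N/ε`).

Cluster correspondence between the two segmentations is established by
greedy maximal-voxel-overlap matching (deterministic tie-breaks); a
cluster with no partner is paired with an empty segmentation, driving its
A terms to 0.  The total objective is Σ<sub>j</sub> L<sub>j</sub> over
the clusters at λ<sub>t</sub>.

The halo fraction N_f/N_t (above-threshold pixels in a user-supplied
annulus around a border) is reported as a **diagnostic only**; it is not
a term of L.  Likewise, only the stochastic search below is implemented —
no analytic gradients of L.

### Landscape anatomy (what the optimiser actually faces)

L is piecewise constant in λ: segmentations change only when *t_h*
crosses an occupied intensity level.  On GC-like images three regimes
appear, confirmed by the test suite's 1-D sweeps:

* a **flat valley**, where the segmentation is identical at *t_h* and
  *t_h*+1 (the border sits in the sparsely populated intensity gap of the
  dark halo): L is *exactly* constant there, ≈ 1/β per stable cluster;
* **instability walls** (values ~N/ε ≈ 10¹⁰), where thresholding inside
  a noise mode makes clusters larger than *s*<sub>min</sub> flicker
  between the two neighbouring thresholds;
* distant **degenerate regimes** with *fewer* clusters.  Because each
  stable cluster contributes ≈ 1/β, the raw sum is lower wherever fewer
  clusters survive — e.g. a threshold below the tissue background that
  merges everything into one blob, or an *s*<sub>min</sub> just below the
  largest GC that silently discards the others.  This is an intrinsic
  property of the objective, not an implementation artifact.

## Optimisation

Simulated annealing with geometric cooling `T ← 0.95·T`, 20 Metropolis
proposals per temperature, stopping at `T < 10⁻³·T₀` or after 50
temperatures without improvement.  T₀ is the spread of the objective over
the seed and 8 random neighbours.  Proposals move *t_h* by ±uniform{1..5}
and scale *s*<sub>min</sub> by uniform[0.8, 1.25] (rounded), clipped to
user bounds; a grid mode restricts the walk to explicit candidate lists
instead.  Every (t_h, s_min) evaluation is cached, so revisits are free
and runs with the same RNG seed are bit-identical.  The instability walls
are effectively impassable once T has dropped, which makes the search
local around the user's seed — matching the intended workflow, where the
user seeds the threshold in the bright regime by eye.

Because the valley floor is exactly flat, no purely stochastic search can
return a reproducible λ*.  `optimize` therefore ends with a deterministic
**tie-breaking refinement** (on by default): adopt the loosest admissible
*s*<sub>min</sub> whenever it ties the optimum, then walk *t_h* downward
through the contiguous basin (bridging micro-bumps up to a relative 10⁻³,
stopping at the first wall), iterated to a fixed point.  The preference —
the most *inclusive* stable segmentation, lowest *t_h* then lowest
*s*<sub>min</sub> — implements the design goal that λ should maximise the
segmented areas while staying stable.  The refinement only ever moves
within the basin the annealer ended in; it deliberately does not jump to
the degenerate fewer-cluster regimes even though their raw Σ L is lower.

**Practical guidance / limitation.**  On stacks with several GCs, give
the optimiser bounds that encode prior knowledge of scale: a threshold
floor above the merge-everything regime and an *s*<sub>min</sub> ceiling
below the smallest object of interest (the extraction workflow accepts a
user maximum size for exactly this reason).  Without bounds the walk can
drift into a degenerate regime on long runs: one seeded run in three on
an unbounded two-GC benchmark returned the merged-background solution.
With a single GC, or with such bounds, recovery is exact on the phantom
benchmarks (Dice 1.0) and independent of the initialisation.

## Quantification and surfaces

Volumes are voxel counts times the voxel volume — never derived from the
mesh, and identical by construction to Σ *a*<sub>jn</sub>·dx·dy·dz.
Reports add slice span, bounding box and centroid in µm.

Per-slice borders are convex hulls of the region's pixel coordinates
(degenerate regions — a single pixel or collinear pixels — keep the
degenerate polygon and count their area as the pixel count, so the area
the objective uses is always |γ|).  The 2σ outlier rule removes contour
points whose distance to the geometric centre exceeds mean + 2σ of all
centre distances (O(n)); the full pairwise-distance variant is available
behind a flag.  At most 20% of the points are removed per pass.

The 3D surface is a **loft**: consecutive slice hulls are joined by a
merged angular sweep producing m+k triangles per ring pair, with fan caps
at the ends; any slice whose hull is degenerate falls back to the hull of
its pixel-corner boxes, so every ring is a proper convex polygon and the
mesh is always closed with V − E + F = 2 (asserted in tests).  A
single-slice cluster becomes a flat prism of thickness dz.  Surfaces are
written as standard OFF files (`OFF`, `V F E` counts, vertices, faces).
Medial-axis (power-diagram) reconstruction is out of scope; the loft
serves the same purpose — visual confirmation and export — without
affecting any quantification.

## Stitching

Registration inverts the unit-magnitude cross-power spectrum of one
representative slice per stack (the maximum-variance slice; the offset is
applied rigidly to all slices) and takes the integer-pixel peak within
±`search_window` of the stage-position prior.  Windowed search matters:
multi-GC fields can produce spurious global correlation peaks at the
GC-to-GC spacing, which the prior excludes.  The peak height (1.0 for a
perfect periodic match) is reported; low peaks are flagged and the
workflow falls back to the prior.  No subpixel refinement is attempted.

Exposure differences are compensated by a single multiplicative gain per
tile, the ratio of overlap-region means against the mosaic built so far
(first tile = reference); no vignetting model.  Seams are hidden by a
Laplacian-pyramid blend: the mask ramps across the overlap via
distance-transform feathering, pyramid depth is `floor(log₂(overlap
width))` capped at 4, with a plain linear blend for overlaps under 16 px.
Blending uses the form `b + M·(a − b)`, which is exact wherever the two
sources agree, and is applied only inside the overlap — pixels covered by
a single tile equal their gain-scaled source exactly.

## Synthetic phantoms: what they do and do not show

`make_phantom` renders the canonical GC geometry — ellipsoidal plateaus
(voxel centre inside the implicit ellipsoid equation, which matches the
brute-force lattice-count volume oracle), a dark halo shell, homogeneous
background — plus additive zero-mean Gaussian noise, rounded and clipped
to the dtype.  Defaults encode the study conditions on an 8-bit scale:
plateau 200, background 80, halo 10, noise σ = 5, halo thickness 3
voxels.  Phantoms are specified in voxel units; physical size enters only
through the stack spacing.  GCs (including halos) must be pairwise
disjoint, and ground truth is the analytic ellipsoid interior.

What passing phantom benchmarks shows: the segmentation, objective,
optimiser, quantification and stitching behave exactly as specified on
images that match the model (sharp three-level structure, additive
Gaussian noise, rigid integer tile offsets).  What it does not show:
robustness to PSF blur (real borders are smooth gradients, which widen
the valley walls), photobleaching or depth-dependent attenuation,
channel crosstalk, anisotropic or structured noise, and non-rigid tile
distortion — none of which the generator simulates.  On real data the
valley is correspondingly shallower and a sanity check of the halo
fraction diagnostic on the final borders is recommended.

## Numerical and format choices

* Threshold comparison is inclusive (≥ *t_h*); documented so
  segmentations are reproducible across implementations.
* Histograms: 64 bins over the dtype range; all-zero histograms are
  rejected rather than silently normalised.
* CSV output: comma-separated, header row, UTF-8, floats at 6
  significant digits — reruns with the same seed are byte-identical.
* TIFF I/O is plain multi-page grayscale (8/16-bit) via `tifffile`;
  channel-interleaved page sequences are supported with an explicit
  interleave factor; no OME-XML parsing.  Round trips are bit-exact.
* All randomness (phantom noise, annealing proposals) flows from
  explicit integer seeds through `numpy.random.default_rng`.

## Benchmark scales

The test suite and the acceptance script run phantoms at 64×64×12 (the
optimisation studies, where the full landscape is swept), 24³ (volume
oracles), 96×160 tiles (stitching), and one 512×512×35 stack for the
end-to-end extraction determinism check — the acquisition-scale geometry
with segmentation parameters supplied directly.  These sizes exercise
every code path at full fidelity; nothing in the algorithms is
scale-dependent beyond linear cost in voxel count.
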