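# Methods

This document describes the algorithms, conventions and default parameters
implemented in `projcomp`. All of them are the package's own choices; every
quantitative claim here is enforced by a test.

## Coordinate conventions

* Volumes are indexed `(x, y, z)` with 0-based integer indices; axis `x` is
  left–right, `y` is posterior→anterior, `z` is inferior→superior.
* The center of voxel `i` lies at `(i + 0.5) * spacing` millimetres, so a
  volume of shape `n` spans `[0, n * spacing)` mm.
* Coronal sections are fixed-`y` planes; the anterior–posterior (A-P) axis is
  `y`. A-P coordinates are reported relative to a stated origin (an analog of
  stereotaxic ear-bar zero); the atlas places it at the volume's mid-`y`.
* Section stacks are arrays `(n_sections, nx, nz)`: section index along the
  A-P axis, in-plane axes matching the volume's `x` and `z`.

## Phantom

**Atlas.** The brain is an axis-aligned ellipsoid with semi-axes 0.45 of the
volume extent. It is partitioned into `n_regions` convex, connected regions
by a nearest-center Voronoi tessellation of points placed on a Fibonacci ball
(at 0.55 of the brain radii), giving deterministic, roughly equal-volume
regions labeled `1..n`, with `0` outside the brain.

**Tracts.** Each tract is a piecewise-linear centerline through specified
control points, carrying a radius. Tube masks are exact: a voxel belongs to
the tube when its center lies within the radius of the densely resampled
centerline (sampling step = voxel/4). Each tube voxel also stores the local
centerline tangent. Tests verify tube masks against a brute-force
point-to-segment oracle.

**Fluorescence sections.** The green channel contains per-axon strokes
(individual axons jittered inside the tube, intensity 100), somata at the
injection site (intensity 800, brighter than axons by construction), shared
lipofuscin-like puncta drawn at identical locations in green and red with
independently drawn intensities in 150–400, a background level of 20 and
Gaussian noise (SD 5). The red channel contains only puncta, background and
noise. Ground truth (axon mask, soma mask, their union as the GFP mask,
puncta centroids, injection mask and center) is returned alongside the
stack.

**Diffusion signal.** The DWI signal is the monoexponential tensor model
`S(g) = S0 · exp(-b gᵀDg)` on the atlas grid: inside tube masks `D` is
prolate along the local tangent with eigenvalues `(1.5, 0.3, 0.3)×10⁻³
mm²/s` (FA = 0.7698, closed form); elsewhere in the brain `D` is isotropic
(`0.7×10⁻³ mm²/s`); outside the brain `S0 = 0`, so under Rician noise the
background is pure Rayleigh noise as in magnitude MRI. The gradient scheme
is 60 Fibonacci-sphere directions at b = 4000 s/mm² plus five b = 0 volumes.

**Default scale.** The default phantom is 32×48×32 voxels at 0.5 mm with
50 µm in-plane pixels and a 100 µm section interval. These spacings are
integer divisors of both analysis grids (200 µm and 500 µm), so density
binning is exact. A full-brain scale (hundreds of multi-megapixel sections)
would put classifier training far beyond desk runtime; the reduced scale
preserves every pipeline property that the package quantifies. One
consequence for thresholds is documented below.

## Segmentation

Two approaches separate axonal green signal from puncta that fluoresce in
both channels:

* **Channel subtraction** `clip(green − s·red, 0)`. The scale `s` is either
  1 (`norm_mode="unit"`) or estimated from candidate puncta
  (`"puncta-quantile"`, default): over the brightest 0.5 % of red pixels,
  `s` is the ratio of the 99th-percentile green to 99th-percentile red
  intensity, which is robust to global gain differences.
* **Trainable pixel classifier** (used for all quantitative outputs): a
  random forest (40 trees, depth ≤ 16, fixed seed) over a fixed 12-feature
  bank — raw green/red, green/(red+1), Gaussian-smoothed green and red at
  σ ∈ {1, 2, 4} px, green gradient magnitude at σ ∈ {1, 2}, and a
  bright-ridge (tubularity) response on green. Training pixels are sampled
  class-balanced from ground-truth sections; in the pipeline, the sections
  with the most GFP-positive pixels are used for training and the next ones
  are held out for scoring.

Segmentations are scored with precision, recall and their harmonic mean
(F-score). Empty-denominator conventions: empty prediction and empty truth
score (1, 1, 1); no predicted positives against non-empty truth gives
precision 0; predictions against empty truth give recall 0.

## Projectome density

**Binning.** Positive pixels of a segmented section stack are counted into
coarse grid cells (200 µm for projectome quantification, 500 µm for the
tractography comparison). The grid spacing must be an integer multiple of
the pixel size and of the section interval — there is no resampling
heuristic — so binning is exact and conserves the total count (tested as
integer equality).

**Count threshold.** The library default false-positive filter on density
counts is `10^2.8 ≈ 631` positive pixels per cell
(`projcomp.density.INTENSITY_THRESHOLD`), appropriate when cells aggregate
sub-micrometre pixels by the hundreds of thousands. At the default phantom
scale a 500 µm cell contains at most `10×10×5 = 500` pixels (50 µm pixels,
100 µm sections), so that default is unreachable; the *pipeline*
configuration therefore defaults to a count threshold of 5, scaled to the
phantom's pixel budget. Both values are explicit, serialised configuration
fields.

**Region statistics.** For each atlas region: `percent_total` is the
region's positive-pixel count as a percentage of all positive pixels (label
0, "outside", is included so the column sums to exactly 100), and
`innervation_density_percent` is the region's count per voxel as a
percentage of the maximal per-voxel regional density (the densest region
scores 100).

**A-P profile.** Counts are summed per coronal slice and reported at slice
centers in mm relative to the ear-bar-zero analog, with percent-of-total.

**Cluster extents.** Connected components (26-connectivity) of a thresholded
density volume are measured along the section axis; the extent counts slices
inclusively (a one-slice cluster has extent equal to the slice spacing).

**Injection site.** Somata are rendered brighter than axons, so green pixels
above a soma threshold (pipeline default 500, between the axon intensity 100
and soma intensity 800) localise the injected cell bodies; coarse cells with
at least 3 suprathreshold pixels form the injection-site mask, which seeds
the tractography. A warning is emitted if the threshold does not exceed the
axon intensity.

## Tractography

**Tensor fit.** Voxel-wise log-linear least squares:
`ln S = ln S0 − b gᵀDg` is linear in `(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`
with design row `[1, −b gx², −b gy², −b gz², −2b gxgy, −2b gxgz, −2b gygz]`.
With ≥ 6 distinct directions and ≥ 1 b0 the design has full rank and a
noise-free monoexponential signal is inverted exactly (tested to 1e-8
relative eigenvalue error). Eigenvalues are sorted descending;
`FA = sqrt(1.5 · Σ(λᵢ − mean λ)² / Σλᵢ²)`. The fit optionally stores the
fitted log-signal, log-residuals and the design pseudoinverse for the
residual bootstrap.

**SNR.** Two-region SNR per volume: mean over a tissue region divided by
the SD (ddof = 1) over a signal-free region (≥ 27 voxels each, disjoint).
Optionally the Rayleigh correction multiplies by `sqrt(2 − π/2)`, converting
the magnitude-background SD to the underlying Gaussian σ.

**Tracker.** Streamlines advance by fixed steps along a direction derived
from the trilinearly interpolated tensor (the six unique components are
interpolated, then the eigensystem is recomputed at the point — not an
interpolation of eigenvectors). Direction models:

* `deterministic` — the principal eigenvector;
* `perturbed-principal` — the principal eigenvector plus isotropic Gaussian
  noise with σ = perturbation × (1 − FA) (default perturbation 0.3), so
  dispersion grows where the tensor is ambiguous;
* `residual-bootstrap` — per streamline, the voxel-wise log-residuals are
  resampled with replacement, added to the fitted log-signal, and the tensor
  is re-fitted at each interpolated point; with zero residuals this
  collapses to the exact tensor (tested).

Each step direction is sign-aligned with the previous step (the first step
with the launch orientation). Termination rules: leaving the grid or the
fit mask; interpolated FA at the *new* position below `fa_cutoff`; cosine
between successive steps below the minimum cosine; exceeding the length
bound; and, when the loop check is enabled, entering any voxel more than
twice. When both a curvature threshold (minimum cosine) and a maximum angle
are set, the stricter applies.

**Presets.**

* *visitation*: 0.2 mm steps, curvature threshold 0.2 (≈ 78.46° maximum
  turn), 5000 samples per seed voxel, 2000 steps, loop check, bidirectional,
  perturbed-principal directions.
* *bowtie* (long-association-bundle reconstruction): 0.25 mm steps, 45°
  maximum angle, 10–150 mm length bounds, FA cutoff 0.1, up to 10,000
  accepted fibers, unidirectional, residual-bootstrap directions.

The pipeline's visitation runs override `fa_cutoff` to 0.15: the phantom has
exactly two tissue classes (tube FA 0.7698, isotropic FA 0), and a small
positive cutoff terminates samples cleanly at the tube boundary; 0.15 stays
well below any fitted tube FA at the pipeline's noise level while excluding
the isotropic compartment.

**Reproducibility.** Monte-Carlo samples use counter-based Philox substreams
keyed by the run seed and jumped per global streamline index, so visitation
maps are bit-identical across batch sizes and iteration orders (tested).

**Visitation maps** count, per voxel, the number of distinct samples whose
trajectory enters it — a sample increments a voxel at most once, and every
sample counts its own seed voxel, so a single-voxel seed yields a seed count
exactly equal to the number of samples.

**Waypoint filtering** keeps streamlines that traverse every inclusion mask,
avoid every exclusion mask and fall within length bounds (membership via the
voxels visited by the polyline vertices). **Track-density images** count
streamlines per voxel, each streamline at most once per voxel.

## Overlap statistics

Between a tract map (visitation or track-density) and an axon density map on
a common grid, after per-volume thresholding (binarisation is inclusive,
`value ≥ threshold`):

* **Dice** `2|A∩B| / (|A|+|B|)`; NaN when both masks are empty.
* **Szymkiewicz–Simpson** `|A∩B| / min(|A|,|B|)`: 1 when the smaller set is
  contained in the larger; NaN when either mask is empty. The normaliser is
  the *smaller set's size*, not the union (the union normaliser is the
  Jaccard index, a different statistic).
* **Pearson r** over a support of voxels: `"union"` (default) uses voxels
  non-zero in either map, optionally within a brain mask — shared empty
  background otherwise inflates the correlation; `"all"` uses every voxel.
  NaN when the support has fewer than two voxels or either map has zero
  variance on it.

Profiles are computed per coronal slice along the A-P axis; slices where
either thresholded map is empty are reported as missing (NaN, serialised as
`NA`), never zero-filled, and summaries (mean ± SD, ddof = 1) average only
over valid slices. 3D scalars are computed on the full volumes. An optional
weighted Dice `2·Σ min(a,b) / Σ(a+b)` on thresholded intensities is
available.

## Pipeline

`projcomp run config.yaml` executes phantom → segmentation → density →
tractography → comparison. Stage seeds are derived deterministically from
the run seed (`(seed · 1000003 + k) mod (2³¹ − 1)` for stage index `k`), so
stages are independently reproducible. The manifest records the package
version, the full configuration and its SHA-256 hash, per-stage artifact
classes, results summaries and a SHA-256 checksum of every artifact (plots
excluded — compressed PNG encoding is not specified to be stable across
library versions). Volumes are written as *uncompressed* NIfTI-1
specifically so checksums are reproducible (gzip embeds timestamps).
Identical configurations reproduce identical checksums (tested).

Unknown configuration keys are rejected rather than ignored, so typos fail
loudly. A stage failure raises `PipelineError` naming the stage; completed
stages' outputs remain on disk.

## Limitations

* The phantom's diffusion signal is single-tensor per voxel; crossing-fiber
  models are out of scope, and the residual bootstrap explores fit
  uncertainty, not fiber dispersion.
* Tube tracts are piecewise-linear with constant radius; no fanning,
  branching or terminal arborisation.
* Section rendering assumes perfect alignment (as in block-face imaging);
  no registration errors are simulated.
* The cluster-extent statistic depends strongly on the count threshold; at
  the default scale, thresholded 200 µm cells fragment thin axon bundles
  into small clusters. The threshold is a reported, serialised parameter.
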