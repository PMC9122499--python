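# projcomp

Cross-modal comparison of axonal projection maps and diffusion tractography
on synthetic brain phantoms.

`projcomp` builds a fully synthetic "brain": a labeled atlas volume, smooth
axon-bundle tracts with known tube geometry, serial two-channel fluorescence
sections (green axons/somata plus lipofuscin-like puncta that bleed into both
channels), and a diffusion-weighted MRI signal with the same tracts encoded as
prolate tensors. Because every voxel of ground truth is known, the package can
quantify each stage of a tracer-vs-tractography comparison pipeline:

1. **phantom** — atlas, tracts, section stacks, DWI, and exact ground-truth
   masks (`projcomp.phantom`);
2. **segmentation** — autofluorescence channel subtraction and a trainable
   random-forest pixel classifier, scored with the precision–recall F measure
   (`projcomp.segmentation`);
3. **projectome density** — 200 µm / 500 µm density binning, per-region
   projection percentages and innervation densities, anterior–posterior
   profiles, cluster section-axis extents, injection-site localisation
   (`projcomp.density`);
4. **tractography** — log-linear diffusion tensor fit, two-region SNR,
   probabilistic streamline tracking with two presets, waypoint filtering,
   track-density images (`projcomp.tractography`);
5. **overlap** — slice-wise and 3D Dice, Pearson and Szymkiewicz–Simpson
   statistics between the tract map and the axon density map
   (`projcomp.overlap`);
6. **pipeline / CLI** — one-command orchestration with a reproducible run
   manifest (`projcomp.pipeline`, `projcomp` console script).

## Worked example

### Library quick start

```python
import numpy as np
from projcomp import overlap, phantom, tractography

# two binary volumes constructed to share exactly half of the smaller set
a, b = phantom.make_overlap_phantom(0.5, (10, 10, 10), size_a=100, size_b=200)
print(overlap.simpson_overlap(a, b))   # 0.5
print(overlap.dice(a, b))              # 0.3333333333333333

# Pearson on matched maps (hand-checkable): r = 0.8
x = np.array([1.0, 2.0, 3.0, 4.0])
y = np.array([1.0, 3.0, 2.0, 4.0])
print(overlap.pearson_map(x, y, support_mode="all"))  # 0.7999999999999998

# closed-form FA of the phantom's tube tensor (1.5, 0.3, 0.3) x 1e-3 mm^2/s
print(tractography.fa_from_eigenvalues([1.5e-3, 0.3e-3, 0.3e-3]))
# 0.7698003589195009
```

### Full pipeline

```bash
projcomp demo --out config.yaml --seed 0   # write the default configuration
projcomp run config.yaml                   # run all five stages
```

The default run (seed 0) finishes in about a minute on one CPU and prints a
manifest path. Key numbers from `projcomp_run/manifest.json` for that exact
configuration:

| quantity | value |
|---|---|
| held-out classifier F-score (4 test sections) | 0.9933 |
| two-region SNR, b = 0 volumes | 72.29 |
| two-region SNR, diffusion-weighted volumes | 10.13 |
| streamlines generated / retained by waypoint filter | 612 / 595 |
| slice-wise Dice (mean ± SD over 24 valid slices) | 0.7366 ± 0.1295 |
| slice-wise Pearson r (mean ± SD) | 0.4019 ± 0.2589 |
| slice-wise Simpson (mean ± SD) | 0.9075 ± 0.0996 |
| 3D Dice / Simpson | 0.7395 / 0.8647 |

Per-region projection table from the same run
(`projcomp_run/density/region_table.tsv`; the injection is placed in
region 1 and tracts target regions 2–4 with relative densities 3 : 1.5 : 0.5):

| label | name | positive pixels | % of total | innervation density % |
|---|---|---|---|---|
| 0 | outside | 3 | 0.01 | 0.00 |
| 1 | region_1 | 11974 | 54.09 | 100.00 |
| 2 | region_2 | 5914 | 26.71 | 46.14 |
| 3 | region_3 | 2987 | 13.49 | 17.20 |
| 4 | region_4 | 1159 | 5.24 | 8.43 |
| 5 | region_5 | 102 | 0.46 | 0.84 |

The ordering region_2 > region_3 > region_4 recovers the planted relative
tract densities; region_1 dominates because it hosts the labeled somata.

Every artifact (NIfTI volumes, TIFF masks, TSV tables, TrackVis streamlines,
JSON summaries) is listed in the manifest with a SHA-256 checksum; re-running
the same configuration reproduces identical checksums bit for bit.

### Individual stages from the shell

```bash
projcomp track fit dwi.nii bvals bvecs --fa-out fa.nii
projcomp track prob dwi.nii bvals bvecs seed.nii --preset visitation \
    --n-samples 100 --fa-cutoff 0.15 --out visitmap.nii
projcomp compare slices visitmap.nii density.nii --tract-threshold 1 \
    --density-threshold 5 --out overlap      # writes overlap.tsv + overlap.json
```

Run `projcomp --help` (and `projcomp <group> --help`) for the full command
set: `run`, `demo`, `segment train/apply/score`, `density
build/regions/profile`, `track fit/prob/streamlines/filter`, `compare
slices/volume`.

## Documentation

`docs/methods.md` describes the phantom construction, the coordinate
conventions, every algorithm, and the package's default thresholds (including
where and why they deviate between pixel scales).
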