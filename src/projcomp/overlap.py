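"""Spatial-overlap statistics between tractography and axonal density maps.

Slice-wise Dice, pixel-wise Pearson correlation and Szymkiewicz-Simpson
overlap profiles along the anterior-posterior axis, plus 3D scalar
coefficients, between a co-gridded tract map (probabilistic visitation or
track-density image) and an axonal density map.

Conventions: binarisation is inclusive (voxel >= threshold); the
Szymkiewicz-Simpson coefficient is |A ∩ B| / min(|A|, |B|); undefined values
(empty masks, zero variance) are reported as missing (NaN), never zero-filled,
and summaries average only over valid slices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import DensityVolume, INTENSITY_THRESHOLD

__all__ = [
    "OverlapReport",
    "binarize",
    "dice",
    "simpson_overlap",
    "pearson_map",
    "slice_metrics",
]


def _as_array(vol) -> np.ndarray:
    if isinstance(vol, DensityVolume):
        return vol.counts
    return np.asarray(vol)


def binarize(volume, threshold: float) -> np.ndarray:
    """Inclusive threshold: voxel >= threshold -> 1, else 0.

    Note the boundary: threshold 0 marks every voxel, so meaningful masks
    need a strictly positive threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return _as_array(volume) >= threshold


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); NaN when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must be on the same grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return math.nan
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def simpson_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Szymkiewicz-Simpson coefficient |A∩B| / min(|A|,|B|).

    1 when the smaller set is contained in the larger, 0 when disjoint, NaN
    when either mask is empty (the coefficient is undefined).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must be on the same grid")
    na, nb = int(a.sum()), int(b.sum())
    if min(na, nb) == 0:
        return math.nan
    return int(np.logical_and(a, b).sum()) / min(na, nb)


def pearson_map(
    vol_a,
    vol_b,
    support_mode: str = "union",
    brain_mask: np.ndarray | None = None,
) -> float:
    """Pixel-wise Pearson correlation between two maps.

    ``support_mode`` chooses the voxels entering the correlation: ``"union"``
    uses voxels non-zero in either map (within ``brain_mask`` when given),
    avoiding inflation by the empty background; ``"all"`` uses every voxel
    (within the brain mask when given).  NaN when the support has fewer than
    two voxels or either map has zero variance on it.
    """
    a = _as_array(vol_a).astype(float)
    b = _as_array(vol_b).astype(float)
    if a.shape != b.shape:
        raise ValueError("maps must be on the same grid")
    if support_mode == "union":
        support = (a != 0) | (b != 0)
    elif support_mode == "all":
        support = np.ones(a.shape, dtype=bool)
    else:
        raise ValueError(f"unknown support_mode {support_mode!r}")
    if brain_mask is not None:
        support &= np.asarray(brain_mask, dtype=bool)
    x = a[support]
    y = b[support]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class OverlapReport:
    """Per-slice overlap profiles plus 3D scalars and their summaries.

    ``slices`` has one row per coronal slice with columns ap_mm, dice,
    pearson, simpson (NaN = missing).  ``summary`` carries the 3D Dice and
    Simpson coefficients and mean ± SD of each per-slice metric over valid
    slices; ``thresholds`` records the binarisation thresholds used.
    """

    slices: pd.DataFrame
    summary: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.thresholds.items():
                fh.write(f"# {k} = {v}\n")
            self.slices.to_csv(fh, sep="\t", index=False, na_rep="NA")

    def to_json(self, path) -> None:
        payload = {"summary": self.summary, "thresholds": self.thresholds}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)


def _mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    valid = values[~np.isnan(values)]
    if valid.size == 0:
        return math.nan, math.nan, 0
    sd = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
    return float(valid.mean()), sd, int(valid.size)


def slice_metrics(
    tract_map,
    density_map,
    tract_threshold: float,
    density_threshold: float = INTENSITY_THRESHOLD,
    axis_origin_mm: float = 0.0,
    slice_spacing_mm: float | None = None,
    support_mode: str = "union",
    brain_mask: np.ndarray | None = None,
    weighted_dice: bool = False,
) -> OverlapReport:
    """Slice-wise Dice / Pearson / Simpson along the A-P (y) axis plus 3D
    scalars, after per-volume thresholding.

    Both volumes must be co-gridded (generated in the common space).  Slices
    where either thresholded map is empty are missing.  The Pearson support
    per slice follows ``support_mode``; values below threshold are zeroed
    before correlating.  ``weighted_dice`` computes a weighted (Fleiss-style)
    Dice 2*sum(min)/sum(a+b) on the thresholded intensities instead of the
    binary one.
    """
    a = _as_array(tract_map).astype(float)
    b = _as_array(density_map).astype(float)
    if a.shape != b.shape:
        raise ValueError("tract and density maps must be on the same grid")
    if slice_spacing_mm is None:
        if isinstance(density_map, DensityVolume):
            slice_spacing_mm = density_map.grid_spacing_mm
        elif isinstance(tract_map, DensityVolume):
            slice_spacing_mm = tract_map.grid_spacing_mm
        else:
            raise ValueError("slice_spacing_mm required for bare arrays")

    a_thr = np.where(a >= tract_threshold, a, 0.0)
    b_thr = np.where(b >= density_threshold, b, 0.0)
    mask_a = a_thr > 0
    mask_b = b_thr > 0

    ny = a.shape[1]
    coords = (np.arange(ny) + 0.5) * slice_spacing_mm - axis_origin_mm
    rows = []
    for y in range(ny):
        ma, mb = mask_a[:, y, :], mask_b[:, y, :]
        bm = brain_mask[:, y, :] if brain_mask is not None else None
        if not ma.any() or not mb.any():
            rows.append((coords[y], math.nan, math.nan, math.nan))
            continue
        if weighted_dice:
            sa, sb = a_thr[:, y, :], b_thr[:, y, :]
            d = 2.0 * np.minimum(sa, sb).sum() / (sa.sum() + sb.sum())
        else:
            d = dice(ma, mb)
        r = pearson_map(a_thr[:, y, :], b_thr[:, y, :], support_mode, bm)
        s = simpson_overlap(ma, mb)
        rows.append((coords[y], d, r, s))
    slices = pd.DataFrame(rows, columns=["ap_mm", "dice", "pearson", "simpson"])

    dice_m, dice_sd, n_d = _mean_sd(slices["dice"].to_numpy())
    r_m, r_sd, n_r = _mean_sd(slices["pearson"].to_numpy())
    s_m, s_sd, n_s = _mean_sd(slices["simpson"].to_numpy())
    summary = {
        "dice_3d": dice(mask_a, mask_b),
        "simpson_3d": simpson_overlap(mask_a, mask_b),
        "pearson_3d": pearson_map(a_thr, b_thr, support_mode, brain_mask),
        "dice_slice_mean": dice_m,
        "dice_slice_sd": dice_sd,
        "pearson_slice_mean": r_m,
        "pearson_slice_sd": r_sd,
        "simpson_slice_mean": s_m,
        "simpson_slice_sd": s_sd,
        "n_valid_slices": n_d,
    }
    thresholds = {
        "tract_threshold": tract_threshold,
        "density_threshold": density_threshold,
        "support_mode": support_mode,
        "weighted_dice": weighted_dice,
        "slice_spacing_mm": slice_spacing_mm,
    }
    return OverlapReport(slices=slices, summary=summary, thresholds=thresholds)
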