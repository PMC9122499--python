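"""Ground-truthed synthetic brain phantom.

Generates every input the cross-modal comparison pipeline consumes: an
integer-labeled atlas volume, smooth axon-bundle tracts with tube masks, serial
two-channel fluorescence sections (GFP-like axons plus lipofuscin-like puncta
shared across channels), and a diffusion-weighted volume whose tensor field is
coherent with the rendered bundles.

Coordinate convention (used package-wide): 0-based voxel indices, physical
coordinate of a voxel center = (index + 0.5) * spacing, axes ordered
(x = left-right, y = posterior-anterior, z = inferior-superior).  Sections are
coronal, i.e. fixed-y planes; the anterior-posterior axis is y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage

__all__ = [
    "AtlasVolume",
    "TractSpec",
    "PhantomSpec",
    "SectionStack",
    "TractSet",
    "SectionGroundTruth",
    "DWIVolume",
    "GradientScheme",
    "build_atlas",
    "build_tracts",
    "render_sections",
    "synthesize_dwi",
    "make_gradient_scheme",
    "make_overlap_phantom",
    "default_phantom_spec",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AtlasVolume:
    """Integer region labels on a voxel grid.

    ``labels`` is 0 outside the brain and 1..n_regions inside.  ``origin_mm``
    is the physical position of the grid corner (voxel (0,0,0) has its center
    at origin + 0.5*spacing).  ``ap_origin_mm`` is the ear-bar-zero analog on
    the y (anterior-posterior) axis.
    """

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ap_origin_mm: float = 0.0
    region_table: pd.DataFrame | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def label_at(self, point_mm: Sequence[float]) -> int:
        idx = tuple(int(p // self.voxel_size_mm) for p in point_mm)
        if any(i < 0 or i >= s for i, s in zip(idx, self.labels.shape)):
            return 0
        return int(self.labels[idx])


@dataclass(frozen=True)
class TractSpec:
    """One axon bundle: a smooth centerline with a tube radius.

    ``relative_density`` weights the number of individual axons drawn for the
    bundle, emulating targets of varying innervation strength.
    """

    control_points_mm: tuple[tuple[float, float, float], ...]
    tube_radius_mm: float = 1.0
    relative_density: float = 1.0
    seed_region_label: int = 1

    def __post_init__(self):
        if len(self.control_points_mm) < 2:
            raise ValueError("a tract needs at least 2 control points")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube_radius_mm must be positive")
        if self.relative_density < 0:
            raise ValueError("relative_density must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic brain.

    All stochastic output is a pure function of ``seed``.  Intensities are in
    arbitrary fluorescence units; spacings in micrometres.
    """

    grid_shape: tuple[int, int, int] = (32, 48, 32)
    voxel_size_um: float = 500.0
    n_regions: int = 5
    tract_specs: tuple[TractSpec, ...] = ()
    pixel_size_um: float = 50.0
    z_interval_um: float = 100.0
    puncta_density_per_mm3: float = 1.5
    puncta_intensity_range: tuple[float, float] = (150.0, 400.0)
    axon_intensity: float = 100.0
    soma_intensity: float = 800.0
    axons_per_tract: int = 30
    injection_radius_mm: float = 1.5
    background_level: float = 20.0
    anatomy_level: float = 60.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.voxel_size_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("spacings must be positive")
        if self.puncta_density_per_mm3 < 0:
            raise ValueError("puncta_density_per_mm3 must be non-negative")
        if self.z_interval_um < self.pixel_size_um:
            raise ValueError("section interval must be >= in-plane pixel size")
        if self.soma_intensity <= self.axon_intensity:
            raise ValueError("somata must be rendered brighter than axons")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_mm for s in self.grid_shape)


@dataclass
class SectionStack:
    """Ordered coronal two-channel fluorescence sections.

    ``green``/``red`` are (n_sections, nx_pixels, nz_pixels) float arrays;
    section k covers y in [k, k+1) * z_interval.  Pixel (i, j) covers
    x in [i, i+1) * pixel_size and z in [j, j+1) * pixel_size.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float
    z_interval_um: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.green.shape != self.red.shape:
            raise ValueError("green and red stacks must share a shape")

    @property
    def n_sections(self) -> int:
        return self.green.shape[0]


@dataclass
class TractSet:
    """Geometry of all bundles rasterised onto the coarse grid."""

    specs: tuple[TractSpec, ...]
    centerlines_mm: list[np.ndarray]
    tube_masks: list[np.ndarray]
    tangents: np.ndarray  # (X, Y, Z, 3) unit tangent inside tubes, 0 outside
    union_mask: np.ndarray

    @property
    def n_tracts(self) -> int:
        return len(self.specs)


@dataclass
class SectionGroundTruth:
    """Per-pixel truth for the rendered sections."""

    axon_mask_stack: np.ndarray      # axon strokes only
    soma_mask_stack: np.ndarray      # injection-site somata
    gfp_mask_stack: np.ndarray       # axon | soma (all GFP-positive pixels)
    puncta_centroids: np.ndarray     # (n, 3) as (section, i, j) indices
    injection_mask: np.ndarray       # coarse-grid binary volume
    injection_center_mm: np.ndarray


@dataclass
class GradientScheme:
    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3), unit norm where bval > 0

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError("bvals and bvecs length mismatch")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit vectors")

    @property
    def n_dw(self) -> int:
        return int((self.bvals > 0).sum())

    @property
    def n_b0(self) -> int:
        return int((self.bvals == 0).sum())


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its gradient table."""

    data: np.ndarray  # (X, Y, Z, n_volumes), signal >= 0
    scheme: GradientScheme
    voxel_size_mm: float

    def __post_init__(self):
        if self.data.shape[-1] != self.scheme.bvals.shape[0]:
            raise ValueError("number of volumes must match gradient table")
        if np.any(self.data < 0):
            raise ValueError("signal must be non-negative")

    @property
    def bvals(self) -> np.ndarray:
        return self.scheme.bvals

    @property
    def bvecs(self) -> np.ndarray:
        return self.scheme.bvecs


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def _region_center_fractions(n: int) -> np.ndarray:
    """n well-separated points in the unit ball (deterministic Fibonacci set)."""
    if n == 1:
        return np.zeros((1, 3))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = np.empty((n, 3))
    for k in range(n):
        zf = 1.0 - 2.0 * (k + 0.5) / n
        r = math.sqrt(max(0.0, 1.0 - zf * zf))
        th = golden * k
        pts[k] = (r * math.cos(th), r * math.sin(th), zf)
    return 0.55 * pts


def _voxel_centers_mm(shape: tuple[int, int, int], voxel_mm: float) -> tuple[np.ndarray, ...]:
    return tuple((np.arange(s) + 0.5) * voxel_mm for s in shape)


def region_centers_mm(spec: PhantomSpec) -> np.ndarray:
    """Physical centers of the atlas regions (label k at row k-1)."""
    ext = np.asarray(spec.extent_mm)
    center = ext / 2.0
    semi = 0.45 * ext
    return center + _region_center_fractions(spec.n_regions) * semi


def build_atlas(spec: PhantomSpec) -> AtlasVolume:
    """Brain ellipsoid split into ``n_regions`` nearest-center (Voronoi) blobs.

    Voronoi cells of Euclidean nearest-center assignment are convex, hence
    every label is one connected blob.  Fully deterministic.
    """
    if spec.n_regions < 2:
        raise ValueError("need at least 2 atlas regions")
    voxel_mm = spec.voxel_size_mm
    xs, ys, zs = _voxel_centers_mm(spec.grid_shape, voxel_mm)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    ext = np.asarray(spec.extent_mm)
    center = ext / 2.0
    semi = 0.45 * ext
    inside = ((X - center[0]) / semi[0]) ** 2 + ((Y - center[1]) / semi[1]) ** 2 + (
        (Z - center[2]) / semi[2]
    ) ** 2 <= 1.0
    n_brain = int(inside.sum())
    if spec.n_regions > n_brain:
        raise ValueError(
            f"n_regions={spec.n_regions} exceeds brain capacity of {n_brain} voxels"
        )
    centers = region_centers_mm(spec)
    pts = np.stack([X[inside], Y[inside], Z[inside]], axis=1)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1) + 1  # ties -> lower label
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[inside] = nearest.astype(np.int32)
    counts = np.bincount(labels.ravel(), minlength=spec.n_regions + 1)
    table = pd.DataFrame(
        {
            "label": np.arange(1, spec.n_regions + 1),
            "name": [f"region_{k}" for k in range(1, spec.n_regions + 1)],
            "n_voxels": counts[1:],
            "center_x_mm": centers[:, 0],
            "center_y_mm": centers[:, 1],
            "center_z_mm": centers[:, 2],
        }
    )
    return AtlasVolume(
        labels=labels,
        voxel_size_mm=voxel_mm,
        origin_mm=(0.0, 0.0, 0.0),
        ap_origin_mm=float(ext[1] / 2.0),
        region_table=table,
    )


# ---------------------------------------------------------------------------
# tracts
# ---------------------------------------------------------------------------

def _interp_centerline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Smooth (cubic where possible) interpolation through control points."""
    points = np.asarray(points, dtype=float)
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = float(seglen.sum())
    if total == 0:
        return points[:1].copy()
    t = np.concatenate([[0.0], np.cumsum(seglen)]) / total
    n_out = max(int(math.ceil(total / step_mm)) + 1, 2)
    u = np.linspace(0.0, 1.0, n_out)
    k = min(3, len(points) - 1)
    if k == 1:
        out = np.stack([np.interp(u, t, points[:, d]) for d in range(3)], axis=1)
    else:
        spl = interpolate.make_interp_spline(t, points, k=k)
        out = spl(u)
    return out


def _segment_distances(
    voxel_pts: np.ndarray, polyline: np.ndarray, chunk: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Exact min distance from each point to the polyline, plus the local tangent.

    Returns (dist, tangent) with tangent the unit direction of the nearest
    segment of the polyline.
    """
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    ab_len = np.linalg.norm(ab, axis=1)
    keep = ab_len > 0
    a, b, ab, ab_len = a[keep], b[keep], ab[keep], ab_len[keep]
    tang = ab / ab_len[:, None]
    n_seg = a.shape[0]
    best_d2 = np.full(voxel_pts.shape[0], np.inf)
    best_seg = np.zeros(voxel_pts.shape[0], dtype=np.int64)
    for s0 in range(0, n_seg, chunk):
        s1 = min(s0 + chunk, n_seg)
        ap = voxel_pts[:, None, :] - a[None, s0:s1, :]          # (V, c, 3)
        t = np.einsum("vcd,cd->vc", ap, ab[s0:s1]) / (ab_len[s0:s1] ** 2)
        t = np.clip(t, 0.0, 1.0)
        proj = a[None, s0:s1, :] + t[..., None] * ab[None, s0:s1, :]
        d2 = ((voxel_pts[:, None, :] - proj) ** 2).sum(axis=2)  # (V, c)
        local = np.argmin(d2, axis=1)
        local_d2 = d2[np.arange(d2.shape[0]), local]
        upd = local_d2 < best_d2
        best_d2[upd] = local_d2[upd]
        best_seg[upd] = local[upd] + s0
    return np.sqrt(best_d2), tang[best_seg]


def build_tracts(spec: PhantomSpec, atlas: AtlasVolume) -> TractSet:
    """Interpolate centerlines and rasterise their tube masks on the atlas grid.

    A coarse voxel belongs to a tube when its center lies within
    ``tube_radius_mm`` of the (densely sampled, piecewise-linear) centerline.
    The per-voxel tangent used for diffusion synthesis is that of the nearest
    centerline segment of the nearest tract.
    """
    ext = np.asarray(spec.extent_mm)
    voxel_mm = spec.voxel_size_mm
    xs, ys, zs = _voxel_centers_mm(spec.grid_shape, voxel_mm)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vox_pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    centerlines: list[np.ndarray] = []
    tube_masks: list[np.ndarray] = []
    tangents = np.zeros(spec.grid_shape + (3,), dtype=float)
    best_dist = np.full(spec.grid_shape, np.inf)

    for ts in spec.tract_specs:
        pts = np.asarray(ts.control_points_mm, dtype=float)
        if np.any(pts < 0) or np.any(pts > ext[None, :]):
            raise ValueError("tract control point lies outside the grid")
        if ts.seed_region_label not in atlas.labels:
            raise ValueError(f"seed region {ts.seed_region_label} absent from atlas")
        dense = _interp_centerline(pts, step_mm=voxel_mm / 4.0)
        if atlas.label_at(dense[0]) != ts.seed_region_label:
            raise ValueError("centerline does not start inside its seed region")
        dist, tang = _segment_distances(vox_pts, dense)
        dist = dist.reshape(spec.grid_shape)
        tang = tang.reshape(spec.grid_shape + (3,))
        mask = dist <= ts.tube_radius_mm
        inside_and_closer = mask & (dist < best_dist)
        tangents[inside_and_closer] = tang[inside_and_closer]
        best_dist = np.where(inside_and_closer, dist, best_dist)
        centerlines.append(dense)
        tube_masks.append(mask)

    union = np.zeros(spec.grid_shape, dtype=bool)
    for m in tube_masks:
        union |= m
    return TractSet(
        specs=tuple(spec.tract_specs),
        centerlines_mm=centerlines,
        tube_masks=tube_masks,
        tangents=tangents,
        union_mask=union,
    )


# ---------------------------------------------------------------------------
# fluorescence sections
# ---------------------------------------------------------------------------

def _rasterise_points(
    pts_mm: np.ndarray,
    n_sections: int,
    nx: int,
    nz: int,
    pix_mm: float,
    dy_mm: float,
) -> np.ndarray:
    """Map 3D mm points to (section, i, j) pixel indices, dropping out-of-bounds."""
    k = np.floor(pts_mm[:, 1] / dy_mm).astype(np.int64)
    i = np.floor(pts_mm[:, 0] / pix_mm).astype(np.int64)
    j = np.floor(pts_mm[:, 2] / pix_mm).astype(np.int64)
    ok = (k >= 0) & (k < n_sections) & (i >= 0) & (i < nx) & (j >= 0) & (j < nz)
    return np.stack([k[ok], i[ok], j[ok]], axis=1)


def _disk_offsets(radius_px: int) -> np.ndarray:
    r = int(radius_px)
    di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    keep = di**2 + dj**2 <= r**2
    return np.stack([di[keep], dj[keep]], axis=1)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def render_sections(
    spec: PhantomSpec,
    tracts: TractSet,
    atlas: AtlasVolume,
    rng: np.random.Generator,
) -> tuple[SectionStack, SectionGroundTruth]:
    """Render serial coronal two-channel sections with per-pixel ground truth.

    Green channel: individual axon strokes at ``axon_intensity`` jittered inside
    each tube, somata blobs (brighter than axons) in the injection site, shared
    lipofuscin-like puncta, Gaussian noise on a flat background.  Red channel:
    smooth anatomy contrast derived from the brain mask plus the *same* puncta
    locations with an independently drawn intensity, plus noise.
    """
    pix_mm = spec.pixel_size_um / 1000.0
    dy_mm = spec.z_interval_um / 1000.0
    ext = np.asarray(spec.extent_mm)
    n_sections = int(round(ext[1] / dy_mm))
    nx = int(round(ext[0] / pix_mm))
    nz = int(round(ext[2] / pix_mm))

    axon_mask = np.zeros((n_sections, nx, nz), dtype=bool)
    soma_mask = np.zeros_like(axon_mask)

    # --- axon strokes: jittered copies of each centerline -------------------
    for ts, cl in zip(tracts.specs, tracts.centerlines_mm):
        n_axons = int(round(spec.axons_per_tract * ts.relative_density))
        if n_axons == 0:
            continue
        # resample centerline at sub-pixel steps so strokes are continuous
        dense = _interp_centerline(cl, step_mm=pix_mm / 2.0)
        length = np.linalg.norm(np.diff(dense, axis=0), axis=1).sum()
        arclen = np.linspace(0.0, 1.0, dense.shape[0])
        offsets = rng.uniform(-1.0, 1.0, size=(n_axons, 3))
        offsets *= 0.7 * ts.tube_radius_mm / np.maximum(
            np.linalg.norm(offsets, axis=1, keepdims=True), 1.0
        )
        amp = min(0.5 * ts.tube_radius_mm, 0.25)
        for ax in range(n_axons):
            phase = rng.uniform(0, 2 * np.pi, size=3)
            freq = rng.uniform(0.5, 2.0, size=3) * max(length, 1.0)
            wiggle = amp * np.sin(
                arclen[:, None] * freq[None, :] + phase[None, :]
            )
            path = dense + offsets[ax][None, :] + wiggle
            idx = _rasterise_points(path, n_sections, nx, nz, pix_mm, dy_mm)
            axon_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    # --- injection site somata ----------------------------------------------
    if tracts.n_tracts > 0:
        inj_center = np.asarray(tracts.centerlines_mm[0][0], dtype=float)
    else:
        inj_center = ext / 2.0
    voxel_mm = spec.voxel_size_mm
    xs, ys, zs = _voxel_centers_mm(spec.grid_shape, voxel_mm)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    injection_mask = (
        (X - inj_center[0]) ** 2 + (Y - inj_center[1]) ** 2 + (Z - inj_center[2]) ** 2
    ) <= spec.injection_radius_mm**2

    n_somata = 150 if tracts.n_tracts > 0 else 0
    soma_disk = _disk_offsets(2)
    for _ in range(n_somata):
        u = _random_unit_vectors(rng, 1)[0]
        r = spec.injection_radius_mm * rng.uniform() ** (1.0 / 3.0)
        p = inj_center + r * u
        idx = _rasterise_points(p[None, :], n_sections, nx, nz, pix_mm, dy_mm)
        if idx.shape[0] == 0:
            continue
        k, i, j = idx[0]
        ii = np.clip(i + soma_disk[:, 0], 0, nx - 1)
        jj = np.clip(j + soma_disk[:, 1], 0, nz - 1)
        soma_mask[k, ii, jj] = True

    # --- anatomy contrast in red --------------------------------------------
    smooth_brain = ndimage.gaussian_filter(atlas.brain_mask.astype(float), sigma=2.0)
    red = np.empty((n_sections, nx, nz), dtype=np.float32)
    zoom_xy = (nx / spec.grid_shape[0], nz / spec.grid_shape[2])
    for k in range(n_sections):
        yv = min(int(k * dy_mm / voxel_mm), spec.grid_shape[1] - 1)
        sl = ndimage.zoom(smooth_brain[:, yv, :], zoom_xy, order=1, grid_mode=True,
                          mode="nearest")
        red[k] = (0.3 + 1.2 * sl) * spec.anatomy_level

    green = np.full((n_sections, nx, nz), spec.background_level, dtype=np.float32)
    green[axon_mask] = spec.axon_intensity
    green[soma_mask] = spec.soma_intensity

    # --- shared puncta --------------------------------------------------------
    brain_frac = atlas.brain_mask.mean()
    volume_mm3 = float(np.prod(ext)) * brain_frac
    n_puncta = int(rng.poisson(spec.puncta_density_per_mm3 * volume_mm3))
    brain_vox = np.argwhere(atlas.brain_mask)
    centroids = []
    lo, hi = spec.puncta_intensity_range
    for _ in range(n_puncta):
        v = brain_vox[rng.integers(len(brain_vox))]
        p = (v + rng.uniform(0, 1, size=3)) * voxel_mm
        idx = _rasterise_points(p[None, :], n_sections, nx, nz, pix_mm, dy_mm)
        if idx.shape[0] == 0:
            continue
        k, i, j = idx[0]
        disk = _disk_offsets(int(rng.integers(1, 3)))
        ii = np.clip(i + disk[:, 0], 0, nx - 1)
        jj = np.clip(j + disk[:, 1], 0, nz - 1)
        g_int = rng.uniform(lo, hi)
        r_int = rng.uniform(lo, hi)
        green[k, ii, jj] = np.maximum(green[k, ii, jj], g_int)
        red[k, ii, jj] = np.maximum(red[k, ii, jj], r_int)
        centroids.append((k, i, j))

    if spec.noise_sd > 0:
        green += rng.normal(0.0, spec.noise_sd, size=green.shape).astype(np.float32)
        red += rng.normal(0.0, spec.noise_sd, size=red.shape).astype(np.float32)
        np.clip(green, 0.0, None, out=green)
        np.clip(red, 0.0, None, out=red)

    stack = SectionStack(
        green=green,
        red=red,
        pixel_size_um=spec.pixel_size_um,
        z_interval_um=spec.z_interval_um,
    )
    truth = SectionGroundTruth(
        axon_mask_stack=axon_mask,
        soma_mask_stack=soma_mask,
        gfp_mask_stack=axon_mask | soma_mask,
        puncta_centroids=np.asarray(centroids, dtype=np.int64).reshape(-1, 3),
        injection_mask=injection_mask,
        injection_center_mm=inj_center,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# diffusion MRI
# ---------------------------------------------------------------------------

def make_gradient_scheme(n_dirs: int = 60, bval: float = 4000.0, n_b0: int = 5) -> GradientScheme:
    """Deterministic gradient table: Fibonacci-sphere directions plus b0s."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    dirs = np.empty((n_dirs, 3))
    for k in range(n_dirs):
        zf = 1.0 - 2.0 * (k + 0.5) / n_dirs
        r = math.sqrt(max(0.0, 1.0 - zf * zf))
        th = golden * k
        dirs[k] = (r * math.cos(th), r * math.sin(th), zf)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, bval)])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


#: default eigenvalues of the prolate tensor inside tubes (mm^2/s)
TUBE_EIGENVALUES = (1.5e-3, 0.3e-3, 0.3e-3)
#: isotropic diffusivity of brain tissue outside tubes (mm^2/s)
ISO_DIFFUSIVITY = 0.7e-3
#: b0 signal level inside the brain (arbitrary units)
S0_BRAIN = 1000.0


def synthesize_dwi(
    tracts: TractSet,
    atlas: AtlasVolume,
    bscheme: GradientScheme,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    tube_eigenvalues: tuple[float, float, float] = TUBE_EIGENVALUES,
    iso_diffusivity: float = ISO_DIFFUSIVITY,
    s0: float = S0_BRAIN,
) -> tuple[DWIVolume, np.ndarray]:
    """Monoexponential tensor signal S(g) = S0 exp(-b g'Dg) on the atlas grid.

    Inside tube masks D is prolate along the local tube tangent; elsewhere in
    the brain D is isotropic; outside the brain S0 = 0 (so with Rician noise
    the background is pure Rayleigh noise, as in magnitude MRI).  Returns the
    volume and the ground-truth principal direction per voxel.
    """
    if bscheme.n_dw < 6 or bscheme.n_b0 < 1:
        raise ValueError("need >= 6 diffusion directions and >= 1 b0 volume")
    if noise_sd > 0 and rng is None:
        raise ValueError("rng required when noise_sd > 0")
    shape = atlas.shape
    l1, l2, _ = tube_eigenvalues
    tang = tracts.tangents.reshape(-1, 3)
    in_tube = tracts.union_mask.ravel()
    brain = atlas.brain_mask.ravel()

    # D = l2*I + (l1-l2) t t'  inside tubes; iso*I in brain; 0 outside
    eye = np.eye(3)
    D = np.zeros((tang.shape[0], 3, 3))
    D[brain] = iso_diffusivity * eye
    tt = np.einsum("vi,vj->vij", tang[in_tube], tang[in_tube])
    D[in_tube] = l2 * eye + (l1 - l2) * tt

    g = bscheme.bvecs
    b = bscheme.bvals
    quad = np.einsum("ni,vij,nj->vn", g, D, g)  # (V, n_volumes)
    signal = np.where(brain[:, None], s0 * np.exp(-b[None, :] * quad), 0.0)

    if noise_sd > 0:
        n1 = rng.normal(0.0, noise_sd, size=signal.shape)
        n2 = rng.normal(0.0, noise_sd, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    data = signal.reshape(shape + (len(b),))
    dwi = DWIVolume(data=data, scheme=bscheme, voxel_size_mm=atlas.voxel_size_mm)
    tensor_gt = tracts.tangents.copy()
    return dwi, tensor_gt


# ---------------------------------------------------------------------------
# overlap fixtures
# ---------------------------------------------------------------------------

def make_overlap_phantom(
    f: float,
    shape: tuple[int, int, int],
    size_a: int = 100,
    size_b: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Two binary volumes with Szymkiewicz-Simpson overlap exactly ``f``.

    |A| = size_a <= |B| = size_b and |A ∩ B| = f * size_a, which must be an
    integer (otherwise the target is not exactly representable and an error is
    raised).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    if size_a > size_b:
        size_a, size_b = size_b, size_a
    n_inter = f * size_a
    if abs(n_inter - round(n_inter)) > 1e-9:
        raise ValueError(f"overlap {f} not representable with |A|={size_a}")
    n_inter = int(round(n_inter))
    total_needed = size_a + size_b - n_inter
    n_vox = int(np.prod(shape))
    if total_needed > n_vox:
        raise ValueError("shape too small for requested mask sizes")
    a = np.zeros(n_vox, dtype=bool)
    b = np.zeros(n_vox, dtype=bool)
    a[:size_a] = True
    b[size_a - n_inter : size_a - n_inter + size_b] = True
    return a.reshape(shape), b.reshape(shape)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def with_default_tracts(base: PhantomSpec) -> PhantomSpec:
    """Attach the default bundle layout to a phantom: one seed region (label 1)
    branching to up to three targets of decreasing innervation density."""
    centers = region_centers_mm(base)
    start = centers[0]
    specs = []
    densities = (3.0, 1.5, 0.5)
    targets = [t for t in (2, 3, 4) if t <= base.n_regions]
    for t_label, dens in zip(targets, densities):
        end = centers[t_label - 1]
        mid = 0.5 * (start + end)
        mid = mid + 0.15 * (np.asarray(base.extent_mm) / 2.0 - mid)  # bend inward
        specs.append(
            TractSpec(
                control_points_mm=(tuple(start), tuple(mid), tuple(end)),
                tube_radius_mm=1.0,
                relative_density=dens,
                seed_region_label=1,
            )
        )
    return replace(base, tract_specs=tuple(specs))


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Default phantom: one seed bundle branching to three targets of
    decreasing innervation density, at the package's desk-scale resolution."""
    return with_default_tracts(PhantomSpec(seed=seed))
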