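"""Diffusion tensor fitting, SNR, and probabilistic streamline tracking.

The tensor field is estimated voxel-wise by log-linear least squares; a
noise-free monoexponential signal is inverted exactly.  Tracking follows the
principal eigenvector of the locally interpolated tensor, with Monte-Carlo
direction sampling provided by either an FA-tied angular perturbation or a
residual bootstrap of the tensor fit.  Two parameter presets are provided:

* ``preset_visitation`` — seed-based visitation mapping: 5000 samples per
  seed voxel, 2000 steps per sample, 0.2 mm steps, loop check, minimum
  step-cosine (curvature threshold) 0.2;
* ``preset_bowtie`` — streamline bundle reconstruction: 0.25 mm steps, max
  45 deg between successive steps, length 10-150 mm, FA cutoff 0.1, up to
  10,000 fibers, unidirectional growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .density import DensityVolume
from .phantom import DWIVolume

__all__ = [
    "TensorField",
    "TrackingParams",
    "Streamline",
    "VisitMap",
    "fit_tensors",
    "compute_snr",
    "propagate_streamline",
    "probabilistic_map",
    "generate_streamlines",
    "filter_streamlines",
    "track_density",
    "preset_visitation",
    "preset_bowtie",
    "fa_from_eigenvalues",
]

#: Rayleigh-background correction for two-region SNR: an air region of a
#: magnitude image has SD = sigma * sqrt(2 - pi/2), so the Gaussian sigma is
#: recovered by dividing by this factor (equivalently SNR is multiplied by it).
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


# ---------------------------------------------------------------------------
# tensor field
# ---------------------------------------------------------------------------

def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from tensor eigenvalues (last axis length 3)."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = ((evals - mean) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ],
        axis=1,
    )


def _dt_to_matrices(dt: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric."""
    out = np.empty(dt.shape[:-1] + (3, 3), dtype=dt.dtype)
    out[..., 0, 0] = dt[..., 0]
    out[..., 1, 1] = dt[..., 1]
    out[..., 2, 2] = dt[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = dt[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = dt[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = dt[..., 5]
    return out


@dataclass
class TensorField:
    """Per-voxel diffusion tensor eigensystem plus the raw components.

    ``evecs[..., :, k]`` is the eigenvector of ``evals[..., k]``; eigenvalues
    are sorted descending.  ``dt`` holds the six unique tensor components for
    interpolation during tracking.  The optional bootstrap payload
    (``log_fit``, ``log_residuals``, ``design_pinv``) supports the
    residual-bootstrap direction model.
    """

    evals: np.ndarray            # (X, Y, Z, 3), descending, mm^2/s
    evecs: np.ndarray            # (X, Y, Z, 3, 3), orthonormal columns
    fa: np.ndarray               # (X, Y, Z)
    s0: np.ndarray               # (X, Y, Z)
    dt: np.ndarray               # (X, Y, Z, 6)
    mask: np.ndarray             # (X, Y, Z) bool, valid voxels
    voxel_size_mm: float
    log_fit: np.ndarray | None = None        # (X, Y, Z, M)
    log_residuals: np.ndarray | None = None  # (X, Y, Z, M)
    design_pinv: np.ndarray | None = None    # (7, M)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.fa.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size_mm

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """True where a point lies inside the grid and in a valid voxel."""
        pts = np.atleast_2d(points_mm)
        ext = self.extent_mm
        inside = np.all((pts >= 0) & (pts < ext[None, :]), axis=1)
        ok = inside.copy()
        if inside.any():
            idx = np.floor(pts[inside] / self.voxel_size_mm).astype(int)
            ok[inside] = self.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        return ok

    @classmethod
    def from_eigensystem(
        cls,
        evals: np.ndarray,
        evecs: np.ndarray,
        voxel_size_mm: float,
        mask: np.ndarray | None = None,
        s0: np.ndarray | None = None,
    ) -> "TensorField":
        """Build a field directly from a planted eigensystem (test helper)."""
        evals = np.asarray(evals, dtype=float)
        evecs = np.asarray(evecs, dtype=float)
        shape = evals.shape[:-1]
        D = np.einsum("...ik,...k,...jk->...ij", evecs, evals, evecs)
        dt = np.stack(
            [D[..., 0, 0], D[..., 1, 1], D[..., 2, 2], D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]],
            axis=-1,
        )
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        if s0 is None:
            s0 = np.ones(shape)
        return cls(
            evals=evals,
            evecs=evecs,
            fa=fa_from_eigenvalues(evals),
            s0=s0,
            dt=dt,
            mask=mask,
            voxel_size_mm=voxel_size_mm,
        )


def fit_tensors(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    store_bootstrap: bool = True,
) -> TensorField:
    """Voxel-wise log-linear least-squares diffusion tensor fit.

    ln S = ln S0 - b g'Dg is linear in (ln S0, D); with at least six distinct
    diffusion directions and one b0 the design has full rank and a noise-free
    monoexponential signal is inverted exactly.
    """
    scheme = dwi.scheme
    if scheme.n_dw < 6 or scheme.n_b0 < 1:
        raise ValueError("need >= 6 diffusion directions and >= 1 b0 volume")
    X = _design_matrix(scheme.bvals, scheme.bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient gradient design (directions not distinct)")
    pinv = np.linalg.pinv(X)

    data = np.asarray(dwi.data, dtype=float)
    shape = data.shape[:3]
    if mask is None:
        b0_mean = data[..., scheme.bvals == 0].mean(axis=-1)
        mask = b0_mean > 1e-6 * max(b0_mean.max(), 1e-30)
    mask = np.asarray(mask, dtype=bool)

    flat = data.reshape(-1, data.shape[-1])
    logy = np.log(np.clip(flat, 1e-12, None))
    beta = logy @ pinv.T  # (V, 7)
    dt = beta[:, 1:7]
    dt[~mask.ravel()] = 0.0
    D = _dt_to_matrices(dt)
    w, v = np.linalg.eigh(D)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    fa = fa_from_eigenvalues(w)
    fa[~mask.ravel()] = 0.0
    s0 = np.exp(beta[:, 0])
    s0[~mask.ravel()] = 0.0

    log_fit = log_res = None
    if store_bootstrap:
        fit = beta @ X.T
        log_fit = fit.reshape(shape + (X.shape[0],)).astype(np.float32)
        log_res = (logy - fit).reshape(shape + (X.shape[0],)).astype(np.float32)

    return TensorField(
        evals=w.reshape(shape + (3,)),
        evecs=v.reshape(shape + (3, 3)),
        fa=fa.reshape(shape),
        s0=s0.reshape(shape),
        dt=dt.reshape(shape + (6,)),
        mask=mask,
        voxel_size_mm=dwi.voxel_size_mm,
        log_fit=log_fit,
        log_residuals=log_res,
        design_pinv=pinv if store_bootstrap else None,
    )


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def compute_snr(
    dwi: DWIVolume,
    signal_mask: np.ndarray,
    noise_mask: np.ndarray,
    rayleigh_correction: bool = False,
) -> np.ndarray:
    """Two-region SNR per volume: mean(signal region) / SD(noise region).

    The signal region is tissue (e.g. deep white matter); the noise region a
    signal-free corner of the image.  With ``rayleigh_correction`` the noise
    SD is converted from the Rayleigh background of a magnitude image to the
    underlying Gaussian sigma (divide by sqrt(2 - pi/2)), i.e. the SNR is
    multiplied by that factor.  Off by default.
    """
    signal_mask = np.asarray(signal_mask, dtype=bool)
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if signal_mask.sum() < 27 or noise_mask.sum() < 27:
        raise ValueError("signal and noise regions must each contain >= 27 voxels")
    if np.logical_and(signal_mask, noise_mask).any():
        raise ValueError("signal and noise regions must be disjoint")
    data = np.asarray(dwi.data, dtype=float)
    sig = data[signal_mask].mean(axis=0)
    sd = data[noise_mask].std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("noise region has zero standard deviation")
    snr = sig / sd
    if rayleigh_correction:
        snr = snr * RAYLEIGH_SD_FACTOR
    return snr


# ---------------------------------------------------------------------------
# tracking parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackingParams:
    """Immutable streamline tracking configuration.

    Exactly one of ``curvature_threshold`` (minimum cosine between successive
    steps) or ``max_angle_deg`` should normally be set; if both are given the
    stricter (larger) minimum cosine applies.
    """

    step_mm: float = 0.2
    curvature_threshold: float | None = None
    max_angle_deg: float | None = None
    n_samples_per_seed: int = 5000
    max_steps: int = 2000
    min_length_mm: float = 0.0
    max_length_mm: float = math.inf
    fa_cutoff: float = 0.0
    loop_check: bool = False
    unidirectional: bool = False
    direction_model: str = "perturbed-principal"
    perturbation: float = 0.3
    max_fibers: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.curvature_threshold is not None and not -1.0 <= self.curvature_threshold <= 1.0:
            raise ValueError("curvature_threshold must lie in [-1, 1]")
        if self.direction_model not in (
            "deterministic",
            "perturbed-principal",
            "residual-bootstrap",
        ):
            raise ValueError(f"unknown direction_model {self.direction_model!r}")
        if self.min_length_mm > self.max_length_mm:
            raise ValueError("min_length_mm exceeds max_length_mm")

    @property
    def min_cosine(self) -> float:
        cands = []
        if self.curvature_threshold is not None:
            cands.append(self.curvature_threshold)
        if self.max_angle_deg is not None:
            cands.append(math.cos(math.radians(self.max_angle_deg)))
        return max(cands) if cands else -1.0


def preset_visitation(seed: int = 0, **overrides) -> TrackingParams:
    """Seed-region visitation mapping preset (5000 samples, 2000 x 0.2 mm
    steps, curvature threshold 0.2, loop check, bidirectional)."""
    base = TrackingParams(
        step_mm=0.2,
        curvature_threshold=0.2,
        n_samples_per_seed=5000,
        max_steps=2000,
        loop_check=True,
        unidirectional=False,
        fa_cutoff=0.0,
        direction_model="perturbed-principal",
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def preset_bowtie(seed: int = 0, **overrides) -> TrackingParams:
    """Long-association-bundle preset (0.25 mm steps, 45 deg angle limit,
    10-150 mm length, FA cutoff 0.1, up to 10,000 unidirectional fibers)."""
    base = TrackingParams(
        step_mm=0.25,
        max_angle_deg=45.0,
        n_samples_per_seed=1,
        max_steps=int(150.0 / 0.25),
        min_length_mm=10.0,
        max_length_mm=150.0,
        fa_cutoff=0.1,
        loop_check=False,
        unidirectional=True,
        direction_model="residual-bootstrap",
        max_fibers=10_000,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# streamlines
# ---------------------------------------------------------------------------

@dataclass
class Streamline:
    """Ordered polyline in mm with launch provenance."""

    points_mm: np.ndarray
    seed_voxel: tuple[int, int, int]
    sample_index: int

    @property
    def length_mm(self) -> float:
        if self.points_mm.shape[0] < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1).sum())

    def visited_voxels(self, voxel_size_mm: float, shape: tuple[int, int, int]) -> set:
        idx = np.floor(self.points_mm / voxel_size_mm).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(shape)[None, :]), axis=1)
        return set(map(tuple, idx[ok]))


@dataclass
class VisitMap:
    """Per-voxel count of Monte-Carlo samples passing through that voxel."""

    counts: np.ndarray
    n_samples: int
    voxel_size_mm: float

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("visitation counts must be non-negative")


# ---------------------------------------------------------------------------
# tracking engine
# ---------------------------------------------------------------------------

def _trilinear(values_flat: np.ndarray, shape: tuple[int, int, int], pts_vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of (V, C) voxel data at fractional voxel coords.

    ``pts_vox`` are in voxel-center units (voxel i center at coordinate i).
    Edge values are clamped.
    """
    nx, ny, nz = shape
    p = pts_vox
    i0 = np.floor(p).astype(int)
    frac = p - i0
    out = np.zeros((p.shape[0], values_flat.shape[1]), dtype=float)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ii = np.clip(i0[:, 0] + dx, 0, nx - 1)
                jj = np.clip(i0[:, 1] + dy, 0, ny - 1)
                kk = np.clip(i0[:, 2] + dz, 0, nz - 1)
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                lin = (ii * ny + jj) * nz + kk
                out += w[:, None] * values_flat[lin]
    return out


class _TrackState:
    """Eigensystem of the interpolated tensor at a set of points."""

    __slots__ = ("evals", "evecs", "fa")

    def __init__(self, evals, evecs):
        self.evals = evals
        self.evecs = evecs
        self.fa = fa_from_eigenvalues(evals)

    @property
    def e1(self):
        return self.evecs[..., :, 0]


def _eig_at(
    field: TensorField,
    points_mm: np.ndarray,
    boot_idx: np.ndarray | None = None,
) -> _TrackState:
    """Interpolated tensor eigensystem at continuous positions.

    With ``boot_idx`` (n, M) the residual-bootstrap realisation is used: the
    fitted log-signal plus resampled residuals are interpolated and the tensor
    re-fitted per point.
    """
    pts_vox = points_mm / field.voxel_size_mm - 0.5
    if boot_idx is None:
        dt = _trilinear(field.dt.reshape(-1, 6), field.shape, pts_vox)
    else:
        if field.log_fit is None:
            raise ValueError("field lacks bootstrap payload; refit with store_bootstrap")
        m = field.log_fit.shape[-1]
        fit = _trilinear(field.log_fit.reshape(-1, m), field.shape, pts_vox)
        res = _trilinear(field.log_residuals.reshape(-1, m), field.shape, pts_vox)
        y = fit + np.take_along_axis(res, boot_idx, axis=1)
        beta = y @ field.design_pinv.T
        dt = beta[:, 1:7]
    D = _dt_to_matrices(dt)
    w, v = np.linalg.eigh(D)
    return _TrackState(w[:, ::-1], v[:, :, ::-1])


def _sample_directions(
    state: _TrackState,
    params: TrackingParams,
    rngs: Sequence[np.random.Generator | None],
) -> np.ndarray:
    e1 = state.e1
    if params.direction_model == "deterministic" or (
        params.direction_model == "perturbed-principal" and params.perturbation == 0
    ):
        return e1.copy()
    if params.direction_model == "perturbed-principal":
        sigma = params.perturbation * (1.0 - np.clip(state.fa, 0.0, 1.0))
        eta = np.stack([r.standard_normal(3) for r in rngs], axis=0)
        d = e1 + sigma[:, None] * eta
        n = np.linalg.norm(d, axis=1, keepdims=True)
        bad = n[:, 0] < 1e-12
        d[bad] = e1[bad]
        n[bad] = 1.0
        return d / n
    # residual-bootstrap: the bootstrap already randomised the tensor
    return e1.copy()


def _track_batch(
    field: TensorField,
    seeds_mm: np.ndarray,
    params: TrackingParams,
    rngs: list,
    boot_indices: np.ndarray | None,
    collect_points: bool,
) -> tuple[list, list]:
    """Grow streamlines from ``seeds_mm``; bidirectional unless configured.

    Returns (list of point arrays, list of visited-voxel sets).
    """
    n = seeds_mm.shape[0]
    vox = field.voxel_size_mm
    min_cos = params.min_cosine

    all_points: list[list] = [[seeds_mm[i].copy()] for i in range(n)]
    visited: list[dict] = [dict() for _ in range(n)]
    seed_voxels = np.floor(seeds_mm / vox).astype(int)
    for i in range(n):
        visited[i][tuple(seed_voxels[i])] = 1

    passes = (1,) if params.unidirectional else (1, -1)
    for orient in passes:
        pos = seeds_mm.copy()
        alive = field.contains(pos).copy()
        state = _eig_at(field, pos, boot_indices)
        alive &= state.fa >= params.fa_cutoff
        prev = None  # no curvature constraint on the first step
        ref = orient * state.e1  # sign reference for the first step
        steps_left = params.max_steps
        lengths = np.zeros(n)
        side_points: list[list] = [[] for _ in range(n)]
        cur_state = state
        while alive.any() and steps_left > 0:
            steps_left -= 1
            ia = np.flatnonzero(alive)
            sub = _TrackState(cur_state.evals[ia], cur_state.evecs[ia])
            d = _sample_directions(sub, params, [rngs[i] for i in ia])
            base = prev[ia] if prev is not None else ref[ia]
            flip = np.einsum("ij,ij->i", d, base) < 0
            d[flip] = -d[flip]
            if prev is not None:
                cosv = np.einsum("ij,ij->i", d, prev[ia])
                stop = cosv < min_cos
            else:
                stop = np.zeros(len(ia), dtype=bool)
            new = pos[ia] + params.step_mm * d
            inside = field.contains(new)
            too_long = lengths[ia] + params.step_mm > params.max_length_mm
            ok = ~stop & inside & ~too_long
            # FA at the accepted new positions
            if ok.any():
                sub_idx = ia[ok]
                boot_sub = boot_indices[sub_idx] if boot_indices is not None else None
                new_state = _eig_at(field, new[ok], boot_sub)
                fa_ok = new_state.fa >= params.fa_cutoff
            else:
                new_state = None
                fa_ok = np.zeros(0, dtype=bool)
            # commit
            if prev is None:
                prev = np.zeros((n, 3))
            next_alive = np.zeros(n, dtype=bool)
            acc_rows = np.flatnonzero(ok)
            for row_j, j in enumerate(acc_rows):
                if not fa_ok[row_j]:
                    continue
                i = ia[j]
                p_new = new[j]
                v_new = tuple(np.floor(p_new / vox).astype(int))
                cnt = visited[i].get(v_new, 0)
                p_old_vox = tuple(np.floor(pos[i] / vox).astype(int))
                if v_new != p_old_vox:
                    cnt += 1
                    visited[i][v_new] = cnt
                    if params.loop_check and cnt > 2:
                        continue  # loop detected: terminate this streamline
                side_points[i].append(p_new)
                pos[i] = p_new
                prev[i] = d[j]
                lengths[i] += params.step_mm
                next_alive[i] = True
            alive = next_alive
            if alive.any() and new_state is not None:
                # rebuild full-size state for the survivors
                evals_full = np.zeros((n, 3))
                evecs_full = np.zeros((n, 3, 3))
                for row_j, j in enumerate(acc_rows):
                    i = ia[j]
                    if next_alive[i]:
                        evals_full[i] = new_state.evals[row_j]
                        evecs_full[i] = new_state.evecs[row_j]
                cur_state = _TrackState(evals_full, evecs_full)
        if collect_points:
            for i in range(n):
                if orient == 1:
                    all_points[i] = all_points[i] + side_points[i]
                else:
                    all_points[i] = side_points[i][::-1] + all_points[i]
    polylines = [np.asarray(p) for p in all_points] if collect_points else []
    return polylines, [set(v.keys()) for v in visited]


def _stream_rngs(params: TrackingParams, n: int, offset: int = 0):
    """Independent, scheduling-invariant substreams: one Philox jump per
    (global) streamline index."""
    root = np.random.Philox(key=params.seed)
    return [np.random.Generator(root.jumped(offset + i)) for i in range(n)]


def _boot_indices(rngs, m: int) -> np.ndarray:
    return np.stack([r.integers(0, m, size=m) for r in rngs], axis=0)


def _prepare_batch(field, seeds_mm, params, offset):
    rngs = _stream_rngs(params, seeds_mm.shape[0], offset)
    boot = None
    if params.direction_model == "residual-bootstrap":
        if field.log_residuals is None:
            raise ValueError("residual bootstrap requires a field fitted with store_bootstrap")
        boot = _boot_indices(rngs, field.log_residuals.shape[-1])
    return rngs, boot


def propagate_streamline(
    field: TensorField,
    seed_point_mm: Sequence[float],
    params: TrackingParams,
    sample_index: int = 0,
) -> Streamline:
    """Grow a single streamline from a seed point (bidirectional unless the
    parameters say otherwise).  Deterministic for a given (params.seed,
    sample_index)."""
    seed = np.asarray(seed_point_mm, dtype=float)[None, :]
    if not field.contains(seed)[0]:
        raise ValueError("seed point lies outside the field")
    rngs, boot = _prepare_batch(field, seed, params, offset=sample_index)
    polylines, _ = _track_batch(field, seed, params, rngs, boot, collect_points=True)
    voxel = tuple(np.floor(seed[0] / field.voxel_size_mm).astype(int))
    return Streamline(points_mm=polylines[0], seed_voxel=voxel, sample_index=sample_index)


def probabilistic_map(
    field: TensorField,
    seed_mask: np.ndarray,
    params: TrackingParams,
    batch_size: int = 2500,
) -> VisitMap:
    """Visitation-count map from Monte-Carlo streamline samples.

    Launches ``params.n_samples_per_seed`` samples from the center of every
    seed voxel; each voxel's count is the number of distinct samples whose
    trajectory enters it (a sample increments a voxel at most once, and every
    sample visits its own seed voxel).  Streamline substreams are indexed by
    (seed voxel, sample) in canonical row-major order, so counts do not depend
    on seed iteration order or batching.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if seed_mask.shape != field.shape:
        raise ValueError("seed mask must be on the field grid")
    vox = field.voxel_size_mm
    seed_voxels = np.argwhere(seed_mask)  # row-major canonical order
    seeds = np.repeat((seed_voxels + 0.5) * vox, params.n_samples_per_seed, axis=0)
    counts = np.zeros(field.shape, dtype=np.int64)
    shape = field.shape
    total = seeds.shape[0]
    for start in range(0, total, batch_size):
        block = seeds[start : start + batch_size]
        rngs, boot = _prepare_batch(field, block, params, offset=start)
        _, visited = _track_batch(field, block, params, rngs, boot, collect_points=False)
        for vis in visited:
            for (i, j, k) in vis:
                if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
                    counts[i, j, k] += 1
    return VisitMap(counts=counts, n_samples=total, voxel_size_mm=vox)


def generate_streamlines(
    field: TensorField,
    seed_mask: np.ndarray,
    params: TrackingParams,
) -> list[Streamline]:
    """Streamline bundle from a seed mask, honouring the length bounds and the
    ``max_fibers`` cap (accepted fibers, as in bundle reconstruction)."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    vox = field.voxel_size_mm
    seed_voxels = np.argwhere(seed_mask)
    seeds = np.repeat((seed_voxels + 0.5) * vox, params.n_samples_per_seed, axis=0)
    voxel_of = np.repeat(seed_voxels, params.n_samples_per_seed, axis=0)
    out: list[Streamline] = []
    batch = 2500
    for start in range(0, seeds.shape[0], batch):
        block = seeds[start : start + batch]
        rngs, boot = _prepare_batch(field, block, params, offset=start)
        polylines, _ = _track_batch(field, block, params, rngs, boot, collect_points=True)
        for j, pts in enumerate(polylines):
            s = Streamline(
                points_mm=pts,
                seed_voxel=tuple(voxel_of[start + j]),
                sample_index=start + j,
            )
            if params.min_length_mm <= s.length_mm <= params.max_length_mm:
                out.append(s)
                if params.max_fibers is not None and len(out) >= params.max_fibers:
                    return out
    return out


# ---------------------------------------------------------------------------
# streamline filtering and track density
# ---------------------------------------------------------------------------

def filter_streamlines(
    streamlines: Sequence[Streamline],
    inclusion_masks: Sequence[np.ndarray] = (),
    exclusion_masks: Sequence[np.ndarray] = (),
    length_bounds: tuple[float, float] = (0.0, math.inf),
    voxel_size_mm: float | None = None,
) -> list[Streamline]:
    """Keep streamlines that traverse every inclusion mask, avoid every
    exclusion mask, and fall within the length bounds."""
    masks = list(inclusion_masks) + list(exclusion_masks)
    if masks and voxel_size_mm is None:
        raise ValueError("voxel_size_mm required when masks are given")
    shape = masks[0].shape if masks else None
    for m in masks:
        if m.shape != shape:
            raise ValueError("all masks must share a grid")
    lo, hi = length_bounds
    kept = []
    for s in streamlines:
        if not lo <= s.length_mm <= hi:
            continue
        if masks:
            vis = s.visited_voxels(voxel_size_mm, shape)
            if any(not any(m[v] for v in vis) for m in inclusion_masks):
                continue
            if any(any(m[v] for v in vis) for m in exclusion_masks):
                continue
        kept.append(s)
    return kept


def track_density(
    streamlines: Sequence[Streamline],
    grid_spacing_mm: float,
    grid_shape: tuple[int, int, int],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DensityVolume:
    """Track-density image: per voxel, the number of streamlines entering it
    (each streamline counted at most once per voxel)."""
    counts = np.zeros(grid_shape, dtype=np.int64)
    origin = np.asarray(origin_mm)
    for s in streamlines:
        pts = s.points_mm - origin[None, :]
        idx = np.floor(pts / grid_spacing_mm).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid_shape)[None, :]), axis=1)
        for v in set(map(tuple, idx[ok])):
            counts[v] += 1
    return DensityVolume(
        counts=counts, grid_spacing_um=grid_spacing_mm * 1000.0, origin_mm=origin_mm
    )
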