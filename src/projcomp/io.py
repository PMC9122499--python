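"""File formats: NIfTI-1 volumes, multi-page TIFF section stacks with JSON
sidecars, FSL-style bvals/bvecs, TrackVis .trk streamlines, TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .density import DensityVolume
from .phantom import DWIVolume, GradientScheme, SectionStack
from .tractography import Streamline

__all__ = [
    "save_volume",
    "load_volume",
    "save_density",
    "load_density",
    "save_section_stack",
    "load_section_stack",
    "save_gradient_scheme",
    "load_gradient_scheme",
    "save_dwi",
    "load_dwi",
    "save_streamlines",
    "load_streamlines",
    "save_table",
]


def _affine(voxel_size_mm: float, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def save_volume(path, data: np.ndarray, voxel_size_mm: float, origin_mm=(0.0, 0.0, 0.0)):
    """Write a volume as uncompressed NIfTI-1 (affine encodes spacing+origin)."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, _affine(voxel_size_mm, origin_mm))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, float, tuple]:
    img = nib.load(str(path))
    vox = float(img.affine[0, 0])
    origin = tuple(img.affine[:3, 3])
    return np.asarray(img.dataobj), vox, origin


def save_density(path, vol: DensityVolume):
    save_volume(path, vol.counts.astype(np.float64), vol.grid_spacing_mm, vol.origin_mm)


def load_density(path) -> DensityVolume:
    data, vox, origin = load_volume(path)
    return DensityVolume(
        counts=np.asarray(data).astype(np.int64),
        grid_spacing_um=vox * 1000.0,
        origin_mm=origin,
    )


def save_section_stack(dirpath, stack: SectionStack, prefix: str = "sections"):
    """One multi-page TIFF per channel plus a JSON geometry sidecar."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        d / f"{prefix}_green.tif", stack.green.astype(np.float32), photometric="minisblack"
    )
    tifffile.imwrite(
        d / f"{prefix}_red.tif", stack.red.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "z_interval_um": stack.z_interval_um,
        "origin_mm": list(stack.origin_mm),
    }
    with open(d / f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_section_stack(dirpath, prefix: str = "sections") -> SectionStack:
    d = Path(dirpath)
    green = tifffile.imread(d / f"{prefix}_green.tif")
    red = tifffile.imread(d / f"{prefix}_red.tif")
    with open(d / f"{prefix}.json") as fh:
        meta = json.load(fh)
    return SectionStack(
        green=green,
        red=red,
        pixel_size_um=meta["pixel_size_um"],
        z_interval_um=meta["z_interval_um"],
        origin_mm=tuple(meta["origin_mm"]),
    )


def save_gradient_scheme(bvals_path, bvecs_path, scheme: GradientScheme):
    """FSL convention: one row of b-values; three rows of vector components."""
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.8f")


def load_gradient_scheme(bvals_path, bvecs_path) -> GradientScheme:
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def save_dwi(nii_path, bvals_path, bvecs_path, dwi: DWIVolume):
    save_volume(nii_path, dwi.data.astype(np.float32), dwi.voxel_size_mm)
    save_gradient_scheme(bvals_path, bvecs_path, dwi.scheme)


def load_dwi(nii_path, bvals_path, bvecs_path) -> DWIVolume:
    data, vox, _ = load_volume(nii_path)
    scheme = load_gradient_scheme(bvals_path, bvecs_path)
    return DWIVolume(data=np.asarray(data), scheme=scheme, voxel_size_mm=vox)


def save_streamlines(path, streamlines, voxel_size_mm: float, grid_shape):
    """TrackVis .trk, with the header carrying voxel size and dimensions."""
    from nibabel.streamlines import Tractogram, TrkFile

    affine = _affine(voxel_size_mm)
    tractogram = Tractogram(
        [np.asarray(s.points_mm, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "voxel_sizes": (voxel_size_mm,) * 3,
        "dimensions": tuple(int(x) for x in grid_shape),
        "voxel_to_rasmm": affine,
    }
    TrkFile(tractogram, header=header).save(str(path))


def load_streamlines(path) -> list[Streamline]:
    from nibabel.streamlines import load as trk_load

    trk = trk_load(str(path))
    return [
        Streamline(points_mm=np.asarray(pts, dtype=float), seed_voxel=(0, 0, 0), sample_index=i)
        for i, pts in enumerate(trk.tractogram.streamlines)
    ]


def save_table(path, frame, comments: dict | None = None):
    """TSV with '#'-prefixed header comments (thresholds, grid spacing...)."""
    with open(path, "w") as fh:
        for k, v in (comments or {}).items():
            fh.write(f"# {k} = {v}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")
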