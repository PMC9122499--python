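"""One-command orchestration of the full cross-modal comparison workflow.

generate phantom -> segment axons -> density maps & region statistics ->
tensor fit & probabilistic tracking -> slice-wise and 3D overlap, with a
reproducible run manifest (config hash, stage seeds, per-file checksums).
Re-running an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import io as pio
from . import __version__
from .density import (
    ap_profile,
    apply_intensity_threshold,
    cluster_z_extents,
    density_map,
    locate_injection_site,
    region_projection_table,
)
from .overlap import slice_metrics
from .phantom import (
    PhantomSpec,
    build_atlas,
    build_tracts,
    make_gradient_scheme,
    render_sections,
    synthesize_dwi,
    with_default_tracts,
)
from .segmentation import (
    classify,
    evaluate_fscore,
    sample_training_pixels,
    subtract_channels,
    train_classifier,
)
from .tractography import (
    compute_snr,
    filter_streamlines,
    fit_tensors,
    generate_streamlines,
    preset_bowtie,
    preset_visitation,
    probabilistic_map,
    track_density,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "default_config"]

log = logging.getLogger("projcomp")

#: pipeline stage order (used in error reporting and the manifest)
STAGES = ("phantom", "segmentation", "density", "tractography", "comparison")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the output directory."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully serialisable run configuration; units are explicit in key names
    (micrometres for imaging grids, millimetres for tracking)."""

    seed: int = 0
    output_dir: str = "projcomp_run"
    # phantom overrides onto PhantomSpec defaults; "zero_tracts" drops bundles
    phantom: dict = field(default_factory=dict)
    # segmentation
    segmentation_method: str = "classifier"  # or "subtraction"
    n_train_sections: int = 6
    n_test_sections: int = 4
    n_pixels_per_class: int = 2000
    subtraction_threshold: float = 50.0
    # quantification
    soma_threshold: float = 500.0
    projectome_grid_um: float = 200.0
    comparison_grid_um: float = 500.0
    projectome_density_threshold: float = 5.0
    cluster_threshold: float = 20.0
    # diffusion
    dwi_noise_sd: float = 20.0
    # tracking
    tracking_preset: str = "visitation"  # or "bowtie"
    n_samples_per_seed: int = 100
    max_steps: int = 400
    fa_cutoff: float = 0.15
    # comparison
    tract_threshold_fraction: float = 0.01
    density_threshold: float = 5.0
    pearson_support: str = "union"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def build_phantom_spec(self) -> PhantomSpec:
        overrides = dict(self.phantom)
        zero_tracts = overrides.pop("zero_tracts", False)
        if "grid_shape" in overrides:
            overrides["grid_shape"] = tuple(overrides["grid_shape"])
        if "puncta_intensity_range" in overrides:
            overrides["puncta_intensity_range"] = tuple(overrides["puncta_intensity_range"])
        base = PhantomSpec(seed=self.seed, **overrides)
        if zero_tracts:
            return base
        return with_default_tracts(base)


def default_config(output_dir: str = "projcomp_run", seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed, output_dir=output_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _derived_seed(root: int, k: int) -> int:
    return (root * 1000003 + k) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write every artifact and the run manifest.

    Returns the manifest dictionary.  Any stage failure raises
    ``PipelineError`` naming the stage; outputs of completed stages remain on
    disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    artifacts: dict[str, list[str]] = {}
    results: dict = {}

    def record(klass: str, *paths):
        artifacts.setdefault(klass, []).extend(str(Path(p).relative_to(out)) for p in paths)

    try:
        stage = "phantom"
        log.info("stage: phantom")
        spec = config.build_phantom_spec()
        atlas = build_atlas(spec)
        tracts = build_tracts(spec, atlas)
        rng = np.random.default_rng(_derived_seed(config.seed, 1))
        stack, truth = render_sections(spec, tracts, atlas, rng)
        scheme = make_gradient_scheme()
        rng_dwi = np.random.default_rng(_derived_seed(config.seed, 2))
        dwi, tensor_gt = synthesize_dwi(
            tracts, atlas, scheme, noise_sd=config.dwi_noise_sd, rng=rng_dwi
        )
        pdir = out / "phantom"
        pdir.mkdir(exist_ok=True)
        pio.save_volume(pdir / "atlas.nii", atlas.labels, atlas.voxel_size_mm)
        pio.save_volume(pdir / "injection_truth.nii", truth.injection_mask, atlas.voxel_size_mm)
        pio.save_volume(pdir / "tube_union.nii", tracts.union_mask, atlas.voxel_size_mm)
        pio.save_section_stack(pdir, stack)
        pio.save_dwi(pdir / "dwi.nii", pdir / "bvals", pdir / "bvecs", dwi)
        record(
            "phantom",
            pdir / "atlas.nii",
            pdir / "injection_truth.nii",
            pdir / "tube_union.nii",
            pdir / "sections_green.tif",
            pdir / "sections_red.tif",
            pdir / "sections.json",
            pdir / "dwi.nii",
            pdir / "bvals",
            pdir / "bvecs",
        )

        stage = "segmentation"
        log.info("stage: segmentation")
        sdir = out / "segmentation"
        sdir.mkdir(exist_ok=True)
        gfp_truth = truth.gfp_mask_stack
        n_sec = stack.n_sections
        # pick informative sections (most GFP pixels) for training, held-out test
        order = np.argsort(gfp_truth.reshape(n_sec, -1).sum(axis=1))[::-1]
        train_secs = sorted(order[: config.n_train_sections].tolist())
        test_secs = sorted(
            order[config.n_train_sections : config.n_train_sections + config.n_test_sections].tolist()
        )
        if config.segmentation_method == "classifier" and len(train_secs) > 0 and gfp_truth.any():
            rng_tr = np.random.default_rng(_derived_seed(config.seed, 3))
            feats, labels = [], []
            for k in train_secs:
                f, l = sample_training_pixels(
                    stack.green[k], stack.red[k], gfp_truth[k], config.n_pixels_per_class, rng_tr
                )
                feats.append(f)
                labels.append(l)
            clf = train_classifier(
                np.concatenate(feats), np.concatenate(labels), seed=_derived_seed(config.seed, 4)
            )
            clf.save(sdir / "classifier.joblib")
            mask_stack = np.zeros_like(gfp_truth)
            for k in range(n_sec):
                mask_stack[k] = classify(clf, stack.green[k], stack.red[k])
        else:
            mask_stack = np.zeros_like(gfp_truth)
            for k in range(n_sec):
                cleaned = subtract_channels(stack.green[k], stack.red[k])
                mask_stack[k] = cleaned >= config.subtraction_threshold
        scores = [
            evaluate_fscore(mask_stack[k], gfp_truth[k]).as_dict() for k in test_secs
        ]
        seg_summary = {
            "per_section": scores,
            "test_sections": test_secs,
            "train_sections": train_secs,
            "mean_f_score": float(np.mean([s["f_score"] for s in scores])) if scores else None,
        }
        import tifffile

        tifffile.imwrite(sdir / "axon_mask.tif", mask_stack.astype(np.uint8))
        with open(sdir / "seg_score.json", "w") as fjson:
            json.dump(seg_summary, fjson, indent=2, sort_keys=True)
        record("segmentation_mask", sdir / "axon_mask.tif")
        record("segmentation_score", sdir / "seg_score.json")
        results["segmentation"] = seg_summary

        stage = "density"
        log.info("stage: density")
        ddir = out / "density"
        ddir.mkdir(exist_ok=True)
        dens200 = density_map(
            mask_stack, spec.pixel_size_um, spec.z_interval_um, config.projectome_grid_um
        )
        dens200_thr = apply_intensity_threshold(dens200, config.projectome_density_threshold)
        dens500 = density_map(
            mask_stack, spec.pixel_size_um, spec.z_interval_um, config.comparison_grid_um
        )
        inj_site = locate_injection_site(
            stack.green,
            config.soma_threshold,
            spec.pixel_size_um,
            spec.z_interval_um,
            config.comparison_grid_um,
            axon_intensity=spec.axon_intensity,
        )
        # region table on the atlas grid (atlas voxels are the comparison grid)
        table = region_projection_table(dens500, atlas)
        profile = ap_profile(dens200, origin_mm=atlas.ap_origin_mm)
        extents = cluster_z_extents(
            dens200_thr.counts >= max(config.cluster_threshold, 1),
            dens200_thr.grid_spacing_mm,
        )
        pio.save_density(ddir / "density_200um.nii", dens200)
        pio.save_density(ddir / "density_200um_thresholded.nii", dens200_thr)
        pio.save_density(ddir / "density_500um.nii", dens500)
        pio.save_volume(ddir / "injection_site.nii", inj_site, dens500.grid_spacing_mm)
        pio.save_table(
            ddir / "region_table.tsv",
            table,
            {"grid_spacing_um": config.comparison_grid_um},
        )
        pio.save_table(
            ddir / "ap_profile.tsv",
            profile.to_frame(),
            {
                "grid_spacing_um": config.projectome_grid_um,
                "origin_mm": atlas.ap_origin_mm,
            },
        )
        with open(ddir / "cluster_extents.json", "w") as fjson:
            json.dump({"extent_mm": extents}, fjson, indent=2, sort_keys=True)
        record(
            "density_volume",
            ddir / "density_200um.nii",
            ddir / "density_200um_thresholded.nii",
            ddir / "density_500um.nii",
            ddir / "injection_site.nii",
        )
        record("region_projection_table", ddir / "region_table.tsv")
        record("ap_profile", ddir / "ap_profile.tsv")
        results["cluster_extent_mm"] = extents
        results["region_table"] = table.to_dict(orient="list")

        stage = "tractography"
        log.info("stage: tractography")
        tdir = out / "tractography"
        tdir.mkdir(exist_ok=True)
        field_ = fit_tensors(dwi)
        pio.save_volume(tdir / "fa.nii", field_.fa.astype(np.float32), field_.voxel_size_mm)
        noise_box = np.zeros(atlas.shape, dtype=bool)
        noise_box[:4, :4, :4] = True
        signal_mask = tracts.union_mask if tracts.union_mask.sum() >= 27 else atlas.brain_mask
        snr = compute_snr(dwi, signal_mask, noise_box)
        snr_summary = {
            "b0_mean": float(snr[dwi.bvals == 0].mean()),
            "dw_mean": float(snr[dwi.bvals > 0].mean()),
        }
        with open(tdir / "snr.json", "w") as fjson:
            json.dump(snr_summary, fjson, indent=2, sort_keys=True)
        results["snr"] = snr_summary

        if config.tracking_preset == "visitation":
            params = preset_visitation(
                seed=_derived_seed(config.seed, 5),
                n_samples_per_seed=config.n_samples_per_seed,
                max_steps=config.max_steps,
                fa_cutoff=config.fa_cutoff,
            )
        elif config.tracking_preset == "bowtie":
            params = preset_bowtie(
                seed=_derived_seed(config.seed, 5),
                n_samples_per_seed=config.n_samples_per_seed,
            )
        else:
            raise ValueError(f"unknown tracking preset {config.tracking_preset!r}")

        if inj_site.any():
            vm = probabilistic_map(field_, inj_site, params)
            stream_params = preset_bowtie(
                seed=_derived_seed(config.seed, 6),
                n_samples_per_seed=max(1, config.n_samples_per_seed // 10),
                min_length_mm=2.0,
                max_fibers=2000,
            )
            streams = generate_streamlines(field_, inj_site, stream_params)
        else:
            from .tractography import VisitMap

            vm = VisitMap(
                counts=np.zeros(atlas.shape, dtype=np.int64),
                n_samples=0,
                voxel_size_mm=field_.voxel_size_mm,
            )
            streams = []
        # waypoint filter: retain streamlines reaching any tube target
        inclusion = [ndimage.binary_dilation(m) for m in tracts.tube_masks[:1]]
        filtered = filter_streamlines(
            streams,
            inclusion_masks=inclusion,
            voxel_size_mm=field_.voxel_size_mm,
        ) if inclusion else list(streams)
        tdi = track_density(
            filtered, field_.voxel_size_mm, field_.shape
        )
        pio.save_volume(tdir / "visitmap.nii", vm.counts, vm.voxel_size_mm)
        pio.save_streamlines(tdir / "streamlines.trk", streams, field_.voxel_size_mm, field_.shape)
        pio.save_streamlines(
            tdir / "streamlines_filtered.trk", filtered, field_.voxel_size_mm, field_.shape
        )
        pio.save_density(tdir / "tdi.nii", tdi)
        record("visitation_map", tdir / "visitmap.nii")
        record("streamlines", tdir / "streamlines.trk", tdir / "streamlines_filtered.trk")
        record("track_density_image", tdir / "tdi.nii")
        results["n_streamlines"] = len(streams)
        results["n_streamlines_filtered"] = len(filtered)

        stage = "comparison"
        log.info("stage: comparison")
        cdir = out / "compare"
        cdir.mkdir(exist_ok=True)
        tract_threshold = max(config.tract_threshold_fraction * max(vm.n_samples, 1), 1.0)
        report = slice_metrics(
            vm.counts,
            dens500,
            tract_threshold=tract_threshold,
            density_threshold=config.density_threshold,
            axis_origin_mm=atlas.ap_origin_mm,
            slice_spacing_mm=dens500.grid_spacing_mm,
            support_mode=config.pearson_support,
            brain_mask=atlas.brain_mask,
        )
        report.to_tsv(cdir / "overlap.tsv")
        report.to_json(cdir / "overlap.json")
        _plot_profiles(cdir / "ap_profiles.png", profile, report)
        record("overlap_report", cdir / "overlap.tsv", cdir / "overlap.json")
        results["overlap_summary"] = report.summary
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        raise PipelineError(stage, exc) from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(STAGES),
        "artifact_classes": artifacts,
        "results": results,
        "checksums": {},
    }
    for paths in artifacts.values():
        for rel in paths:
            p = out / rel
            if p.suffix == ".png":
                manifest["checksums"][rel] = None
            else:
                manifest["checksums"][rel] = _sha256(p)
    with open(out / "manifest.json", "w") as fjson:
        json.dump(manifest, fjson, indent=2, sort_keys=True, default=float)
    return manifest


def _plot_profiles(path, profile, report) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    axes[0].plot(profile.coords_mm, profile.percent_of_total, color="forestgreen")
    axes[0].set_ylabel("% of total projection")
    sl = report.slices
    axes[1].plot(sl["ap_mm"], sl["dice"], label="Dice", color="steelblue")
    axes[1].plot(sl["ap_mm"], sl["pearson"], label="Pearson r", color="darkorange")
    axes[1].plot(sl["ap_mm"], sl["simpson"], label="Simpson", color="purple")
    axes[1].set_xlabel("anterior-posterior position (mm)")
    axes[1].set_ylabel("slice overlap")
    axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
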