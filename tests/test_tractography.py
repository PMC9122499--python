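"""Unit tests for tensor fitting, SNR, and the streamline tracker."""

from __future__ import annotations

import math

import numpy as np
import pytest

from projcomp import phantom as ph
from projcomp import tractography as tr

TUBE_EVALS = (1.5e-3, 0.3e-3, 0.3e-3)
FA_TUBE = math.sqrt(
    1.5
    * sum((v - sum(TUBE_EVALS) / 3) ** 2 for v in TUBE_EVALS)
    / sum(v**2 for v in TUBE_EVALS)
)


def _uniform_field(shape=(20, 10, 10), voxel=0.5, direction=(1.0, 0.0, 0.0)):
    """Planted prolate eigensystem, identical in every voxel."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    # complete to an orthonormal basis
    a = np.array([0.0, 1.0, 0.0]) if abs(d[0]) > 0.5 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(d, a)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(d, e2)
    evecs = np.zeros(shape + (3, 3))
    evecs[..., :, 0] = d
    evecs[..., :, 1] = e2
    evecs[..., :, 2] = e3
    evals = np.zeros(shape + (3,))
    evals[:] = TUBE_EVALS
    return tr.TensorField.from_eigensystem(evals, evecs, voxel)


class TestFaFromEigenvalues:
    def test_isotropic_is_zero(self):
        assert tr.fa_from_eigenvalues([0.7e-3] * 3) == pytest.approx(0.0)

    def test_prolate_reference_value(self):
        assert tr.fa_from_eigenvalues(TUBE_EVALS) == pytest.approx(0.76980035, abs=1e-7)

    def test_stick_is_one(self):
        assert tr.fa_from_eigenvalues([1.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_zero_tensor_is_zero(self):
        assert tr.fa_from_eigenvalues([0.0, 0.0, 0.0]) == 0.0


class TestFitTensors:
    def test_noise_free_round_trip(self, straight_tube):
        tracts, atlas, _ = straight_tube
        scheme = ph.make_gradient_scheme()
        dwi, gt_dirs = ph.synthesize_dwi(tracts, atlas, scheme)
        field = tr.fit_tensors(dwi)
        tube = tracts.union_mask
        np.testing.assert_allclose(
            field.evals[tube],
            np.broadcast_to(TUBE_EVALS, (tube.sum(), 3)),
            rtol=1e-8,
            atol=1e-12,
        )
        np.testing.assert_allclose(field.fa[tube], FA_TUBE, atol=1e-8)
        # principal direction matches ground truth up to sign
        dots = np.abs(np.einsum("vi,vi->v", field.evecs[tube][:, :, 0], gt_dirs[tube]))
        assert dots.min() > 1 - 1e-8
        # isotropic brain voxels
        iso = atlas.brain_mask & ~tube
        np.testing.assert_allclose(field.fa[iso], 0.0, atol=1e-7)
        np.testing.assert_allclose(field.s0[tube], 1000.0, rtol=1e-8)

    def test_too_few_directions_raises(self, straight_tube):
        tracts, atlas, _ = straight_tube
        scheme = ph.make_gradient_scheme(n_dirs=12)
        dwi, _ = ph.synthesize_dwi(tracts, atlas, scheme)
        short = ph.DWIVolume(
            data=dwi.data[..., :6],  # 5 b0s + 1 direction
            scheme=ph.GradientScheme(bvals=scheme.bvals[:6], bvecs=scheme.bvecs[:6]),
            voxel_size_mm=dwi.voxel_size_mm,
        )
        with pytest.raises(ValueError):
            tr.fit_tensors(short)

    def test_bootstrap_payload_stored(self, straight_tube):
        tracts, atlas, _ = straight_tube
        scheme = ph.make_gradient_scheme(n_dirs=12)
        dwi, _ = ph.synthesize_dwi(tracts, atlas, scheme)
        field = tr.fit_tensors(dwi, store_bootstrap=True)
        m = len(scheme.bvals)
        assert field.log_fit.shape == field.shape + (m,)
        assert field.log_residuals.shape == field.shape + (m,)
        assert field.design_pinv.shape == (7, m)
        # noise-free signal: residuals vanish in the brain
        brain = atlas.brain_mask
        assert np.abs(field.log_residuals[brain]).max() < 1e-5
        no_boot = tr.fit_tensors(dwi, store_bootstrap=False)
        assert no_boot.log_fit is None and no_boot.design_pinv is None

    def test_noisy_fit_direction_still_close(self, straight_tube):
        tracts, atlas, _ = straight_tube
        scheme = ph.make_gradient_scheme()
        rng = np.random.default_rng(5)
        dwi, gt_dirs = ph.synthesize_dwi(tracts, atlas, scheme, noise_sd=20.0, rng=rng)
        field = tr.fit_tensors(dwi)
        tube = tracts.union_mask
        dots = np.abs(np.einsum("vi,vi->v", field.evecs[tube][:, :, 0], gt_dirs[tube]))
        assert np.median(dots) > 0.99


class TestComputeSnr:
    def test_known_snr_recovered(self, straight_tube):
        tracts, atlas, _ = straight_tube
        # carve an outside-brain corner (away from the tube) for the noise ROI
        labels = atlas.labels.copy()
        labels[:6, :4, :4] = 0
        atlas = ph.AtlasVolume(
            labels=labels,
            voxel_size_mm=atlas.voxel_size_mm,
            ap_origin_mm=atlas.ap_origin_mm,
        )
        scheme = ph.make_gradient_scheme(n_dirs=12)
        rng = np.random.default_rng(7)
        noise_sd = 25.0
        dwi, _ = ph.synthesize_dwi(tracts, atlas, scheme, noise_sd=noise_sd, rng=rng)
        signal = tracts.union_mask & atlas.brain_mask
        noise = np.zeros_like(signal)
        noise[:6, :4, :4] = True  # outside-brain corner, pure Rayleigh
        snr = tr.compute_snr(dwi, signal, noise, rayleigh_correction=True)
        b0 = snr[scheme.bvals == 0]
        # b0 signal is 1000, so corrected SNR should be near 1000/25 = 40
        assert np.all(np.abs(b0 / (1000.0 / noise_sd) - 1) < 0.25)

    def test_matches_formula(self):
        rng = np.random.default_rng(0)
        data = rng.random((6, 6, 6, 4)) + 1.0
        dwi = ph.DWIVolume(
            data=data,
            scheme=ph.GradientScheme(bvals=np.zeros(4), bvecs=np.zeros((4, 3))),
            voxel_size_mm=1.0,
        )
        sig = np.zeros((6, 6, 6), dtype=bool)
        sig[:3] = True
        noi = np.zeros((6, 6, 6), dtype=bool)
        noi[3:] = True
        snr = tr.compute_snr(dwi, sig, noi)
        expected = data[sig].mean(axis=0) / data[noi].std(axis=0, ddof=1)
        np.testing.assert_allclose(snr, expected)
        corrected = tr.compute_snr(dwi, sig, noi, rayleigh_correction=True)
        np.testing.assert_allclose(corrected, expected * math.sqrt(2 - math.pi / 2))

    def test_small_or_overlapping_regions_raise(self):
        data = np.ones((4, 4, 4, 2))
        dwi = ph.DWIVolume(
            data=data,
            scheme=ph.GradientScheme(bvals=np.zeros(2), bvecs=np.zeros((2, 3))),
            voxel_size_mm=1.0,
        )
        big = np.ones((4, 4, 4), dtype=bool)
        small = np.zeros((4, 4, 4), dtype=bool)
        small[0, 0, 0] = True
        with pytest.raises(ValueError):
            tr.compute_snr(dwi, small, big)
        with pytest.raises(ValueError):
            tr.compute_snr(dwi, big, big)


class TestTrackingParams:
    def test_presets_match_documented_values(self):
        v = tr.preset_visitation(seed=3)
        assert v.step_mm == 0.2
        assert v.n_samples_per_seed == 5000
        assert v.max_steps == 2000
        assert v.min_cosine == pytest.approx(0.2)
        assert v.loop_check and not v.unidirectional
        b = tr.preset_bowtie(seed=4)
        assert b.step_mm == 0.25
        assert b.min_cosine == pytest.approx(math.cos(math.radians(45.0)))
        assert (b.min_length_mm, b.max_length_mm) == (10.0, 150.0)
        assert b.fa_cutoff == 0.1
        assert b.max_fibers == 10_000
        assert b.unidirectional
        assert b.direction_model == "residual-bootstrap"

    def test_preset_overrides(self):
        p = tr.preset_visitation(seed=1, n_samples_per_seed=10, fa_cutoff=0.15)
        assert p.n_samples_per_seed == 10 and p.fa_cutoff == 0.15
        assert p.curvature_threshold == 0.2  # untouched

    def test_validation(self):
        with pytest.raises(ValueError):
            tr.TrackingParams(step_mm=0.0)
        with pytest.raises(ValueError):
            tr.TrackingParams(curvature_threshold=1.5)
        with pytest.raises(ValueError):
            tr.TrackingParams(direction_model="bogus")
        with pytest.raises(ValueError):
            tr.TrackingParams(min_length_mm=5.0, max_length_mm=1.0)

    def test_min_cosine_takes_stricter(self):
        p = tr.TrackingParams(curvature_threshold=0.2, max_angle_deg=45.0)
        assert p.min_cosine == pytest.approx(math.cos(math.radians(45.0)))
        assert tr.TrackingParams().min_cosine == -1.0


class TestPropagateStreamline:
    def test_deterministic_unidirectional_exact_endpoint(self):
        field = _uniform_field()
        params = tr.TrackingParams(
            step_mm=0.2,
            max_steps=10,
            direction_model="deterministic",
            unidirectional=True,
        )
        s = tr.propagate_streamline(field, (1.0, 2.5, 2.5), params)
        assert s.points_mm.shape == (11, 3)
        np.testing.assert_allclose(s.points_mm[-1], [3.0, 2.5, 2.5], atol=1e-12)
        assert s.length_mm == pytest.approx(2.0)

    def test_bidirectional_spans_field(self):
        field = _uniform_field()
        params = tr.TrackingParams(
            step_mm=0.2, max_steps=2000, direction_model="deterministic"
        )
        s = tr.propagate_streamline(field, (5.0, 2.5, 2.5), params)
        # runs to both x boundaries of the 10 mm field
        assert s.points_mm[:, 0].min() < 0.3
        assert s.points_mm[:, 0].max() > 9.7
        # interior points form a straight line in y, z
        np.testing.assert_allclose(s.points_mm[:, 1], 2.5, atol=1e-9)
        np.testing.assert_allclose(s.points_mm[:, 2], 2.5, atol=1e-9)

    def test_step_cosines_respect_curvature_threshold(self):
        field = _uniform_field()
        params = tr.preset_visitation(seed=9, n_samples_per_seed=1, max_steps=200)
        s = tr.propagate_streamline(field, (5.0, 2.5, 2.5), params)
        steps = np.diff(s.points_mm, axis=0)
        norms = np.linalg.norm(steps, axis=1)
        cos = np.einsum("ij,ij->i", steps[:-1], steps[1:]) / (norms[:-1] * norms[1:])
        assert cos.min() >= params.min_cosine - 1e-9

    def test_bowtie_angle_constraint(self):
        field = _uniform_field()
        params = tr.preset_bowtie(
            seed=2, min_length_mm=0.0, max_steps=100,
            direction_model="perturbed-principal",
        )
        s = tr.propagate_streamline(field, (2.0, 2.5, 2.5), params)
        steps = np.diff(s.points_mm, axis=0)
        norms = np.linalg.norm(steps, axis=1)
        if len(steps) > 1:
            cos = np.einsum("ij,ij->i", steps[:-1], steps[1:]) / (norms[:-1] * norms[1:])
            assert cos.min() >= math.cos(math.radians(45.0)) - 1e-9

    def test_sharp_turn_terminates_streamline(self):
        """A >78.46 deg bend (cos < 0.2) stops the visitation tracker."""
        shape = (30, 12, 12)
        evecs = np.zeros(shape + (3, 3))
        # x-aligned in the first half, then bent by 85 degrees in-plane
        ang = math.radians(85.0)
        d2 = np.array([math.cos(ang), math.sin(ang), 0.0])
        for half, d in ((slice(0, 15), np.array([1.0, 0.0, 0.0])), (slice(15, 30), d2)):
            e2 = np.array([-d[1], d[0], 0.0])
            e3 = np.array([0.0, 0.0, 1.0])
            evecs[half, ..., :, 0] = d
            evecs[half, ..., :, 1] = e2
            evecs[half, ..., :, 2] = e3
        evals = np.zeros(shape + (3,))
        evals[:] = TUBE_EVALS
        field = tr.TensorField.from_eigensystem(evals, evecs, 0.5)
        # step larger than the one-voxel interpolation transition, so the
        # direction change is seen as a single sharp turn
        strict = tr.TrackingParams(
            step_mm=1.5,
            curvature_threshold=0.2,
            max_steps=50,
            direction_model="deterministic",
            unidirectional=True,
        )
        s = tr.propagate_streamline(field, (1.0, 3.0, 3.0), strict)
        # terminates near the bend rather than following the turned field
        assert s.points_mm[-1, 0] < 9.5
        assert abs(s.points_mm[-1, 1] - 3.0) < 0.3
        # without the curvature limit the tracker follows the bend
        loose = tr.TrackingParams(
            step_mm=1.5, max_steps=50, direction_model="deterministic",
            unidirectional=True,
        )
        s2 = tr.propagate_streamline(field, (1.0, 3.0, 3.0), loose)
        assert s2.points_mm[-1, 1] > 4.0

    def test_fa_cutoff_blocks_launch(self):
        field = _uniform_field()
        params = tr.TrackingParams(
            step_mm=0.2, max_steps=50, direction_model="deterministic",
            fa_cutoff=0.9, unidirectional=True,
        )
        s = tr.propagate_streamline(field, (5.0, 2.5, 2.5), params)
        assert s.points_mm.shape[0] == 1  # seed only; FA 0.77 < 0.9

    def test_seed_outside_field_raises(self):
        field = _uniform_field()
        with pytest.raises(ValueError):
            tr.propagate_streamline(field, (100.0, 0.0, 0.0), tr.TrackingParams())

    def test_reproducible_per_sample_index(self):
        field = _uniform_field()
        params = tr.preset_visitation(seed=5, max_steps=100)
        a = tr.propagate_streamline(field, (5.0, 2.5, 2.5), params, sample_index=3)
        b = tr.propagate_streamline(field, (5.0, 2.5, 2.5), params, sample_index=3)
        c = tr.propagate_streamline(field, (5.0, 2.5, 2.5), params, sample_index=4)
        np.testing.assert_array_equal(a.points_mm, b.points_mm)
        assert a.points_mm.shape != c.points_mm.shape or not np.array_equal(
            a.points_mm, c.points_mm
        )


class TestProbabilisticMap:
    def test_seed_voxel_count_equals_samples(self):
        field = _uniform_field(shape=(10, 8, 8))
        seed_mask = np.zeros(field.shape, dtype=bool)
        seed_mask[5, 4, 4] = True
        params = tr.preset_visitation(seed=1, n_samples_per_seed=50, max_steps=30)
        vm = tr.probabilistic_map(field, seed_mask, params)
        assert vm.counts[5, 4, 4] == 50
        assert vm.n_samples == 50
        assert vm.counts.max() <= 50  # one count per sample per voxel

    def test_mass_confined_to_straight_tube(self, straight_tube):
        tracts, atlas, _ = straight_tube
        scheme = ph.make_gradient_scheme()
        dwi, _ = ph.synthesize_dwi(tracts, atlas, scheme)
        field = tr.fit_tensors(dwi, store_bootstrap=False)
        seed_mask = np.zeros(field.shape, dtype=bool)
        seed_mask[20, 6, 6] = True
        params = tr.preset_visitation(seed=3, n_samples_per_seed=200, fa_cutoff=0.15)
        vm = tr.probabilistic_map(field, seed_mask, params)
        from scipy import ndimage

        dilated = ndimage.binary_dilation(tracts.union_mask, iterations=1)
        frac = vm.counts[dilated].sum() / vm.counts.sum()
        assert frac > 0.9

    def test_batch_size_invariance(self):
        field = _uniform_field(shape=(12, 8, 8))
        seed_mask = np.zeros(field.shape, dtype=bool)
        seed_mask[6, 4, 4] = True
        seed_mask[6, 4, 5] = True
        params = tr.preset_visitation(seed=2, n_samples_per_seed=20, max_steps=40)
        a = tr.probabilistic_map(field, seed_mask, params, batch_size=7)
        b = tr.probabilistic_map(field, seed_mask, params, batch_size=40)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_empty_or_mismatched_seed_mask_raises(self):
        field = _uniform_field(shape=(8, 8, 8))
        with pytest.raises(ValueError):
            tr.probabilistic_map(field, np.zeros(field.shape, dtype=bool), tr.TrackingParams())
        with pytest.raises(ValueError):
            tr.probabilistic_map(field, np.ones((4, 4, 4), dtype=bool), tr.TrackingParams())


class TestGenerateAndFilter:
    def _bundle(self):
        field = _uniform_field(shape=(40, 10, 10))
        seed_mask = np.zeros(field.shape, dtype=bool)
        seed_mask[20, 4:6, 4:6] = True
        params = tr.preset_bowtie(
            seed=1, n_samples_per_seed=5, min_length_mm=5.0,
            direction_model="perturbed-principal",
        )
        return field, tr.generate_streamlines(field, seed_mask, params), params

    def test_length_bounds_honoured(self):
        _, lines, params = self._bundle()
        assert lines
        for s in lines:
            assert params.min_length_mm <= s.length_mm <= params.max_length_mm

    def test_max_fibers_cap(self):
        field = _uniform_field(shape=(40, 10, 10))
        seed_mask = np.zeros(field.shape, dtype=bool)
        seed_mask[20, 4:6, 4:6] = True
        params = tr.preset_bowtie(
            seed=1, n_samples_per_seed=5, min_length_mm=5.0, max_fibers=3,
            direction_model="perturbed-principal",
        )
        lines = tr.generate_streamlines(field, seed_mask, params)
        assert len(lines) == 3

    def test_filter_matches_brute_force(self):
        field, lines, _ = self._bundle()
        include = np.zeros(field.shape, dtype=bool)
        include[30:35] = True
        exclude = np.zeros(field.shape, dtype=bool)
        exclude[:3] = True
        kept = tr.filter_streamlines(
            lines, [include], [exclude], length_bounds=(6.0, 100.0),
            voxel_size_mm=field.voxel_size_mm,
        )
        expected = []
        for s in lines:
            if not 6.0 <= s.length_mm <= 100.0:
                continue
            vis = s.visited_voxels(field.voxel_size_mm, field.shape)
            if not any(include[v] for v in vis):
                continue
            if any(exclude[v] for v in vis):
                continue
            expected.append(s)
        assert [id(s) for s in kept] == [id(s) for s in expected]
        assert kept  # the straight bundle does cross the inclusion slab

    def test_filter_requires_voxel_size_with_masks(self):
        _, lines, _ = self._bundle()
        with pytest.raises(ValueError):
            tr.filter_streamlines(lines, [np.ones((4, 4, 4), dtype=bool)])

    def test_track_density_counts_each_streamline_once(self):
        line = tr.Streamline(
            points_mm=np.array([[0.1, 0.1, 0.1], [0.2, 0.1, 0.1], [1.1, 0.1, 0.1]]),
            seed_voxel=(0, 0, 0),
            sample_index=0,
        )
        vol = tr.track_density([line, line], 1.0, (3, 3, 3))
        assert vol.counts[0, 0, 0] == 2  # two streamlines, each counted once
        assert vol.counts[1, 0, 0] == 2
        assert vol.total == 4

    def test_track_density_ignores_out_of_grid_points(self):
        line = tr.Streamline(
            points_mm=np.array([[-1.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
            seed_voxel=(0, 0, 0),
            sample_index=0,
        )
        vol = tr.track_density([line], 1.0, (2, 2, 2))
        assert vol.total == 1


class TestResidualBootstrap:
    def test_requires_bootstrap_payload(self, straight_tube):
        tracts, atlas, _ = straight_tube
        scheme = ph.make_gradient_scheme(n_dirs=12)
        dwi, _ = ph.synthesize_dwi(tracts, atlas, scheme)
        field = tr.fit_tensors(dwi, store_bootstrap=False)
        params = tr.preset_bowtie(seed=0, min_length_mm=0.0)
        with pytest.raises(ValueError):
            tr.propagate_streamline(field, (10.0, 3.0, 3.0), params)

    def test_noise_free_bootstrap_tracks_straight(self, straight_tube):
        """With zero residuals the bootstrap collapses to the exact tensor."""
        tracts, atlas, _ = straight_tube
        scheme = ph.make_gradient_scheme()
        dwi, _ = ph.synthesize_dwi(tracts, atlas, scheme)
        field = tr.fit_tensors(dwi, store_bootstrap=True)
        params = tr.preset_bowtie(seed=0, min_length_mm=0.0, max_steps=40)
        s = tr.propagate_streamline(field, (10.0, 3.0, 3.0), params)
        assert s.points_mm.shape[0] > 10
        np.testing.assert_allclose(s.points_mm[:, 1], 3.0, atol=1e-3)
        np.testing.assert_allclose(s.points_mm[:, 2], 3.0, atol=1e-3)
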