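"""Bead detection, profile extraction and PSF model fitting."""

import math

import numpy as np
import pytest

from clearquant.errors import EdgeBeadError, NoBeadsError
from clearquant.image_io import ImageStack3D
from clearquant.psf_fitting import (
    FWHM_FACTOR,
    ProfileVector,
    analyze_bead_stack,
    best_slice,
    detect_beads,
    extract_profile,
    fit_psf_model,
    fwhm_from_sigma,
    model_profile,
    summarize_fwhm,
)
from clearquant.synthetic_data import BeadSceneGroundTruth, generate_bead_stack


def _single_bead_stack(z=10, y=32, x=32, shape=(24, 64, 64), sigma=(2.0, 1.5, 1.5)):
    """A Gaussian spot at integer voxel coordinates, unit pitch 0.1/0.05 um."""
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    vox = 100.0 * np.exp(
        -((zz - z) ** 2) / (2 * sigma[0] ** 2)
        - ((yy - y) ** 2) / (2 * sigma[1] ** 2)
        - ((xx - x) ** 2) / (2 * sigma[2] ** 2)
    )
    return ImageStack3D(vox, (0.1, 0.05, 0.05))


class TestDetectBeads:
    def test_single_bead_centroid_within_one_voxel(self):
        dets = detect_beads(_single_bead_stack(), 0.5, 1.0)
        assert len(dets) == 1
        assert np.allclose(dets[0].centroid, (10, 32, 32), atol=1.0)

    def test_close_pair_discarded_pairwise(self):
        stack = _single_bead_stack()
        other = _single_bead_stack(z=10, y=32, x=52)  # 1 um away laterally
        merged = ImageStack3D(stack.voxels + other.voxels, stack.voxel_size_um)
        assert detect_beads(merged, 0.5, min_separation_um=5.0) == []

    def test_zero_stack_raises(self):
        with pytest.raises(NoBeadsError):
            detect_beads(ImageStack3D(np.zeros((4, 8, 8)), (1, 1, 1)), 0.5, 1.0)

    def test_generator_beads_all_found(self, clean_bead_scene):
        truth, stack, centres = clean_bead_scene
        dets = detect_beads(stack, 0.5, 2.0)
        assert len(dets) == truth.n_beads
        found = sorted(tuple(d.centroid) for d in dets)
        expected = sorted(map(tuple, centres))
        for got, want in zip(found, expected):
            assert np.allclose(got, want, atol=1.0)


class TestBestSlice:
    def test_synthetic_bead_peak_slice(self):
        stack = _single_bead_stack(z=10)
        det = detect_beads(stack, 0.5, 1.0)[0]
        assert best_slice(stack, det) == 10

    def test_tie_breaks_to_lowest_z(self):
        vox = np.zeros((4, 3, 3))
        vox[:, 1, 1] = [1.0, 3.0, 3.0, 2.0]
        stack = ImageStack3D(vox, (1, 1, 1))
        det = detect_beads(stack, 0.5, 0.5)[0]
        assert best_slice(stack, det) == 1

    def test_single_slice_stack(self):
        vox = np.zeros((1, 5, 5))
        vox[0, 2, 2] = 1.0
        stack = ImageStack3D(vox, (1, 1, 1))
        det = detect_beads(stack, 0.5, 0.5)[0]
        assert best_slice(stack, det) == 0


class TestExtractProfile:
    def test_profile_peaks_at_origin(self):
        stack = _single_bead_stack()
        det = detect_beads(stack, 0.5, 1.0)[0]
        prof = extract_profile(stack, det, "x", 0.6)
        assert prof.positions[np.argmax(prof.intensities)] == pytest.approx(0.0)

    def test_z_profile_on_single_slice_is_edge_error(self):
        vox = np.zeros((1, 9, 9))
        vox[0, 4, 4] = 1.0
        stack = ImageStack3D(vox, (0.1, 0.05, 0.05))
        det = detect_beads(stack, 0.5, 0.01)[0]
        with pytest.raises(EdgeBeadError):
            extract_profile(stack, det, "z", 0.5)

    def test_window_length_arithmetic(self):
        stack = _single_bead_stack()
        det = detect_beads(stack, 0.5, 1.0)[0]
        half = 0.45
        prof = extract_profile(stack, det, "y", half)
        assert len(prof.positions) == 2 * round(half / 0.05) + 1


class TestModelProfile:
    POS = np.linspace(-0.6, 0.6, 25)

    def test_zero_diameter_reduces_to_gaussian_exactly(self):
        got = model_profile(self.POS, 2.0, 8.0, 0.05, 0.15, 0.0, 0.0)
        expect = 2.0 + 8.0 * np.exp(-((self.POS - 0.05) ** 2) / (2 * 0.15**2))
        np.testing.assert_allclose(got, expect, rtol=0, atol=0)

    def test_peak_value_is_offset_plus_amplitude(self):
        # the convolved-shape peak sits at mu + e and reaches exactly a + b
        val = model_profile(np.array([0.0, 0.1]), 3.0, 7.0, 0.1, 0.12, 0.0, 0.2)
        assert val[1] == pytest.approx(10.0, abs=1e-9)

    def test_matches_direct_double_sum_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.uniform(0, 5), rng.uniform(1, 20)
            mu, e = rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1)
            sig, d = rng.uniform(0.05, 0.4), rng.uniform(0.01, 0.25)
            got = model_profile(self.POS, a, b, mu, sig, e, d)
            oracle = _double_sum_oracle(self.POS, a, b, mu, sig, e, d)
            np.testing.assert_allclose(got, oracle, rtol=1e-8)


def _double_sum_oracle(pos, a, b, mu, sig, e, d):
    """Brute-force midpoint convolution with explicit Python loops."""
    spacing = pos[1] - pos[0]
    step = spacing / 10
    m = max(1, round(d / step))
    mids = [e - d / 2 + step * (j + 0.5) for j in range(m)]

    def shape(x):
        return sum(math.exp(-((x - u - mu) ** 2) / (2 * sig * sig)) for u in mids) / m

    lo = min(pos.min(), mu + e) - max(d, sig)
    hi = max(pos.max(), mu + e) + max(d, sig)
    fine = list(np.arange(lo, hi + step / 2, step)) + [mu + e]
    norm = max(shape(x) for x in fine)
    return np.array([a + b * shape(x) / norm for x in pos])


class TestFitPsfModel:
    def _profile_from_model(self, theta, d, n=31, span=0.75):
        pos = np.linspace(-span, span, n)
        return ProfileVector(pos, model_profile(pos, *theta, d), "x")

    def test_self_consistency_recovers_parameters(self):
        theta = (5.0, 80.0, 0.01, 0.14, 0.01)
        fit = fit_psf_model(self._profile_from_model(theta, 0.2), 0.2)
        assert fit.converged
        assert fit.residual_rms < 1e-9
        assert fit.sigma == pytest.approx(0.14, rel=1e-4)
        assert fit.a == pytest.approx(5.0, rel=1e-4)
        assert fit.b == pytest.approx(80.0, rel=1e-4)

    def test_noise_free_sigma_within_one_percent(self):
        theta = (2.0, 50.0, 0.0, 0.15, 0.0)
        fit = fit_psf_model(self._profile_from_model(theta, 0.2), 0.2)
        assert fit.sigma == pytest.approx(0.15, rel=0.01)

    def test_constant_profile_flagged_degenerate(self):
        prof = ProfileVector(np.linspace(0, 1, 11), np.full(11, 9.0), "x")
        fit = fit_psf_model(prof, 0.2)
        assert not fit.converged

    def test_delta_limit_matches_pure_gaussian_fit(self):
        theta = (2.0, 50.0, 0.0, 0.15, 0.0)
        prof = self._profile_from_model(theta, 0.0)
        pitch = prof.spacing
        sig_tiny = fit_psf_model(prof, pitch / 10).sigma
        sig_zero = fit_psf_model(prof, 0.0).sigma
        assert abs(sig_tiny - sig_zero) / sig_zero < 0.005

    def test_tophat_correction_removes_bead_size_bias(self, clean_bead_scene):
        _, stack, _ = clean_bead_scene
        det = detect_beads(stack, 0.5, 2.0)[0]
        prof = extract_profile(stack, det, "x", 0.6)
        err_full = abs(fit_psf_model(prof, 0.2).sigma - 0.12)
        err_zero = abs(fit_psf_model(prof, 0.0).sigma - 0.12)
        assert fit_psf_model(prof, 0.0).sigma > 0.12  # uncorrected overestimates
        assert err_full < err_zero


class TestFwhm:
    def test_closed_form_and_linearity(self):
        assert fwhm_from_sigma(1.0) == pytest.approx(2 * math.sqrt(2 * math.log(2)), abs=1e-12)
        assert fwhm_from_sigma(2.0) == pytest.approx(2 * fwhm_from_sigma(1.0))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fwhm_from_sigma(0.0)

    def test_matches_dense_grid_half_max_crossing(self):
        sigma = 0.137
        grid = np.linspace(-1.0, 1.0, 20001)
        g = np.exp(-(grid**2) / (2 * sigma**2))
        above = grid[g >= 0.5]
        width = above[-1] - above[0]
        step = grid[1] - grid[0]
        assert abs(fwhm_from_sigma(sigma) - width) <= step


class TestSummarize:
    def _fit(self, sigma):
        return fit_psf_model(
            ProfileVector(
                np.linspace(-0.6, 0.6, 25),
                model_profile(np.linspace(-0.6, 0.6, 25), 1.0, 10.0, 0.0, sigma, 0.0, 0.0),
                "x",
            ),
            0.0,
        )

    def test_single_bead_sem_zero(self):
        f = self._fit(0.15)
        s = summarize_fwhm([{"x": f, "y": f, "z": f}])
        assert s.lateral_fwhm_um == pytest.approx(s.axial_fwhm_um)
        assert s.n_beads == 1 and s.sem_lateral_um == 0.0

    def test_identical_beads_sem_zero(self):
        f = self._fit(0.2)
        s = summarize_fwhm([{"x": f, "y": f, "z": f}] * 5)
        assert s.sem_lateral_um == pytest.approx(0.0, abs=1e-12)
        assert s.sem_axial_um == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(NoBeadsError):
            summarize_fwhm([])

    def test_axial_exceeds_lateral_on_anisotropic_stacks(self, noisy_bead_scene):
        _, stack, _ = noisy_bead_scene
        fits, _ = analyze_bead_stack(stack)
        s = summarize_fwhm(fits)
        assert s.axial_fwhm_um > s.lateral_fwhm_um
        assert s.lateral_fwhm_um == pytest.approx(FWHM_FACTOR * 0.12, rel=0.05)
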