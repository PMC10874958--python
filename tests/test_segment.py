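import numpy as np
import pytest

from octlayers.preprocess import denoise, enhance_retina, trim_optic_disc
from octlayers.segment import (
    ROLES,
    InsufficientCandidatesError,
    LayerSet,
    UnsegmentableScanError,
    extract_candidates,
    fit_boundary,
    replace_mislabels,
    segment_layers,
    wavelet_gram,
    wavelet_kernel,
)
from octlayers.synth import NoiseParams, render_bscan


class TestWaveletKernel:
    def test_identical_inputs_give_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            u = rng.normal(size=3)
            assert wavelet_kernel(u, u, a=0.3) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            u, v = rng.normal(size=2)
            assert wavelet_kernel([u], [v], 0.2) == pytest.approx(
                wavelet_kernel([v], [u], 0.2))

    def test_gram_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        x = rng.random(20)
        gram = wavelet_gram(x, x, a=0.1)
        assert np.linalg.eigvalsh(gram).min() >= -1e-9

    def test_invalid_dilation_rejected(self):
        with pytest.raises(ValueError):
            wavelet_kernel([0.0], [1.0], a=0.0)


class TestFitBoundary:
    def test_straight_line_recovered_within_epsilon(self):
        cols = np.arange(600)
        rows = 50 + 0.05 * cols
        curve = fit_boundary(cols, rows, (0, 600), role="IPL")
        assert np.max(np.abs(curve.depth - rows)) < 0.3

    def test_sinusoid_with_gross_outliers(self):
        rng = np.random.default_rng(7)
        cols = np.arange(600)
        truth = 80 + 5 * np.sin(2 * np.pi * cols / 64)
        rows = truth + rng.normal(0, 0.3, cols.size)
        outliers = rng.choice(cols.size, size=30, replace=False)
        rows[outliers] += rng.choice([-20, 20], size=30)
        curve = fit_boundary(cols, rows, (0, 600), role="IPL")
        curve = replace_mislabels(curve, cols, rows, threshold_px=8)
        rmse = np.sqrt(np.mean((curve.depth - truth) ** 2))
        assert rmse <= 2.0

    def test_insufficient_candidates(self):
        with pytest.raises(InsufficientCandidatesError):
            fit_boundary(np.arange(5), np.arange(5.0), (0, 100), role="EZ")

    def test_agrees_with_smoothing_spline_oracle(self):
        from scipy.interpolate import make_smoothing_spline

        rng = np.random.default_rng(9)
        cols = np.arange(600)
        truth = 90 + 6 * np.sin(2 * np.pi * cols / 80)
        rows = truth + rng.normal(0, 0.2, cols.size)
        curve = fit_boundary(cols, rows, (0, 600), role="IPL")
        spline = make_smoothing_spline(cols.astype(float), rows, lam=50.0)
        rmse = np.sqrt(np.mean((curve.depth - spline(cols.astype(float))) ** 2))
        assert rmse <= 1.0


class TestReplaceMislabels:
    def test_no_op_when_within_threshold(self):
        cols = np.arange(200)
        rows = 60.0 + 0.01 * cols
        curve = fit_boundary(cols, rows, (0, 200), role="IPL")
        out = replace_mislabels(curve, cols, rows, threshold_px=8)
        assert out is curve

    def test_single_outlier_improves_fit(self):
        rng = np.random.default_rng(3)
        cols = np.arange(200)
        truth = 60 + 3 * np.sin(2 * np.pi * cols / 64)
        rows = truth + rng.normal(0, 0.1, 200)
        rows[100] += 30
        first = fit_boundary(cols, rows, (0, 200), role="IPL")
        fixed = replace_mislabels(first, cols, rows, threshold_px=8)
        rmse_before = np.sqrt(np.mean((first.depth - truth) ** 2))
        rmse_after = np.sqrt(np.mean((fixed.depth - truth) ** 2))
        assert rmse_after < rmse_before


class TestExtractCandidates:
    def test_noise_free_candidates_match_truth(self, clean_scan):
        tr, off = clean_scan["truth"], clean_scan["offset"]
        _, mask = enhance_retina(clean_scan["denoised"])
        cand = extract_candidates(clean_scan["denoised"], mask)
        width = clean_scan["denoised"].width
        for role in ROLES:
            cols, rows, _ = cand[role]
            err = np.abs(rows - tr.curves[role][cols + off])
            assert np.mean(err <= 1.0) >= 0.99, role
            assert cols.size >= 0.95 * width, role

    def test_zeroed_columns_have_no_candidates(self, clean_scan):
        img = clean_scan["denoised"]
        px = img.pixels.copy()
        dead = slice(100, 140)
        px[:, dead] = 0.0
        from octlayers.preprocess import BScanImage

        killed = BScanImage(px, orientation=img.orientation, disc_side=img.disc_side)
        _, mask = enhance_retina(killed)
        cand = extract_candidates(killed, mask)
        for role in ROLES:
            cols, _, _ = cand[role]
            assert not np.any((cols >= 105) & (cols < 135)), role

    def test_empty_mask_rejected(self, clean_scan):
        with pytest.raises(UnsegmentableScanError):
            extract_candidates(clean_scan["denoised"],
                               np.zeros_like(clean_scan["denoised"].pixels, bool))


class TestSegmentLayers:
    def test_noise_free_rmse_below_half_pixel(self, clean_scan):
        tr, off = clean_scan["truth"], clean_scan["offset"]
        layers = segment_layers(clean_scan["denoised"])
        lo, hi = tr.domain
        for role in ROLES:
            rmse = np.sqrt(np.mean((layers[role].depth - tr.curves[role][lo:hi]) ** 2))
            assert rmse <= 0.5, role

    def test_ordering_invariant_holds(self, clean_scan):
        layers = segment_layers(clean_scan["denoised"])
        v = layers.valid
        assert v.all()
        assert np.all(layers.ipl.depth[v] < layers.opl_upper.depth[v])
        assert np.all(layers.opl_upper.depth[v] <= layers.opl_lower.depth[v])
        assert np.all(layers.opl_lower.depth[v] < layers.ez.depth[v])

    def test_deterministic_for_fixed_input(self, noisy_scan):
        a = segment_layers(noisy_scan["denoised"])
        b = segment_layers(noisy_scan["denoised"])
        for role in ROLES:
            assert np.array_equal(a[role].depth, b[role].depth)

    def test_rmse_degrades_monotonically_with_speckle(self, small_cohort):
        scan = small_cohort[2]
        tr = scan.truth
        lo, hi = tr.domain
        rmses = []
        for shape in (None, 256.0, 64.0, 16.0, 6.0):
            img = render_bscan(tr, noise=NoiseParams(speckle_shape=shape), seed=21,
                               laterality="OD", disc_side=scan.covariates["disc_side"])
            den = denoise(img)
            trimmed, _ = trim_optic_disc(den)
            layers = segment_layers(trimmed)
            rmses.append(np.mean([
                np.sqrt(np.mean((layers[r].depth - tr.curves[r][lo:hi]) ** 2))
                for r in ROLES]))
        # non-decreasing up to a small jitter allowance, and clearly increasing
        for lo_r, hi_r in zip(rmses, rmses[1:]):
            assert hi_r >= lo_r - 0.05
        assert rmses[-1] > rmses[0]

    def test_layerset_serialization_roundtrip(self, clean_scan):
        layers = segment_layers(clean_scan["denoised"])
        df = layers.to_frame(column_offset=clean_scan["offset"])
        back = LayerSet.from_frame(df, column_offset=clean_scan["offset"])
        for role in ROLES:
            assert np.allclose(back[role].depth, layers[role].depth)
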