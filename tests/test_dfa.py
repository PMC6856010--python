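import numpy as np
import pytest

from broadlrtc.dfa import (
    DFAResult,
    characterize_acf_spectrum,
    dfa_fluctuations,
    estimate_hurst,
    select_box_sizes,
    smooth_hurst_series,
    validate_mldfa,
)
from broadlrtc.preprocessing import AnalysisWindow
from broadlrtc.synth import generate_fgn, simulate_arfima

from conftest import naive_dfa


class TestBoxSizes:
    def test_standard_window(self):
        sizes = select_box_sizes(256)
        assert sizes[0] == 10
        assert sizes[-1] == 64
        assert len(sizes) == 25
        assert np.all(np.diff(sizes) > 0)

    def test_degenerate_single_size(self):
        assert list(select_box_sizes(40)) == [10]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            select_box_sizes(39)

    def test_deduplication_shortens(self):
        sizes = select_box_sizes(64)  # range [10, 16] cannot host 25 sizes
        assert len(sizes) < 25
        assert len(sizes) == len(set(sizes))


class TestFluctuations:
    def test_constant_series_degenerate(self):
        F = dfa_fluctuations(np.full(256, 3.14), select_box_sizes(256))
        assert np.all(F < 1e-10)

    def test_white_noise_slope_half(self):
        slopes = []
        for s in range(200):
            x = np.random.default_rng(s).standard_normal(256)
            sizes = select_box_sizes(256)
            F = dfa_fluctuations(x, sizes)
            slopes.append(np.polyfit(np.log2(sizes), np.log2(F), 1)[0])
        assert abs(np.mean(slopes) - 0.5) < 0.05

    def test_matches_naive_loop(self, rng):
        x = rng.standard_normal(32)
        sizes = [8, 16]
        F = dfa_fluctuations(x, np.array(sizes))
        expected = naive_dfa(x, sizes)
        np.testing.assert_allclose(F, expected, rtol=1e-10)

    def test_oracle_equivalence_many_series(self, rng):
        for _ in range(50):
            n = int(rng.integers(40, 65))
            x = rng.standard_normal(n)
            sizes = select_box_sizes(n)
            np.testing.assert_allclose(
                dfa_fluctuations(x, sizes), naive_dfa(x, sizes), rtol=1e-10
            )

    def test_monotone_for_integrated_noise(self):
        # F(n) grows with n for integrated noise; adjacent log-spaced sizes
        # are only ~8% apart so local inversions are rare but possible —
        # the check is statistical: few inversions, strong global increase
        bad_pairs = total_pairs = 0
        for s in range(20):
            x = np.random.default_rng(s).standard_normal(512)
            sizes = select_box_sizes(512)
            F = dfa_fluctuations(np.cumsum(x), sizes)
            bad_pairs += int(np.sum(np.diff(F) < 0))
            total_pairs += F.size - 1
            assert F[-1] > F[0]
        assert bad_pairs / total_pairs < 0.1


class TestHurstEstimate:
    def test_fgn_recovery(self):
        est = [
            estimate_hurst(generate_fgn(0.7, 256, seed=(5, s))).H for s in range(200)
        ]
        assert abs(np.mean(est) - 0.7) < 0.05

    def test_random_walk(self, rng):
        x = np.cumsum(rng.standard_normal(4096))
        H = estimate_hurst(x, taper=False).H
        assert H == pytest.approx(1.5, abs=0.15)

    def test_white_noise_no_lrtc(self):
        est = [
            estimate_hurst(np.random.default_rng(s).standard_normal(256))
            for s in range(100)
        ]
        mean_H = np.mean([r.H for r in est])
        assert abs(mean_H - 0.5) < 0.05
        # LRTC declared only for H in (0.5, 1): about half the noisy
        # estimates fall below 0.5, so presence is not systematic
        assert np.mean([r.lrtc_present for r in est]) < 0.7

    def test_degenerate_window(self):
        res = estimate_hurst(np.zeros(256), taper=False)
        assert res.H is None
        assert not res.valid

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_hurst(np.zeros(30))

    def test_accepts_analysis_window(self, rng):
        w = AnalysisWindow(rng.standard_normal(256), 128.0, 0.0, "C3")
        assert estimate_hurst(w).H is not None


class TestMLDFA:
    def test_exact_power_law_linear(self):
        sizes = select_box_sizes(256)
        F = sizes.astype(float) ** 0.8
        res = validate_mldfa(DFAResult(0.8, sizes, F))
        assert res.mldfa_best_model == "linear"
        assert res.valid

    def test_crossover_not_linear(self):
        sizes = select_box_sizes(256)
        x = sizes.astype(float)
        logF = np.where(x < 24, 0.5 * np.log2(x), np.log2(x) - 0.5 * np.log2(24))
        res = validate_mldfa(DFAResult(None, sizes, 2.0**logF))
        assert res.mldfa_best_model != "linear"
        assert not res.valid

    def test_pure_power_law_with_noise_mostly_linear(self):
        rng = np.random.default_rng(9)
        sizes = select_box_sizes(256)
        wins = 0
        for _ in range(100):
            H = rng.uniform(0.5, 1.0)
            F = sizes.astype(float) ** H * np.exp(rng.normal(0, 0.01, sizes.size))
            wins += validate_mldfa(DFAResult(H, sizes, F)).mldfa_best_model == "linear"
        assert wins >= 90

    def test_five_points_rejected(self):
        sizes = np.array([10, 14, 20, 28, 40])
        with pytest.raises(ValueError):
            validate_mldfa(DFAResult(0.5, sizes, sizes.astype(float) ** 0.5))


class TestSmoothing:
    def test_identity_at_lambda_one(self, rng):
        h = rng.standard_normal(20)
        np.testing.assert_allclose(smooth_hurst_series(h, 1.0), h)

    def test_constant_fixed_point(self):
        h = np.full(10, 0.7)
        np.testing.assert_allclose(smooth_hurst_series(h, 0.3), h)

    def test_step_response_closed_form(self):
        # three samples after a 0->1 step at lambda=0.5: 1-(1-0.5)^3
        h = np.r_[np.zeros(5), np.ones(10)]
        s = smooth_hurst_series(h, 0.5)
        assert s[7] == pytest.approx(1 - 0.5**3)

    def test_nan_carried_forward(self):
        h = np.array([0.6, np.nan, 0.6])
        s = smooth_hurst_series(h, 0.5)
        assert s[1] == pytest.approx(0.6)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            smooth_hurst_series(np.ones(3), 0.0)
        with pytest.raises(ValueError):
            smooth_hurst_series(np.ones(3), 1.5)


class TestSpectralCharacterization:
    def test_white_noise_flat(self, rng):
        w = AnalysisWindow(rng.standard_normal(4096), 128.0, 0.0)
        c = characterize_acf_spectrum(w, max_lag=20)
        assert c.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(c.acf[1:]) < 0.1)
        assert abs(c.beta) < 0.15
        assert not c.in_lrtc_slope_range

    def test_ar1_acf_closed_form(self):
        x = simulate_arfima(ar_coeffs=[0.9], n_samples=100_000, seed=4)
        c = characterize_acf_spectrum(AnalysisWindow(x, 128.0, 0.0), max_lag=5)
        np.testing.assert_allclose(c.acf[1:4], 0.9 ** np.arange(1, 4), atol=0.03)

    def test_arfima_spectral_slope(self):
        # beta ~ 2d for ARFIMA(0, d, 0); H = 1 - beta/2 consistency
        betas = [
            characterize_acf_spectrum(
                AnalysisWindow(simulate_arfima(d=0.3, n_samples=8192, seed=s), 128.0, 0.0),
                max_lag=20,
            ).beta
            for s in range(20)
        ]
        assert np.mean(betas) == pytest.approx(0.6, abs=0.1)
        assert 0.5 <= np.mean(betas) <= 1.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            characterize_acf_spectrum(AnalysisWindow(np.zeros(256), 128.0, 0.0), 10)
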