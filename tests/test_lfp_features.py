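"""Spectral, entropy, coupling and connectivity measures, each checked
against constructed inputs or independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ipis import lfp_features as lf
from ipis import synthetic_data as sd

FS = 1000.0


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """O(n^2) reference template counter (independent of the library path)."""
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) < r:
                a += 1
    if a == 0 or b == 0:
        return float("inf")
    return -math.log(a / b)


class TestWelch:
    def test_sine_peak_at_its_frequency(self):
        t = np.arange(0, 20, 1 / FS)
        freqs, psd = lf.welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0, abs=0.5)

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(60_000) * 2.0
        freqs, psd = lf.welch_psd(x, FS)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_short_trace_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            freqs, psd = lf.welch_psd(np.random.default_rng(0).standard_normal(500), FS)
        assert freqs.size > 0


class TestParameterizeSpectrum:
    def test_pure_power_law_recovered(self, rng):
        x = sd.powerlaw_noise(60_000, FS, 2.0, rng)
        freqs, psd = lf.welch_psd(x, FS)
        fit = lf.parameterize_spectrum(freqs, psd)
        assert fit.exponent == pytest.approx(2.0, abs=0.1)
        assert fit.peaks == ()

    def test_oscillatory_bump_detected_at_its_center(self, rng):
        t = np.arange(60_000) / FS
        x = sd.powerlaw_noise(60_000, FS, 1.0, rng) + 0.6 * np.sin(2 * np.pi * 8 * t)
        freqs, psd = lf.welch_psd(x, FS)
        fit = lf.parameterize_spectrum(freqs, psd)
        assert len(fit.peaks) >= 1
        assert fit.peaks[0][0] == pytest.approx(8.0, abs=1.0)
        assert fit.exponent == pytest.approx(1.0, abs=0.15)

    def test_white_noise_exponent_near_zero(self, rng):
        freqs, psd = lf.welch_psd(rng.standard_normal(60_000), FS)
        fit = lf.parameterize_spectrum(freqs, psd)
        assert abs(fit.exponent) < 0.1

    def test_nonpositive_psd_rejected(self):
        with pytest.raises(ValueError):
            lf.parameterize_spectrum(np.array([1.0, 10.0]), np.array([1.0, 0.0]),
                                     fit_range=(1, 10))


class TestBandPower:
    def test_flat_psd_band_fraction(self):
        freqs = np.linspace(0, 100, 1001)
        psd = np.ones_like(freqs)
        assert lf.band_power(freqs, psd, (60, 100), relative=True,
                             total_range=(0, 100)) == pytest.approx(0.4, abs=0.01)

    def test_sine_concentrates_relative_theta(self):
        t = np.arange(0, 30, 1 / FS)
        freqs, psd = lf.welch_psd(np.sin(2 * np.pi * 8 * t), FS)
        assert lf.band_power(freqs, psd, lf.THETA_BAND, relative=True) > 0.95

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            lf.band_power(np.linspace(0, 50, 100), np.ones(100), (200, 300))


class TestSampleEntropy:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_exactly(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        r = 0.2 * x.std()
        assert lf.sample_entropy(x) == pytest.approx(
            sampen_bruteforce(x, 2, r), abs=1e-12
        )

    def test_periodic_signal_near_zero(self):
        saw = np.tile(np.linspace(0, 1, 20), 10)
        assert lf.sample_entropy(saw) < 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            lf.sample_entropy(np.ones(100))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lf.sample_entropy(np.array([1.0, 2.0, 3.0]))

    def test_nonnegative_on_random_inputs(self):
        for seed in range(5):
            x = np.random.default_rng(100 + seed).standard_normal(150)
            assert lf.sample_entropy(x) >= 0.0


class TestSlidingFeatures:
    def test_i_windows_separate_from_e_windows(self, healthy_recording):
        from ipis import ei_decoder as ed

        feats = lf.sliding_features(healthy_recording.lfp, healthy_recording.fs)
        labeled = ed.label_windows(feats, healthy_recording.truth_states)
        gi = labeled[labeled.label == "I"]
        ge = labeled[labeled.label == "E"]
        for col, direction in (("slope", 1), ("sampen", -1)):
            d = direction * (gi[col].mean() - ge[col].mean())
            pooled = np.sqrt(0.5 * (gi[col].var() + ge[col].var()))
            assert d / pooled >= 1.0  # at least 1 SD separation
        # delta waves cover I windows, essentially never E windows
        assert gi["delta_covered"].mean() > 0.6
        assert gi["delta_covered"].mean() > 10 * max(ge["delta_covered"].mean(), 0.01)

    def test_windows_far_from_delta_waves_flagged_candidate_e(self, healthy_recording):
        feats = lf.sliding_features(healthy_recording.lfp, healthy_recording.fs)
        flagged = feats[feats.candidate_e]
        assert not flagged["delta_covered"].any()

    def test_stationary_noise_has_no_feature_trend(self, rng):
        feats = lf.sliding_features(rng.standard_normal(30_000), FS)
        for col in ("slope", "sampen"):
            rho, p = sps.spearmanr(feats["t_center_s"], feats[col])
            assert p > 0.05 or abs(rho) < 0.1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            lf.sliding_features(np.zeros(1000), 200.0)


class TestWpli:
    def test_independent_noise_near_zero(self, rng):
        x = rng.standard_normal(60_000)
        y = rng.standard_normal(60_000)
        assert lf.wpli(x, y, FS, (8, 12)) < 0.1

    def test_quarter_cycle_lagged_oscillation_high(self, rng):
        t = np.arange(60_000) / FS
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * rng.standard_normal(t.size)
        y = np.sin(2 * np.pi * 10 * t - np.pi / 2) + 0.5 * rng.standard_normal(t.size)
        assert lf.wpli(x, y, FS, (8, 12)) >= 0.8

    def test_zero_lag_signals_invisible(self, rng):
        t = np.arange(60_000) / FS
        s = np.sin(2 * np.pi * 10 * t)
        x = s + 0.1 * rng.standard_normal(t.size)
        y = s + 0.1 * rng.standard_normal(t.size)
        assert lf.wpli(x, y, FS, (8, 12)) < 0.2

    def test_symmetry(self, rng):
        x = rng.standard_normal(20_000)
        y = rng.standard_normal(20_000)
        assert lf.wpli(x, y, FS, (8, 12)) == pytest.approx(lf.wpli(y, x, FS, (8, 12)))


class TestPac:
    def test_mi_matches_direct_kl_summation(self):
        # the MI of the binned distribution equals brute-force KL / ln(n)
        states = sd.simulate_state_sequence(20.0, seed=0)
        lfp = sd.simulate_lfp(states, sd.LfpSpec(), seed=1)
        res = lf.pac(lfp["BNST"], lfp["NAc"], FS)
        p = res.amp_dist
        kl = sum(pi * math.log(pi * p.size) for pi in p if pi > 0)
        assert res.mi == pytest.approx(kl / math.log(p.size), abs=1e-12)
        assert res.amp_dist.sum() == pytest.approx(1.0)

    def test_uncoupled_surrogates_below_permutation_null(self, rng):
        x = sd.powerlaw_noise(20_000, FS, 1.0, rng)
        y = sd.powerlaw_noise(20_000, FS, 1.0, rng)
        mi, p = lf.pac_permutation_p(x, y, FS, n_perm=200, seed=0)
        assert mi < 0.01
        assert p > 0.05

    def test_preferred_phase_recovered(self):
        states = sd.simulate_state_sequence(30.0, seed=2)
        lfp = sd.simulate_lfp(states, sd.LfpSpec(pac_strength=0.8), seed=3)
        res = lf.pac(lfp["BNST"], lfp["NAc"], FS)
        assert abs(res.preferred_phase_deg - 330.0) <= 20.0

    def test_mi_monotone_in_coupling_strength(self):
        states = sd.simulate_state_sequence(30.0, seed=4)
        mis = []
        for k in (0.0, 0.3, 0.6, 0.9):
            lfp = sd.simulate_lfp(states, sd.LfpSpec(pac_strength=k), seed=5)
            mis.append(lf.pac(lfp["BNST"], lfp["NAc"], FS).mi)
        assert all(a < b for a, b in zip(mis, mis[1:]))


class TestSpectralGranger:
    @pytest.fixture(scope="class")
    def var_pair(self):
        rng = np.random.default_rng(3)
        n = 20_000
        x = np.zeros(n)
        y = np.zeros(n)
        ex, ey = rng.standard_normal(n), rng.standard_normal(n)
        for i in range(2, n):
            x[i] = 0.55 * x[i - 1] - 0.8 * x[i - 2] + ex[i]
            y[i] = 0.5 * y[i - 1] - 0.7 * y[i - 2] + 0.6 * x[i - 1] + ey[i]
        return x, y

    def test_unidirectional_drive_detected(self, var_pair):
        x, y = var_pair
        res = lf.spectral_granger(x, y, fs=200.0, max_order=10)
        assert res.gc_xy.mean() > 0.2
        assert res.gc_yx.mean() < 0.02
        # driven band: x resonates near 0.55/0.8 AR poles
        assert res.gc_xy.max() > res.gc_xy.mean()

    def test_independent_ar_pair_near_zero(self):
        rng = np.random.default_rng(9)
        n = 10_000
        a = np.zeros(n)
        b = np.zeros(n)
        ea, eb = rng.standard_normal(n), rng.standard_normal(n)
        for i in range(2, n):
            a[i] = 0.5 * a[i - 1] - 0.3 * a[i - 2] + ea[i]
            b[i] = 0.4 * b[i - 1] - 0.2 * b[i - 2] + eb[i]
        res = lf.spectral_granger(a, b, fs=200.0, max_order=10)
        assert res.gc_xy.mean() < 0.01 and res.gc_yx.mean() < 0.01

    def test_asymmetry(self, var_pair):
        x, y = var_pair
        res = lf.spectral_granger(x, y, fs=200.0, max_order=10)
        assert res.gc_xy.mean() > 10 * res.gc_yx.mean()


class TestLfpSnrRatio:
    def test_white_noise_matches_bandwidth_ratio(self, rng):
        r = lf.lfp_snr_ratio(rng.standard_normal(200_000), FS)
        assert r == pytest.approx(99.0 / 159.0, rel=0.05)

    def test_band_limited_signal_near_one(self, rng):
        t = np.arange(60_000) / FS
        x = np.sin(2 * np.pi * 10 * t) + 0.01 * rng.standard_normal(t.size)
        assert lf.lfp_snr_ratio(x, FS) > 0.95

    def test_stimulation_artifact_tone_lowers_ratio(self, rng):
        t = np.arange(60_000) / FS
        base = rng.standard_normal(t.size)
        clean = lf.lfp_snr_ratio(base, FS)
        tainted = lf.lfp_snr_ratio(base + 2.0 * np.sin(2 * np.pi * 160 * t), FS)
        assert tainted < clean

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            lf.lfp_snr_ratio(np.zeros(10_000), FS)


class TestComplexityWindows:
    def test_gaussian_stationary_incidences_near_two_percent(self, rng):
        cw = lf.complexity_windows(rng.standard_normal(120 * 500), 500.0)
        # mean +- 2 SD tails of a roughly normal SampEn distribution
        for inc in (cw.low_incidence, cw.high_incidence):
            assert 0.0 <= inc <= 0.08

    def test_injected_sine_seconds_labeled_low(self, rng):
        fs = 500.0
        trace = rng.standard_normal(int(60 * fs))
        t = np.arange(int(fs)) / fs
        for sec in (10, 30, 50):
            trace[int(sec * fs) : int((sec + 1) * fs)] = np.sin(2 * np.pi * 8 * t)
        cw = lf.complexity_windows(trace, fs)
        assert all(cw.labels[s] == "low" for s in (10, 30, 50))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            lf.complexity_windows(np.random.default_rng(0).standard_normal(5000), 500.0)


class TestPeriEntropyHistogram:
    def test_single_event_single_row(self):
        t = np.arange(0, 20, 0.25)
        M, rel, order, dropped = lf.peri_entropy_histogram(
            t, np.sin(t), [10.0], t, np.cos(t)
        )
        assert M.shape[0] == 1 and order.tolist() == [0] and dropped == 0

    def test_rows_sorted_by_wpli_peak_time(self):
        t = np.arange(0, 60, 0.25)
        events = [10.0, 20.0, 30.0]
        wp = np.zeros_like(t)
        for ev, pk in zip(events, [1.0, -1.0, 0.0]):
            wp += np.exp(-((t - (ev + pk)) ** 2) / 0.05)
        M, rel, order, dropped = lf.peri_entropy_histogram(
            t, np.sin(t), events, t, wp
        )
        assert order.tolist() == [1, 2, 0]

    def test_edge_events_dropped_and_counted(self):
        t = np.arange(0, 20, 0.25)
        M, rel, order, dropped = lf.peri_entropy_histogram(
            t, np.sin(t), [0.5, 10.0, 19.5], t, np.cos(t)
        )
        assert dropped == 2 and M.shape[0] == 1

    def test_i_state_events_show_entropy_trough(self, healthy_recording):
        rec = healthy_recording
        feats = lf.sliding_features(rec.lfp, rec.fs)
        ent_t = feats["t_center_s"].to_numpy()
        ent = feats["sampen"].to_numpy()
        wt, wv = lf.wpli_series(rec.lfp["BNST"], rec.lfp["NAc"], rec.fs,
                                lf.GAMMA_BAND)
        onsets = [s for s, e in rec.truth_states.of_label("I")]
        M, rel, order, dropped = lf.peri_entropy_histogram(ent_t, ent, onsets, wt, wv)
        mean_trace = M.mean(axis=0)
        center = mean_trace[np.abs(rel - 0.1) <= 0.1].mean()
        flanks = mean_trace[np.abs(rel) >= 1.5].mean()
        assert center < flanks
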