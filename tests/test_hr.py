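"""Heart-rate pipeline: filtering, envelope, autocorrelation, estimates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedvitals import ChannelModel, SynthesisConfig, apply_channel, synthesize, zscore
from bedvitals.channel import noise_sd_for_snr
from bedvitals.hr import (
    acf,
    bandpass,
    dominant_periodicity,
    estimate_hr,
    estimate_hr_series,
    hilbert_envelope,
    smooth_envelope,
)

FS = 100.0


def brute_force_acf(x, max_lag):
    """Direct double-loop evaluation of the lag-k autocorrelation."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xb = x.mean()
    denom = sum((xi - xb) ** 2 for xi in x)
    out = []
    for k in range(max_lag + 1):
        num = sum((x[i] - xb) * (x[i + k] - xb) for i in range(n - k))
        out.append(num / denom)
    return np.array(out)


class TestZscore:
    def test_standardizes_mean_and_sd(self):
        z = zscore(np.array([1.0, 2.0, 3.0]))
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0)

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(size=500)
        z = zscore(x)
        assert np.allclose(zscore(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.array([5.0, 5.0, 5.0]))


class TestBandpass:
    def test_passband_tone_preserved(self):
        # long record and interior window: the 0.1 Hz corner's
        # transient extends several seconds from each edge
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass(x, FS)
        interior = slice(2000, 4000)
        rms_ratio = np.sqrt((y[interior] ** 2).mean() / (x[interior] ** 2).mean())
        assert rms_ratio == pytest.approx(1.0, rel=0.05)

    def test_dc_rejected(self):
        t = np.arange(3000) / FS
        x = 10.0 + np.sin(2 * np.pi * 2.0 * t)
        y = bandpass(x, FS)
        assert abs(y.mean()) < 0.01

    def test_stopband_tone_crushed(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 45.0 * t)
        y = bandpass(x, FS)
        interior = slice(2000, 4000)
        assert np.sqrt((y[interior] ** 2).mean()) < 0.1 * np.sqrt((x[interior] ** 2).mean())

    def test_high_edge_must_be_below_nyquist(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, high=50.0)


class TestHilbertEnvelope:
    @pytest.mark.parametrize("method", ["fft", "fir"])
    def test_pure_tone_envelope_is_amplitude(self, method):
        t = np.arange(2000) / FS
        x = 2.5 * np.sin(2 * np.pi * 5 * t)
        env = hilbert_envelope(x, method=method)
        assert np.allclose(env[200:-200], 2.5, rtol=0.02)

    def test_zero_signal_zero_envelope(self):
        assert not np.any(hilbert_envelope(np.zeros(100)))

    def test_am_tone_modulation_recovered(self):
        t = np.arange(5000) / FS
        mod = 1 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        env = hilbert_envelope(mod * np.sin(2 * np.pi * 5 * t))
        interior = slice(500, 4500)
        rms_err = np.sqrt(np.mean((env[interior] - mod[interior]) ** 2))
        assert rms_err < 0.05 * np.sqrt(np.mean(mod[interior] ** 2))

    def test_envelope_dominates_signal(self, rng):
        x = bandpass(rng.normal(size=2000), FS)
        env = hilbert_envelope(x)
        assert np.all(env[100:-100] >= np.abs(x[100:-100]) - 1e-9)


class TestSmoothEnvelope:
    def test_constant_preserved(self):
        out = smooth_envelope(np.full(500, 3.7))
        assert np.allclose(out, 3.7)

    def test_impulse_spread_over_double_window(self):
        x = np.zeros(200)
        x[100] = 1.0
        # the two-stage moving average alone spreads an impulse over
        # at least 19 samples (double boxcar support)
        from scipy.ndimage import uniform_filter1d

        sm = uniform_filter1d(uniform_filter1d(x, 10, mode="nearest"), 10, mode="nearest")
        assert np.count_nonzero(sm) >= 19
        assert smooth_envelope(x).size == x.size

    def test_cubic_passes_polynomial_stage(self):
        t = np.linspace(-1, 1, 300)
        cubic = 2 * t**3 - t + 0.5
        # ma_window=1 disables the averaging stage, isolating the
        # degree-3 local fit, which reproduces cubics exactly
        out = smooth_envelope(cubic, ma_window=1)
        assert np.allclose(out, cubic, atol=1e-9)


class TestACF:
    def test_lag_zero_is_one(self, rng):
        rho = acf(rng.normal(size=200), 50)
        assert rho[0] == pytest.approx(1.0)
        assert np.all(np.abs(rho) <= 1.0 + 1e-12)

    def test_periodic_signal_peaks_at_period(self):
        # away from the trivially high near-zero lags, the period lag
        # carries the maximum
        t = np.arange(1000) / FS
        rho = acf(np.sin(2 * np.pi * t / 0.5), 200)
        assert np.argmax(rho[25:76]) + 25 == 50
        assert rho[50] > rho[30] and rho[50] > rho[70]

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            acf(np.ones(50), 10)

    @given(
        st.lists(st.floats(-100, 100), min_size=8, max_size=64).filter(
            lambda v: max(v) - min(v) > 1e-6
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, values):
        x = np.array(values)
        max_lag = min(20, x.size - 1)
        assert np.allclose(acf(x, max_lag), brute_force_acf(x, max_lag), atol=1e-12)


class TestDominantPeriodicity:
    def test_clean_120_bpm_envelope(self):
        sig = synthesize(SynthesisConfig(hr_bpm=120, rr_bpm=15, duration_s=10))
        est = estimate_hr(sig)
        assert est.dominant_lag_samples == 50
        assert est.hr_bpm == pytest.approx(120.0)

    def test_white_noise_scores_below_periodic(self, rng):
        noise_rho = acf(rng.normal(size=1000), 160)
        _, noise_peak, _ = dominant_periodicity(noise_rho, FS)
        sig = synthesize(SynthesisConfig(hr_bpm=90, rr_bpm=15, duration_s=10))
        periodic_peak = estimate_hr(sig).acf_peak_value
        assert noise_peak < 0.5 * periodic_peak

    def test_sub_band_rate_flagged_invalid(self):
        # a 30 bpm (0.5 Hz) oscillation: with the sweep widened to
        # reach its lag, the frequency falls below the 0.6 Hz validity
        # threshold and the estimate is rejected
        t = np.arange(1500) / FS
        rho = acf(np.sin(2 * np.pi * 0.5 * t), 300)
        m, peak, valid = dominant_periodicity(rho, FS, sweep_bpm=(25.0, 240.0))
        assert m == 200
        assert not valid

    def test_requires_full_lag_coverage(self):
        with pytest.raises(ValueError):
            dominant_periodicity(np.ones(100), FS)


class TestEstimateHR:
    def test_formula_links_rate_and_lag(self):
        sig = synthesize(SynthesisConfig(hr_bpm=75, rr_bpm=12, duration_s=10))
        est = estimate_hr(sig)
        assert est.valid
        assert est.hr_bpm == pytest.approx(60 * FS / est.dominant_lag_samples)

    @pytest.mark.parametrize("hr", [60, 240])
    def test_noiseless_recovery(self, hr):
        sig = synthesize(SynthesisConfig(hr_bpm=hr, rr_bpm=12, duration_s=10))
        est = estimate_hr(sig)
        assert est.valid
        assert est.hr_bpm == pytest.approx(hr, abs=2.0)

    def test_respiration_invariance(self):
        """The 0.95-1 amplitude modulation moves the dominant lag by at
        most one sample relative to the unmodulated rhythm."""
        for hr in (60, 110, 180):
            base = SynthesisConfig(hr_bpm=hr, rr_bpm=15, duration_s=10, sawtooth_min=1.0)
            mod = SynthesisConfig(hr_bpm=hr, rr_bpm=15, duration_s=10, sawtooth_min=0.95)
            m0 = estimate_hr(synthesize(base)).dominant_lag_samples
            m1 = estimate_hr(synthesize(mod)).dominant_lag_samples
            assert abs(m0 - m1) <= 1

    def test_monotone_degradation_with_noise(self):
        """Heart-rate error grows (weakly) with channel noise."""
        hrs = [70, 120, 190]
        sigs = {hr: synthesize(SynthesisConfig(hr_bpm=hr, rr_bpm=15, duration_s=12, seed=1))
                for hr in hrs}
        maes = []
        for snr_db in (40, 25, 15, 8, 2):
            errs = []
            for hr, sig in sigs.items():
                sd = noise_sd_for_snr(sig, snr_db)
                noisy = apply_channel(sig, ChannelModel(noise_sd=sd, seed=77))
                est = estimate_hr(noisy.segment(1, 11))
                errs.append(abs(est.hr_bpm - hr) if est.valid else 60.0)
            maes.append(np.mean(errs))
        assert maes[-1] >= maes[0]
        # no step of the sweep may *improve* accuracy by more than a lag
        assert all(b >= a - 2.0 for a, b in zip(maes, maes[1:]))

    def test_series_hops_every_second(self, clean_signal):
        track = estimate_hr_series(clean_signal, window_s=10.0, hop_s=1.0)
        assert len(track) == 11
        assert [t for t, _ in track] == pytest.approx(list(range(11)))
        assert all(e.valid for _, e in track)

    def test_short_segment_rejected(self, clean_signal):
        with pytest.raises(ValueError):
            estimate_hr(clean_signal.segment(0, 3.0))
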