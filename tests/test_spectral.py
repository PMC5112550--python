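"""Tests for tachogram resampling, detrending, Welch PSD and HRV metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardioresp as cr
from cardioresp.records import IBISeries
from cardioresp.spectral import Tachogram


def constant_ibis(n=350, value_ms=1000.0):
    t = np.arange(n + 1) * value_ms / 1000.0
    return IBISeries(beat_times_s=t)


def sine_tachogram(freq=0.25, amp=50.0, duration=300.0, rate=4.0, mean=0.0):
    t = np.arange(int(duration * rate)) / rate
    return Tachogram(times_s=t, values_ms=mean + amp * np.sin(2 * np.pi * freq * t), rate_hz=rate)


class TestResampleTachogram:
    def test_constant_series_gives_constant_tachogram(self):
        tach = cr.resample_tachogram(constant_ibis())
        np.testing.assert_allclose(tach.values_ms, 1000.0, atol=1e-6)

    def test_grid_spacing_is_quarter_second(self):
        tach = cr.resample_tachogram(constant_ibis())
        np.testing.assert_allclose(np.diff(tach.times_s), 0.25, atol=1e-12)

    def test_sinusoidal_modulation_recovered_within_one_percent(self):
        """Beat times constructed so the interval ending at time t equals a
        known sinusoid g(t); the resampled tachogram must match g on the
        grid to within 1% of the modulation amplitude."""
        f, amp, base = 0.15, 50.0, 1000.0

        def g(t):
            return base + amp * np.sin(2 * np.pi * f * t)

        times = [0.0]
        while times[-1] < 310.0:
            t_next = times[-1] + base / 1000.0
            for _ in range(30):  # fixed point of t_next = t + g(t_next)/1000
                t_next = times[-1] + g(t_next) / 1000.0
            times.append(t_next)
        ibis = IBISeries(beat_times_s=np.asarray(times))
        tach = cr.resample_tachogram(ibis)
        err = np.abs(tach.values_ms - g(tach.times_s)) / amp
        assert np.max(err[4:-4]) < 0.01  # interior of the spline
        assert np.max(err) < 0.03  # boundary points feel the end conditions

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="60"):
            cr.resample_tachogram(constant_ibis(n=30))


class TestDetrend:
    def test_linear_ramp_annihilated(self):
        t = np.arange(1200) / 4.0
        tach = Tachogram(times_s=t, values_ms=500.0 + 3.0 * t)
        out = cr.detrend_least_squares(tach)
        assert np.max(np.abs(out.values_ms)) < 1e-8

    def test_whole_period_sinusoid_essentially_unchanged(self):
        """Over whole periods a sinusoid is orthogonal to a linear trend, so
        detrending changes it by at most a sliver (discrete-grid leakage)."""
        tach = sine_tachogram(freq=0.25, amp=50.0, duration=300.0)  # 75 whole periods
        out = cr.detrend_least_squares(tach)
        np.testing.assert_allclose(out.values_ms, tach.values_ms, atol=0.02 * 50.0)

    def test_constant_series_zeroed(self):
        t = np.arange(1200) / 4.0
        out = cr.detrend_least_squares(Tachogram(times_s=t, values_ms=np.full(1200, 800.0)))
        np.testing.assert_allclose(out.values_ms, 0.0, atol=1e-9)


class TestWelchPSD:
    def test_sinusoid_band_power_equals_half_amplitude_squared(self):
        spec = cr.welch_psd(sine_tachogram(freq=0.25, amp=50.0))
        assert cr.band_power(spec) == pytest.approx(1250.0, rel=0.10)

    def test_white_noise_total_power_matches_variance(self):
        """Parseval on noise: integrated PSD ~= sigma^2, 50-seed average."""
        sigma = 20.0
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.arange(1200) / 4.0
            tach = Tachogram(times_s=t, values_ms=rng.normal(0, sigma, 1200))
            spec = cr.welch_psd(tach)
            total = np.trapezoid(spec.psd, spec.freqs_hz)
            ratios.append(total / sigma**2)
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_zero_signal_gives_zero_psd(self):
        t = np.arange(1200) / 4.0
        spec = cr.welch_psd(Tachogram(times_s=t, values_ms=np.zeros(1200)))
        np.testing.assert_array_equal(spec.psd, 0.0)

    def test_single_window_case_reports_one_segment(self):
        spec = cr.welch_psd(sine_tachogram(duration=300.0))  # 300 s vs 256 s window
        assert spec.n_segments == 1

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            cr.welch_psd(sine_tachogram(duration=200.0))

    def test_parseval_within_windowing_loss(self):
        """|integral(PSD) - variance| / variance <= 0.15 for mixed signals."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = np.arange(1280) / 4.0
            x = 40 * np.sin(2 * np.pi * 0.23 * t) + rng.normal(0, 15, t.size)
            tach = cr.detrend_least_squares(Tachogram(times_s=t, values_ms=x))
            spec = cr.welch_psd(tach)
            total = np.trapezoid(spec.psd, spec.freqs_hz)
            var = np.var(tach.values_ms)
            assert abs(total - var) / var <= 0.15


class TestBandPower:
    def test_in_band_tone_captured(self):
        spec = cr.welch_psd(sine_tachogram(freq=0.25))
        total = np.trapezoid(spec.psd, spec.freqs_hz)
        assert cr.band_power(spec) / total >= 0.95

    @pytest.mark.parametrize("freq", [0.10, 0.45])
    def test_out_of_band_tone_rejected(self, freq):
        spec = cr.welch_psd(sine_tachogram(freq=freq))
        total = np.trapezoid(spec.psd, spec.freqs_hz)
        assert cr.band_power(spec) / total < 0.05

    def test_inverted_band_rejected(self):
        spec = cr.welch_psd(sine_tachogram())
        with pytest.raises(ValueError, match="inverted"):
            cr.band_power(spec, lo=0.4, hi=0.15)

    def test_empty_band_returns_zero(self):
        spec = cr.welch_psd(sine_tachogram())
        assert cr.band_power(spec, lo=0.3001, hi=0.3002) == 0.0


class TestRMSSD:
    def test_hand_computed_oracle(self):
        ibis = IBISeries(
            beat_times_s=np.concatenate([[0.0], np.cumsum([800, 810, 790, 805]) / 1000.0]),
            ibis_ms=np.array([800.0, 810.0, 790.0, 805.0]),
        )
        assert cr.rmssd(ibis) == pytest.approx(math.sqrt((10**2 + 20**2 + 15**2) / 3), abs=1e-9)

    def test_constant_series_is_zero(self):
        assert cr.rmssd(constant_ibis()) == 0.0

    def test_single_difference(self):
        ibis = IBISeries(beat_times_s=np.array([0.0, 0.8, 1.61]))
        assert cr.rmssd(ibis) == pytest.approx(10.0, abs=1e-9)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            cr.rmssd(IBISeries(beat_times_s=np.array([0.0, 0.8])))

    @given(offset=st.floats(-200, 200), scale=st.floats(0.5, 3.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_invariant_and_scale_equivariant(self, offset, scale):
        rng = np.random.default_rng(4)
        vals = 800 + rng.normal(0, 20, 40)
        base = IBISeries(beat_times_s=np.concatenate([[0.0], np.cumsum(vals) / 1000.0]),
                         ibis_ms=vals)
        shifted = IBISeries(
            beat_times_s=np.concatenate([[0.0], np.cumsum(vals + offset) / 1000.0]),
            ibis_ms=vals + offset,
        )
        scaled = IBISeries(
            beat_times_s=np.concatenate([[0.0], np.cumsum(vals * scale) / 1000.0]),
            ibis_ms=vals * scale,
        )
        assert cr.rmssd(shifted) == pytest.approx(cr.rmssd(base), rel=1e-12)
        assert cr.rmssd(scaled) == pytest.approx(scale * cr.rmssd(base), rel=1e-12)


class TestSummarize:
    @staticmethod
    def summary_for(ibis):
        spec = cr.welch_psd(cr.detrend_least_squares(cr.resample_tachogram(ibis)))
        return cr.summarize(ibis, spec, resp_peak_hz=0.25)

    def test_log_transforms_and_mean_hr(self):
        ibis = cr.simulate_beats(
            cr.SubjectSimConfig(mean_hr=60, resp_freq=0.25, rsa_amplitude=0.04,
                                noise_sd_ms=0, duration_s=300)
        )
        s = self.summary_for(ibis)
        assert s.ln_hf == pytest.approx(math.log(s.hf_ms2), abs=1e-12)
        assert s.ln_rmssd == pytest.approx(math.log(s.rmssd_ms), abs=1e-12)
        assert s.mean_hr_bpm == pytest.approx(60.0, abs=0.1)

    def test_natural_log_magnitudes_match_published_scale(self):
        """ln(772 ms^2) ~= 6.65 and ln(45.6 ms) ~= 3.82 — the published group
        means are only consistent with natural (not base-10) logs."""
        assert math.log(772) == pytest.approx(6.649, abs=0.001)
        assert math.log(45.6) == pytest.approx(3.820, abs=0.001)

    def test_zero_power_raises_without_floor(self):
        ibis = constant_ibis()
        spec = cr.welch_psd(cr.detrend_least_squares(cr.resample_tachogram(ibis)))
        with pytest.raises(ValueError, match="floor"):
            cr.summarize(ibis, spec)

    def test_hf_power_monotone_in_rsa_amplitude(self):
        """Across a 5-point modulation-depth grid (fixed seed) measured HF
        power must increase strictly with the injected amplitude."""
        hf = []
        for amp in [0.01, 0.02, 0.04, 0.06, 0.08]:
            ibis = cr.simulate_beats(
                cr.SubjectSimConfig(mean_hr=64, resp_freq=0.27, rsa_amplitude=amp,
                                    noise_sd_ms=2, duration_s=300, seed=42)
            )
            hf.append(self.summary_for(ibis).hf_ms2)
        assert np.all(np.diff(hf) > 0)
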