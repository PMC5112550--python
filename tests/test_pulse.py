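"""Tests for waveform trimming, upsampling, beat detection and artifact repair."""

import numpy as np
import pytest

import cardioresp as cr
from cardioresp.records import IBISeries, WaveformRecord


def make_wave(duration_s, rate=50.0, f=1.0):
    t = np.arange(int(duration_s * rate)) / rate
    return WaveformRecord(samples=np.sin(2 * np.pi * f * t), sample_rate_hz=rate)


class TestTrim:
    def test_default_window_drops_habituation_head(self):
        w = make_wave(420)
        out = cr.trim_record(w)
        assert out.start_time_s == pytest.approx(120.0)
        assert out.duration_s == pytest.approx(300.0)

    def test_full_keep_is_identity(self):
        w = make_wave(100)
        out = cr.trim_record(w, drop_head_s=0, keep_s=100)
        np.testing.assert_array_equal(out.samples, w.samples)

    def test_short_record_error_names_durations(self):
        with pytest.raises(ValueError, match=r"420.0 s.*100.0 s"):
            cr.trim_record(make_wave(100))


class TestUpsample:
    def test_sinusoid_matches_analytic_form(self):
        w = make_wave(10, rate=50, f=1.0)
        up = cr.upsample_waveform(w, 1000)
        expected = np.sin(2 * np.pi * up.times_s)
        assert np.max(np.abs(up.samples - expected)) < 1e-3

    def test_equal_rate_is_identity(self):
        w = make_wave(10)
        assert cr.upsample_waveform(w, 50.0) is w

    def test_refines_intersample_parabolic_peak(self):
        """A quadratic peak falling between 50 Hz samples must be located
        more accurately on the 1000 Hz grid than on the original grid."""
        rate, vertex = 50.0, 1.0137
        t = np.arange(int(3 * rate)) / rate
        w = WaveformRecord(samples=1.0 - (t - vertex) ** 2, sample_rate_hz=rate)
        up = cr.upsample_waveform(w, 1000.0)
        err_orig = abs(t[np.argmax(w.samples)] - vertex)
        err_up = abs(up.times_s[np.argmax(up.samples)] - vertex)
        assert err_up < err_orig

    def test_nonfinite_samples_rejected(self):
        w = make_wave(10)
        bad = WaveformRecord(samples=np.r_[w.samples[:-1], np.nan], sample_rate_hz=50)
        with pytest.raises(ValueError, match="finite"):
            cr.upsample_waveform(bad, 1000)

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError, match="below"):
            cr.upsample_waveform(make_wave(10), 10.0)


class TestDetectBeats:
    def test_recovers_known_beat_times_within_2ms(self):
        true = cr.simulate_beats(
            cr.SubjectSimConfig(mean_hr=64, resp_freq=0.25, rsa_amplitude=0.05,
                                noise_sd_ms=0, duration_s=300, seed=2)
        )
        wf = cr.render_pulse_waveform(true)
        detected = cr.detect_beats(cr.upsample_waveform(wf))
        # the record-boundary beat at t=0 renders as a half pulse and may be
        # skipped; every other beat must match truth within 2 ms
        assert detected.n_beats >= true.n_beats - 1
        nearest = true.beat_times_s[
            np.abs(true.beat_times_s[None, :] - detected.beat_times_s[:, None]).argmin(axis=1)
        ]
        np.testing.assert_allclose(detected.beat_times_s, nearest, atol=2e-3)

    def test_flat_signal_rejected(self):
        flat = WaveformRecord(samples=np.ones(1000), sample_rate_hz=50)
        with pytest.raises(ValueError, match="flat"):
            cr.detect_beats(flat)

    def test_spurious_peak_in_refractory_window_suppressed(self):
        """A doubled pulse 100 ms after a true beat (inside the 250 ms
        refractory period) must not produce an extra beat."""
        rate = 1000.0
        t = np.arange(int(5 * rate)) / rate
        x = np.zeros(t.size)
        beats = [1.0, 2.0, 3.0, 4.0]
        for tb in beats:
            x += np.exp(-0.5 * ((t - tb) / 0.04) ** 2)
        x += 0.9 * np.exp(-0.5 * ((t - 2.1) / 0.04) ** 2)  # spurious echo
        detected = cr.detect_beats(WaveformRecord(samples=x, sample_rate_hz=rate))
        assert detected.n_beats == len(beats)
        assert np.min(detected.ibis_ms) > 250.0


class TestDetectArtifacts:
    @staticmethod
    def steady_series(n=60, base=800.0, jitter=15.0, seed=0):
        rng = np.random.default_rng(seed)
        ibis = base + rng.normal(0, jitter, size=n)
        t = np.concatenate([[0.0], np.cumsum(ibis) / 1000.0])
        return IBISeries(beat_times_s=t, ibis_ms=ibis)

    def test_clean_series_has_zero_flags(self):
        clean = cr.simulate_beats(
            cr.SubjectSimConfig(mean_hr=60, rsa_amplitude=0.04, noise_sd_ms=3,
                                duration_s=120, seed=5)
        )
        flagged = cr.detect_artifacts(clean)
        assert flagged.artifact_flags.sum() == 0

    @pytest.mark.parametrize("factor", [2.0, 0.5], ids=["missed_beat", "false_beat"])
    def test_isolated_outlier_flagged(self, factor):
        ibis = self.steady_series()
        vals = ibis.ibis_ms.copy()
        vals[30] *= factor
        t = np.concatenate([[0.0], np.cumsum(vals) / 1000.0])
        flagged = cr.detect_artifacts(IBISeries(beat_times_s=t, ibis_ms=vals))
        assert flagged.artifact_flags[30]
        assert flagged.artifact_flags.sum() == 1

    def test_flags_idempotent(self):
        ibis = self.steady_series()
        vals = ibis.ibis_ms.copy()
        vals[10] *= 2
        t = np.concatenate([[0.0], np.cumsum(vals) / 1000.0])
        once = cr.detect_artifacts(IBISeries(beat_times_s=t, ibis_ms=vals))
        twice = cr.detect_artifacts(once)
        np.testing.assert_array_equal(once.artifact_flags, twice.artifact_flags)

    def test_too_few_ibis_rejected(self):
        short = IBISeries(beat_times_s=np.arange(5, dtype=float))
        with pytest.raises(ValueError, match=">= 10"):
            cr.detect_artifacts(short)

    def test_no_false_positives_on_clean_synthetic_records(self, roundtrip_stats):
        """Default threshold: zero flags across 20 seeded clean subjects."""
        assert all(s["n_flags"] == 0 for s in roundtrip_stats)


class TestCorrectArtifacts:
    def test_no_flags_is_identity(self):
        ibis = TestDetectArtifacts.steady_series()
        out = cr.correct_artifacts(ibis)
        np.testing.assert_array_equal(out.ibis_ms, ibis.ibis_ms)
        assert out.corrected

    def test_doubled_interval_in_constant_series_restored(self):
        vals = np.full(50, 800.0)
        vals[25] = 1600.0
        flags = np.zeros(50, dtype=bool)
        flags[25] = True
        t = np.concatenate([[0.0], np.cumsum(vals) / 1000.0])
        out = cr.correct_artifacts(IBISeries(beat_times_s=t, ibis_ms=vals, artifact_flags=flags))
        assert abs(out.ibis_ms[25] - 800.0) < 1.0

    def test_adjacent_flags_on_linear_trend_interpolated_on_trend(self):
        idx = np.arange(60)
        vals = 700.0 + 2.0 * idx  # slow linear drift
        flags = np.zeros(60, dtype=bool)
        vals[[30, 31]] += [400.0, -350.0]
        flags[[30, 31]] = True
        t = np.concatenate([[0.0], np.cumsum(vals) / 1000.0])
        out = cr.correct_artifacts(IBISeries(beat_times_s=t, ibis_ms=vals, artifact_flags=flags))
        np.testing.assert_allclose(out.ibis_ms[[30, 31]], 700.0 + 2.0 * idx[[30, 31]], atol=2.0)

    def test_unflagged_values_bitwise_unchanged(self):
        ibis = TestDetectArtifacts.steady_series(seed=9)
        vals = ibis.ibis_ms.copy()
        vals[12] *= 2
        t = np.concatenate([[0.0], np.cumsum(vals) / 1000.0])
        flagged = cr.detect_artifacts(IBISeries(beat_times_s=t, ibis_ms=vals))
        out = cr.correct_artifacts(flagged)
        keep = ~flagged.artifact_flags
        np.testing.assert_array_equal(out.ibis_ms[keep], vals[keep])

    def test_excessive_flagging_advises_rejection(self):
        vals = np.full(20, 800.0)
        flags = np.zeros(20, dtype=bool)
        flags[:6] = True
        t = np.concatenate([[0.0], np.cumsum(vals) / 1000.0])
        with pytest.raises(ValueError, match="rejected"):
            cr.correct_artifacts(IBISeries(beat_times_s=t, ibis_ms=vals, artifact_flags=flags))


class TestRoundTripRecovery:
    def test_rmssd_and_hr_recovered_across_seeds(self, roundtrip_stats):
        """PPG round trip: RMSSD within 5% and mean HR within 0.5 bpm of the
        generator's truth for every one of 20 seeded subjects."""
        for s in roundtrip_stats:
            assert abs(s["det_rmssd"] - s["true_rmssd"]) / s["true_rmssd"] < 0.05
            assert abs(s["det_hr"] - s["true_hr"]) < 0.5
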