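"""Pulse-waveform processing: trim, upsample, beat detection, artifact repair.

The chain mirrors standard pulse-oximetry HRV preprocessing: drop the
habituation head of the recording, keep a 5-minute analysis window, upsample
the 50 Hz pulse signal to 1000 Hz with cubic splines to refine peak
locations, pick beats with a refractory-limited peak detector, flag
artifactual intervals with a robust successive-difference criterion, and
replace flagged intervals by cubic-spline interpolation over their
neighbours.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .records import IBISeries, WaveformRecord

__all__ = [
    "trim_record",
    "upsample_waveform",
    "detect_beats",
    "detect_artifacts",
    "correct_artifacts",
    "qc_summary",
]

#: Default habituation period removed from the head of each recording, s.
DEFAULT_DROP_HEAD_S = 120.0
#: Default analysis window length, s.
DEFAULT_KEEP_S = 300.0
#: Refractory period between detected beats (250 ms = 240 bpm ceiling).
DEFAULT_REFRACTORY_S = 0.25
#: Default multiplier on the quartile deviation of successive IBI
#: differences used by the artifact detector.
DEFAULT_ARTIFACT_MULTIPLIER = 6.0
#: Reject a record outright when more than this fraction of IBIs is flagged.
DEFAULT_REJECTION_CEILING = 0.20


def trim_record(
    w: WaveformRecord,
    drop_head_s: float = DEFAULT_DROP_HEAD_S,
    keep_s: float = DEFAULT_KEEP_S,
) -> WaveformRecord:
    """Return the window [drop_head_s, drop_head_s + keep_s) of a record.

    Defaults discard the first two minutes (habituation) and keep the
    following five minutes.
    """
    required = drop_head_s + keep_s
    if w.duration_s + 1e-9 < required:
        raise ValueError(
            f"record too short: need {required:.1f} s "
            f"(drop {drop_head_s:.1f} + keep {keep_s:.1f}) but only "
            f"{w.duration_s:.1f} s available"
        )
    i0 = int(round(drop_head_s * w.sample_rate_hz))
    i1 = i0 + int(round(keep_s * w.sample_rate_hz))
    return WaveformRecord(
        samples=w.samples[i0:i1],
        sample_rate_hz=w.sample_rate_hz,
        start_time_s=w.start_time_s + i0 / w.sample_rate_hz,
    )


def upsample_waveform(w: WaveformRecord, target_rate_hz: float = 1000.0) -> WaveformRecord:
    """Cubic-spline upsample onto a uniform grid at ``target_rate_hz``.

    Identity when the target equals the source rate. Values at the original
    sample times are preserved (spline interpolates the data).
    """
    if target_rate_hz < w.sample_rate_hz:
        raise ValueError(
            f"target rate {target_rate_hz} Hz is below the source rate {w.sample_rate_hz} Hz"
        )
    if not np.all(np.isfinite(w.samples)):
        raise ValueError("waveform contains non-finite samples")
    if target_rate_hz == w.sample_rate_hz:
        return w
    t = w.times_s
    cs = CubicSpline(t, w.samples)
    n_out = int(np.floor((t[-1] - t[0]) * target_rate_hz)) + 1
    t_out = t[0] + np.arange(n_out) / target_rate_hz
    return WaveformRecord(
        samples=cs(t_out), sample_rate_hz=target_rate_hz, start_time_s=w.start_time_s
    )


def _refine_peak(x: np.ndarray, idx: int) -> float:
    """Sub-sample peak refinement by fitting a parabola through the peak
    sample and its two neighbours; returns a fractional index."""
    if idx <= 0 or idx >= x.size - 1:
        return float(idx)
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a strict local max in the quadratic sense
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def detect_beats(
    w: WaveformRecord,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    prominence_fraction: float = 0.3,
) -> IBISeries:
    """Pick pulse peaks and return the interbeat-interval series.

    Local maxima are accepted when separated by at least ``refractory_s``
    and prominent relative to the signal's amplitude range
    (``prominence_fraction`` of the peak-to-trough span, an adaptive
    threshold). Peak times are refined by parabolic interpolation.
    """
    x = w.samples
    span = float(np.max(x) - np.min(x))
    if span <= 0:
        raise ValueError("flat signal: no beats detectable")
    distance = max(1, int(round(refractory_s * w.sample_rate_hz)))
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence_fraction * span)
    if peaks.size < 3:
        raise ValueError(f"only {peaks.size} peaks found; need >= 3 for any HRV")
    refined = np.array([_refine_peak(x, int(p)) for p in peaks])
    beat_times = w.start_time_s + refined / w.sample_rate_hz
    return IBISeries(beat_times_s=beat_times)


def detect_artifacts(
    ibis: IBISeries, multiplier: float = DEFAULT_ARTIFACT_MULTIPLIER
) -> IBISeries:
    """Flag artifactual IBIs by a robust successive-difference criterion.

    The threshold is ``multiplier`` times the quartile deviation (half the
    interquartile range) of the successive-difference distribution — a
    dispersion estimate immune to the very outliers being hunted. An IBI is
    flagged when it deviates from *both* of its neighbours by more than the
    threshold, so an isolated missed beat (doubled interval) or false
    trigger (halved interval) is flagged without dragging its healthy
    neighbours along. Flags are recomputed from values, so the operation is
    idempotent.
    """
    n = ibis.ibis_ms.size
    if n < 10:
        raise ValueError(f"need >= 10 IBIs for a stable dispersion estimate, got {n}")
    v = ibis.ibis_ms
    d = np.diff(v)
    q1, q3 = np.percentile(d, [25, 75])
    qd = (q3 - q1) / 2.0
    qd = max(qd, 1e-6)  # degenerate constant series: any jump is an artifact
    thr = multiplier * qd
    dev_prev = np.abs(np.concatenate([[d[0]], d]))  # |v[i] - v[i-1]|, edge uses forward diff
    dev_next = np.abs(np.concatenate([d, [d[-1]]]))  # |v[i] - v[i+1]|, edge uses backward diff
    flags = (dev_prev > thr) & (dev_next > thr)
    return ibis.with_flags(flags)


def correct_artifacts(
    ibis: IBISeries, rejection_ceiling: float = DEFAULT_REJECTION_CEILING
) -> IBISeries:
    """Replace flagged IBIs by cubic-spline interpolation over beat index.

    The spline is fitted to the unflagged intervals as a function of their
    index, evaluated at the flagged indices. Beat times are rebuilt from the
    corrected intervals so the series stays internally consistent; unflagged
    intervals are untouched.

    Raises
    ------
    ValueError
        If more than ``rejection_ceiling`` of the intervals is flagged
        (the record should be rejected, not patched).
    """
    flags = ibis.artifact_flags
    if not flags.any():
        return IBISeries(
            beat_times_s=ibis.beat_times_s,
            ibis_ms=ibis.ibis_ms,
            artifact_flags=flags,
            corrected=True,
        )
    frac = flags.mean()
    if frac > rejection_ceiling:
        raise ValueError(
            f"{frac:.0%} of IBIs flagged (> {rejection_ceiling:.0%} ceiling): "
            "record should be rejected rather than interpolated"
        )
    idx = np.arange(ibis.ibis_ms.size)
    good = ~flags
    if good.sum() < 4:
        raise ValueError("too few clean IBIs to anchor a cubic spline")
    cs = CubicSpline(idx[good], ibis.ibis_ms[good])
    corrected = ibis.ibis_ms.copy()
    corrected[flags] = cs(idx[flags])
    if np.any(corrected <= 0):
        raise ValueError("spline correction produced non-positive IBIs")
    beat_times = ibis.beat_times_s[0] + np.concatenate([[0.0], np.cumsum(corrected) / 1000.0])
    return IBISeries(
        beat_times_s=beat_times, ibis_ms=corrected, artifact_flags=flags, corrected=True
    )


def qc_summary(ibis: IBISeries) -> dict:
    """Per-record quality-control counts, JSON-serialisable."""
    return {
        "n_beats": int(ibis.n_beats),
        "n_ibis": int(ibis.ibis_ms.size),
        "n_flagged": int(ibis.artifact_flags.sum()),
        "fraction_flagged": float(ibis.artifact_flags.mean()),
        "corrected": bool(ibis.corrected),
        "mean_hr_bpm": float(ibis.mean_hr_bpm),
    }
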