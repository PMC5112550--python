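"""Spectral and time-domain HRV metrics.

From a corrected interbeat-interval series: cubic-spline resampling onto a
uniform 4 Hz tachogram, least-squares linear detrending, a Hann-windowed
Welch periodogram (256 s window, 50% overlap — with a 300 s record only one
complete window fits, so a single windowed periodogram is returned),
trapezoidal band power over the high-frequency band 0.15-0.4 Hz, RMSSD, and
the per-subject summary with natural-log transforms of HF power and RMSSD.

The PSD uses density normalisation with window-power compensation, so
integrating it over frequency recovers the signal variance (Parseval, up to
windowing loss) and "absolute power in ms²" is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.signal
from scipy.interpolate import CubicSpline

from .records import IBISeries

__all__ = [
    "Tachogram",
    "SpectralResult",
    "HRVSummary",
    "resample_tachogram",
    "detrend_least_squares",
    "welch_psd",
    "band_power",
    "rmssd",
    "summarize",
]

#: High-frequency (respiratory) band, Hz.
HF_BAND = (0.15, 0.4)
#: Tachogram resampling rate, Hz.
TACHOGRAM_RATE_HZ = 4.0
#: Welch window length, s.
DEFAULT_WINDOW_S = 256.0


@dataclass(frozen=True)
class Tachogram:
    """Interbeat intervals resampled onto a uniform time grid."""

    times_s: np.ndarray
    values_ms: np.ndarray
    rate_hz: float = TACHOGRAM_RATE_HZ
    detrended: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values_ms, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values_ms", v)
        if t.size != v.size or t.size < 2:
            raise ValueError("tachogram needs matching times and values, >= 2 points")
        dt = np.diff(t)
        if not np.allclose(dt, 1.0 / self.rate_hz, rtol=1e-9, atol=1e-9):
            raise ValueError("tachogram grid must be uniform at rate_hz")
        if not np.all(np.isfinite(v)):
            raise ValueError("tachogram values must be finite")


@dataclass(frozen=True)
class SpectralResult:
    """One-sided PSD of a tachogram with analysis parameters."""

    freqs_hz: np.ndarray
    psd: np.ndarray  # ms^2 / Hz
    window_s: float
    overlap: float
    n_segments: int

    def to_csv(self, path) -> None:
        """Dump the spectrum as two-column CSV (freq_hz, psd)."""
        np.savetxt(
            path,
            np.column_stack([self.freqs_hz, self.psd]),
            fmt="%.8g",
            delimiter=",",
            header="freq_hz,psd",
            comments="",
        )


@dataclass(frozen=True)
class HRVSummary:
    """Per-subject derived HRV metrics."""

    hf_ms2: float
    ln_hf: float
    rmssd_ms: float
    ln_rmssd: float
    mean_hr_bpm: float
    resp_peak_hz: Optional[float] = None
    included: bool = True


def resample_tachogram(ibis: IBISeries, rate_hz: float = TACHOGRAM_RATE_HZ) -> Tachogram:
    """Cubic-spline interpolation of IBI versus beat time onto a uniform grid.

    Each interval is anchored at the time of its terminating beat; the grid
    is restricted to the interior of the beat-time span so the spline never
    extrapolates.
    """
    if ibis.duration_s < 60.0:
        raise ValueError(
            f"IBI series spans {ibis.duration_s:.1f} s; >= 60 s needed for spectral HRV"
        )
    t_anchor = ibis.beat_times_s[1:]
    cs = CubicSpline(t_anchor, ibis.ibis_ms)
    dt = 1.0 / rate_hz
    t0 = np.ceil(t_anchor[0] / dt) * dt
    n = int(np.floor((t_anchor[-1] - t0) / dt)) + 1
    grid = t0 + np.arange(n) * dt
    return Tachogram(times_s=grid, values_ms=cs(grid), rate_hz=rate_hz, detrended=False)


def detrend_least_squares(t: Tachogram) -> Tachogram:
    """Subtract the ordinary-least-squares straight line from the tachogram."""
    if t.times_s.size < 2:
        raise ValueError("need >= 2 points to detrend")
    coef = np.polyfit(t.times_s, t.values_ms, 1)
    resid = t.values_ms - np.polyval(coef, t.times_s)
    return Tachogram(times_s=t.times_s, values_ms=resid, rate_hz=t.rate_hz, detrended=True)


def welch_psd(
    t: Tachogram, window_s: float = DEFAULT_WINDOW_S, overlap: float = 0.5
) -> SpectralResult:
    """Hann-windowed, overlap-averaged periodogram of the tachogram.

    Density scaling with window-power compensation: integrating the PSD over
    frequency recovers the signal variance up to windowing loss. When the
    record admits only one complete window (e.g. 300 s of data with a 256 s
    window) a single windowed periodogram is returned and ``n_segments=1``.
    """
    nperseg = int(round(window_s * t.rate_hz))
    n = t.values_ms.size
    if n < nperseg:
        raise ValueError(
            f"tachogram ({n / t.rate_hz:.0f} s) shorter than the {window_s:.0f} s window; "
            "use a shorter window"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, psd = scipy.signal.welch(
        t.values_ms,
        fs=t.rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
    )
    n_segments = 1 + (n - nperseg) // max(1, nperseg - noverlap)
    return SpectralResult(
        freqs_hz=freqs, psd=psd, window_s=window_s, overlap=overlap, n_segments=n_segments
    )


def band_power(s: SpectralResult, lo: float = HF_BAND[0], hi: float = HF_BAND[1]) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], ms².

    Bins whose centre lies in the closed band contribute.
    """
    if hi <= lo:
        raise ValueError(f"inverted band: [{lo}, {hi}]")
    if lo < 0 or hi > s.freqs_hz[-1] + 1e-12:
        raise ValueError(f"band [{lo}, {hi}] outside [0, Nyquist={s.freqs_hz[-1]}]")
    mask = (s.freqs_hz >= lo) & (s.freqs_hz <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(s.psd[mask], s.freqs_hz[mask]))


def rmssd(ibis: IBISeries) -> float:
    """Root mean square of successive IBI differences, ms."""
    if ibis.ibis_ms.size < 2:
        raise ValueError("RMSSD needs at least 2 IBIs")
    d = np.diff(ibis.ibis_ms)
    return float(np.sqrt(np.mean(d**2)))


def summarize(
    ibis: IBISeries,
    spectral: SpectralResult,
    resp_peak_hz: Optional[float] = None,
    included: bool = True,
    power_floor_ms2: float = 0.0,
) -> HRVSummary:
    """Assemble the per-subject metric summary with natural-log transforms.

    ``power_floor_ms2`` (default 0, i.e. disabled) can clip HF power and
    RMSSD away from zero before the log; with the floor disabled a zero
    value raises instead of propagating -inf.
    """
    hf = band_power(spectral)
    r = rmssd(ibis)
    if power_floor_ms2 > 0:
        hf = max(hf, power_floor_ms2)
        r = max(r, np.sqrt(power_floor_ms2))
    if hf <= 0 or r <= 0:
        raise ValueError(
            "zero HF power or RMSSD: log-transform undefined; pass power_floor_ms2 > 0 "
            "to clip degenerate records"
        )
    return HRVSummary(
        hf_ms2=hf,
        ln_hf=float(np.log(hf)),
        rmssd_ms=r,
        ln_rmssd=float(np.log(r)),
        mean_hr_bpm=ibis.mean_hr_bpm,
        resp_peak_hz=resp_peak_hz,
        included=included,
    )
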