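"""Respiratory peak-frequency estimation and band-inclusion filtering.

The breathing rate is read off the strain-gauge trace as the argmax of a
Hann-windowed FFT magnitude spectrum after linear detrending. The search
runs over the full spectrum up to Nyquist — not just the 0.15–0.4 Hz
respiratory band — because subjects breathing outside the band must be
*seen* to be excluded. The inclusion test then checks the closed interval
[0.15, 0.4] Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .records import WaveformRecord

__all__ = ["RespirationResult", "RESPIRATORY_BAND", "respiratory_peak", "apply_inclusion_filter"]

#: Typical adult respiratory band, Hz (closed interval for inclusion).
RESPIRATORY_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class RespirationResult:
    peak_freq_hz: float
    in_band: bool
    band: tuple[float, float] = RESPIRATORY_BAND


def respiratory_peak(
    w: WaveformRecord, band: tuple[float, float] = RESPIRATORY_BAND
) -> RespirationResult:
    """Estimate the peak respiratory frequency of a strain-gauge record.

    Detrend (linear least squares), apply a Hann window, take the FFT
    magnitude spectrum and return the frequency of its maximum (DC bin
    excluded). Amplitude scaling of the input cannot change the argmax.
    """
    if w.duration_s < 60.0:
        raise ValueError(f"need >= 60 s of respiration signal, got {w.duration_s:.1f} s")
    if not np.all(np.isfinite(w.samples)):
        raise ValueError("respiration record contains non-finite samples")
    if np.ptp(w.samples) < 1e-12:
        raise ValueError("constant respiration signal: no spectral peak")
    x = scipy.signal.detrend(w.samples, type="linear")
    win = scipy.signal.get_window("hann", x.size)
    mag = np.abs(np.fft.rfft(x * win))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / w.sample_rate_hz)
    mag[0] = 0.0  # DC is not a breathing rate
    peak = float(freqs[int(np.argmax(mag))])
    lo, hi = band
    return RespirationResult(peak_freq_hz=peak, in_band=bool(lo <= peak <= hi), band=band)


def apply_inclusion_filter(
    cohort: pd.DataFrame,
    peak_col: str = "resp_peak_hz",
    band: tuple[float, float] = RESPIRATORY_BAND,
) -> pd.DataFrame:
    """Flag subjects whose respiratory peak lies outside the closed band.

    Returns a copy with a boolean ``included`` column; rows with a missing
    peak estimate are excluded. Downstream statistics must restrict to
    ``included`` rows.
    """
    if peak_col not in cohort.columns:
        raise KeyError(f"cohort table lacks a '{peak_col}' column")
    lo, hi = band
    out = cohort.copy()
    peaks = out[peak_col]
    out["included"] = peaks.notna() & (peaks >= lo) & (peaks <= hi)
    return out
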