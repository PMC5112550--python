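"""Core data containers for cardiorespiratory signals.

Two containers travel through the whole pipeline:

* :class:`WaveformRecord` — a uniformly sampled 1-D signal (pulse
  plethysmogram or respiration strain gauge) with its sample rate.
* :class:`IBISeries` — an ordered series of interbeat intervals (IBIs, ms)
  with the beat times they derive from and per-interval artifact flags.

Both read and write small plain-text formats: waveforms as two-column CSV
(time_s, value) and IBI series as one millisecond value per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["WaveformRecord", "IBISeries"]


@dataclass(frozen=True)
class WaveformRecord:
    """Uniformly sampled 1-D physiological signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in arbitrary units.
    sample_rate_hz : float
        Sampling rate, Hz. Must be positive.
    start_time_s : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a waveform needs at least 2 samples in a 1-D array")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Duration covered by the record (n / rate)."""
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV (time_s, value)."""
        arr = np.column_stack([self.times_s, self.samples])
        np.savetxt(path, arr, fmt="%.6f", delimiter=",", header="time_s,value", comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "WaveformRecord":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        t, v = arr[:, 0], arr[:, 1]
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: time column is not uniformly spaced")
        return cls(samples=v, sample_rate_hz=1.0 / dt[0], start_time_s=float(t[0]))


@dataclass(frozen=True)
class IBISeries:
    """Interbeat intervals with beat times and artifact bookkeeping.

    ``ibis_ms[i]`` is the interval ending at ``beat_times_s[i + 1]``;
    ``artifact_flags[i]`` marks it as a suspected artifact. ``corrected``
    records whether artifact replacement has been applied.
    """

    beat_times_s: np.ndarray
    ibis_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    artifact_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_s, dtype=float)
        object.__setattr__(self, "beat_times_s", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("an IBI series needs at least 2 beat times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        ibis = self.ibis_ms
        if ibis is None:
            ibis = np.diff(t) * 1000.0
        ibis = np.asarray(ibis, dtype=float)
        if ibis.size != t.size - 1:
            raise ValueError("len(ibis_ms) must equal len(beat_times_s) - 1")
        if np.any(ibis <= 0):
            raise ValueError("all IBIs must be strictly positive")
        object.__setattr__(self, "ibis_ms", ibis)
        flags = self.artifact_flags
        if flags is None:
            flags = np.zeros(ibis.size, dtype=bool)
        flags = np.asarray(flags, dtype=bool)
        if flags.size != ibis.size:
            raise ValueError("artifact_flags must align with ibis_ms")
        object.__setattr__(self, "artifact_flags", flags)

    @property
    def n_beats(self) -> int:
        return self.beat_times_s.size

    @property
    def duration_s(self) -> float:
        return float(self.beat_times_s[-1] - self.beat_times_s[0])

    @property
    def mean_hr_bpm(self) -> float:
        return 60000.0 / float(np.mean(self.ibis_ms))

    def with_flags(self, flags: np.ndarray) -> "IBISeries":
        return replace(self, artifact_flags=np.asarray(flags, dtype=bool))

    def to_text(self, path: str | Path) -> None:
        """Write intervals as plain text, one ms value per line."""
        np.savetxt(path, self.ibis_ms, fmt="%.6f")

    @classmethod
    def from_text(cls, path: str | Path, start_time_s: float = 0.0) -> "IBISeries":
        """Read a plain-text IBI file (one interval in ms per line).

        Beat times are reconstructed by cumulative summation from
        ``start_time_s``.
        """
        ibis = np.atleast_1d(np.loadtxt(path, dtype=float))
        t = start_time_s + np.concatenate([[0.0], np.cumsum(ibis) / 1000.0])
        return cls(beat_times_s=t, ibis_ms=ibis)
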