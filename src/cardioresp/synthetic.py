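"""Synthetic cardiorespiratory cohort generator.

Real pulse-oximetry and strain-gauge recordings from the study population are
not distributable, so the analysis chain is exercised on simulated subjects
with the same statistical structure: 5-minute-scale supine recordings with
respiratory sinus arrhythmia (RSA) at a subject-specific breathing frequency,
group-specific mean heart rate and high-frequency (HF) power levels, and a
configurable cross-subject correlation between respiratory frequency and
log HF power.

Heart beats come from an integral pulse frequency modulation (IPFM) model:
beats fire when the integral of a modulated instantaneous rate crosses
successive integer multiples of the mean heart period. The modulation is

    m(t) = 1 + a_r * sin(2*pi*f_resp*t) + a_l * sin(2*pi*f_lf*t + phi)

where ``f_resp`` injects RSA and the low-frequency (LF) term emulates
baroreflex-band variability. ``rsa_amplitude`` is specified in the IBI
domain — the peak IBI deviation as a fraction of the mean heart period — and
the rate-domain amplitude ``a_r`` is pre-compensated for the sinc(f*T)
attenuation that integral averaging over one heart period imposes, so a
subject configured with amplitude ``A`` (in fractions of the period) really
shows an IBI oscillation of ``A * T`` ms and HF power ``(A*T)^2 / 2`` ms².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .records import IBISeries, WaveformRecord

__all__ = [
    "SubjectSimConfig",
    "CohortSimConfig",
    "SubjectRecords",
    "CohortSim",
    "simulate_beats",
    "render_pulse_waveform",
    "render_respiration",
    "simulate_cohort",
    "rsa_amplitude_for_hf",
    "patients_like_config",
    "controls_like_config",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is physically inconsistent."""


@dataclass(frozen=True)
class SubjectSimConfig:
    """Configuration for one simulated subject.

    Parameters
    ----------
    mean_hr : float
        Mean heart rate, beats/min; must lie in (20, 220).
    resp_freq : float
        Respiratory frequency, Hz (drives RSA).
    rsa_amplitude : float
        Peak IBI modulation as a fraction of the mean heart period
        (dimensionless; 0.05 at 60 bpm means a ±50 ms IBI swing).
    lf_amplitude : float
        Same convention for the low-frequency term.
    lf_freq : float
        LF oscillation frequency, Hz (default 0.1, the baroreflex band).
    noise_sd_ms : float
        SD of white Gaussian noise added to each IBI, ms.
    duration_s : float
        Length of the simulated recording, s.
    pulse_rate_hz : float
        Sample rate of the rendered pulse waveform, Hz (default 50,
        matching a finger photoplethysmograph).
    seed : int
        Seed for all randomness of this subject.
    """

    mean_hr: float = 64.0
    resp_freq: float = 0.29
    rsa_amplitude: float = 0.05
    lf_amplitude: float = 0.0
    lf_freq: float = 0.1
    noise_sd_ms: float = 0.0
    duration_s: float = 300.0
    pulse_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20.0 < self.mean_hr < 220.0):
            raise ConfigurationError(f"mean_hr must be in (20, 220) bpm, got {self.mean_hr}")
        if not (0.0 < self.resp_freq < self.pulse_rate_hz / 2):
            raise ConfigurationError(
                f"resp_freq must lie in (0, {self.pulse_rate_hz / 2}) Hz, got {self.resp_freq}"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.rsa_amplitude < 0 or self.lf_amplitude < 0:
            raise ConfigurationError("modulation amplitudes must be non-negative")
        if self.noise_sd_ms < 0:
            raise ConfigurationError("noise_sd_ms must be non-negative")

    @property
    def mean_period_s(self) -> float:
        return 60.0 / self.mean_hr


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for a whole simulated group.

    Cross-subject structure: (resp_freq, ln HF) pairs are drawn from a
    bivariate Gaussian with correlation ``target_rho``, with the respiratory
    marginal truncated to ``resp_freq_bounds`` so the downstream band
    inclusion filter (0.15–0.4 Hz) has something to reject. Defaults follow
    the healthy-control group summary statistics; see
    :func:`patients_like_config` for the clinical-group analogue.
    """

    n_subjects: int = 149
    group_label: str = "controls"
    resp_freq_mean: float = 0.29
    resp_freq_sd: float = 0.05
    mean_hr_mean: float = 64.31
    mean_hr_sd: float = 10.06
    ln_hf_mean: float = 6.65
    ln_hf_sd: float = 0.99
    target_rho: float = -0.04
    seed: int = 0
    resp_freq_bounds: tuple[float, float] = (0.10, 0.45)
    lf_amplitude: float = 0.03
    noise_sd_ms: float = 3.0
    duration_s: float = 420.0
    pulse_rate_hz: float = 50.0
    resp_sample_rate_hz: float = 10.0
    resp_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3 (correlation undefined below)")
        if abs(self.target_rho) > 1:
            raise ConfigurationError("|target_rho| must be <= 1")
        for name in ("resp_freq_sd", "mean_hr_sd", "ln_hf_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.resp_freq_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("resp_freq_bounds must satisfy 0 < lo < hi")


def patients_like_config(seed: int = 0, **overrides) -> CohortSimConfig:
    """Cohort configuration mirroring the clinical-group summaries
    (n=55, mean HR 71.3 (12.96) bpm, ln HF 6.18 (1.14), rho = -0.29)."""
    defaults = dict(
        n_subjects=55,
        group_label="patients",
        mean_hr_mean=71.3,
        mean_hr_sd=12.96,
        ln_hf_mean=6.18,
        ln_hf_sd=1.14,
        target_rho=-0.29,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSimConfig(**defaults)


def controls_like_config(seed: int = 0, **overrides) -> CohortSimConfig:
    """Cohort configuration mirroring the healthy-control summaries
    (n=149, mean HR 64.31 (10.06) bpm, ln HF 6.65 (0.99), rho = -0.04)."""
    defaults = dict(seed=seed)
    defaults.update(overrides)
    return CohortSimConfig(**defaults)


def _averaging_factor(freq_hz: float, period_s: float) -> float:
    """Attenuation of an IBI-domain sinusoid caused by integrating the
    modulated rate over one heart period: sinc(f*T) in numpy convention."""
    return float(np.sinc(freq_hz * period_s))


def simulate_beats(cfg: SubjectSimConfig) -> IBISeries:
    """Generate beat times from the IPFM model.

    Beats fire at the times ``t_k`` where the integral of the modulated
    rate crosses successive integer multiples of the mean heart period.
    Gaussian noise (``cfg.noise_sd_ms``) is then added to the intervals and
    beat times are rebuilt by cumulative summation.

    Raises
    ------
    ConfigurationError
        If the (compensated) modulation depth could drive the instantaneous
        rate to zero or below.
    """
    T = cfg.mean_period_s
    a_r = cfg.rsa_amplitude / _averaging_factor(cfg.resp_freq, T)
    a_l = (
        cfg.lf_amplitude / _averaging_factor(cfg.lf_freq, T)
        if cfg.lf_amplitude > 0
        else 0.0
    )
    if a_r + a_l >= 1.0:
        raise ConfigurationError(
            f"total modulation depth {a_r + a_l:.3f} (after averaging "
            "compensation) would make the instantaneous rate non-positive"
        )
    rng = np.random.default_rng(cfg.seed)
    phi = float(rng.uniform(0, 2 * np.pi)) if a_l > 0 else 0.0

    w_r = 2 * np.pi * cfg.resp_freq
    w_l = 2 * np.pi * cfg.lf_freq

    def integrated_rate(t: float) -> float:
        # integral of m(s) ds over [0, t], in units of heart periods
        out = t
        if a_r > 0:
            out += a_r * (1.0 - np.cos(w_r * t)) / w_r
        if a_l > 0:
            out += a_l * (np.cos(phi) - np.cos(w_l * t + phi)) / w_l
        return out / T

    min_rate = (1.0 - a_r - a_l) / T
    beats = [0.0]
    k = 1
    while True:
        lo = beats[-1]
        hi = lo + 1.0 / min_rate + T
        t_k = brentq(lambda s: integrated_rate(s) - k, lo, hi, xtol=1e-9)
        if t_k > cfg.duration_s + 1e-9:
            break
        beats.append(t_k)
        k += 1
    if len(beats) < 3:
        raise ConfigurationError("configuration produced fewer than 3 beats")

    beat_times = np.asarray(beats)
    ibis = np.diff(beat_times) * 1000.0
    if cfg.noise_sd_ms > 0:
        ibis = ibis + rng.normal(0.0, cfg.noise_sd_ms, size=ibis.size)
        if np.any(ibis <= 0):
            raise ConfigurationError("noise_sd_ms too large: produced non-positive IBIs")
        beat_times = beat_times[0] + np.concatenate([[0.0], np.cumsum(ibis) / 1000.0])
    return IBISeries(beat_times_s=beat_times, ibis_ms=ibis)


def render_pulse_waveform(
    ibis: IBISeries,
    pulse_rate_hz: float = 50.0,
    template_width_s: float = 0.25,
    baseline_wander_amp: float = 0.0,
    baseline_wander_freq_hz: float = 0.01,
    duration_s: Optional[float] = None,
) -> WaveformRecord:
    """Render a pulse-oximeter-like waveform from beat times.

    One smooth unimodal (Gaussian) pulse template is superposed per beat, so
    the waveform's local maxima sit at the beat times to within one sample.

    Raises
    ------
    ValueError
        If ``ibis`` is empty or the template is wider than the shortest
        interval (adjacent pulses would merge into one peak).
    """
    if ibis is None or np.size(getattr(ibis, "beat_times_s", [])) == 0:
        raise ValueError("cannot render a waveform from an empty IBI series")
    min_ibi_s = float(np.min(ibis.ibis_ms)) / 1000.0
    if template_width_s >= min_ibi_s:
        raise ValueError(
            f"pulse template width {template_width_s} s is not narrower than "
            f"the shortest IBI ({min_ibi_s:.3f} s); peaks would merge"
        )
    sigma = template_width_s / 6.0  # +-3 sigma spans the template width
    t_end = float(ibis.beat_times_s[-1]) + 2 * template_width_s
    if duration_s is not None:
        t_end = max(t_end, duration_s)
    n = int(np.ceil(t_end * pulse_rate_hz)) + 1
    t = np.arange(n) / pulse_rate_hz
    x = np.zeros(n)
    half = 5.0 * sigma
    for tb in ibis.beat_times_s:
        i0 = max(0, int(np.floor((tb - half) * pulse_rate_hz)))
        i1 = min(n, int(np.ceil((tb + half) * pulse_rate_hz)) + 1)
        x[i0:i1] += np.exp(-0.5 * ((t[i0:i1] - tb) / sigma) ** 2)
    if baseline_wander_amp > 0:
        x += baseline_wander_amp * np.sin(2 * np.pi * baseline_wander_freq_hz * t)
    return WaveformRecord(samples=x, sample_rate_hz=pulse_rate_hz, start_time_s=0.0)


def render_respiration(
    resp_freq: float,
    duration_s: float,
    sample_rate_hz: float = 10.0,
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    seed: Optional[int] = None,
) -> WaveformRecord:
    """Render a strain-gauge-like respiration trace: a sinusoid at
    ``resp_freq`` plus white Gaussian noise."""
    if not (0 < resp_freq < sample_rate_hz / 2):
        raise ValueError(
            f"resp_freq must lie in (0, Nyquist={sample_rate_hz / 2}) Hz, got {resp_freq}"
        )
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    x = amplitude * np.sin(2 * np.pi * resp_freq * t)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return WaveformRecord(samples=x, sample_rate_hz=sample_rate_hz, start_time_s=0.0)


def rsa_amplitude_for_hf(hf_ms2: float, mean_hr: float) -> float:
    """Modulation depth (fraction of the mean heart period) whose sinusoidal
    IBI oscillation carries ``hf_ms2`` of spectral power.

    A sinusoid of amplitude A ms concentrates variance A^2/2 at its
    frequency, so A = sqrt(2 * HF) and the depth is A / T_ms.
    """
    if hf_ms2 <= 0:
        raise ValueError("hf_ms2 must be positive")
    t_ms = 60000.0 / mean_hr
    return float(np.sqrt(2.0 * hf_ms2) / t_ms)


@dataclass(frozen=True)
class SubjectRecords:
    """Rendered signals plus generator ground truth for one subject."""

    subject_id: str
    true_ibis: IBISeries
    pulse: WaveformRecord
    respiration: WaveformRecord


@dataclass(frozen=True)
class CohortSim:
    """A simulated group: per-subject true parameters and, optionally,
    the rendered records."""

    config: CohortSimConfig
    table: pd.DataFrame
    records: Optional[list[SubjectRecords]] = None


def _draw_latents(cfg: CohortSimConfig, rng: np.random.Generator):
    """Bivariate-Gaussian (resp_freq, ln_hf) pairs, jointly truncated so
    resp_freq stays inside cfg.resp_freq_bounds."""
    lo, hi = cfg.resp_freq_bounds
    rho = cfg.target_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    resp = np.empty(cfg.n_subjects)
    lnhf = np.empty(cfg.n_subjects)
    filled = 0
    while filled < cfg.n_subjects:
        z = rng.standard_normal((cfg.n_subjects, 2)) @ chol.T
        r = cfg.resp_freq_mean + cfg.resp_freq_sd * z[:, 0]
        h = cfg.ln_hf_mean + cfg.ln_hf_sd * z[:, 1]
        keep = (r > lo) & (r < hi)
        take = min(int(keep.sum()), cfg.n_subjects - filled)
        resp[filled : filled + take] = r[keep][:take]
        lnhf[filled : filled + take] = h[keep][:take]
        filled += take
    return resp, lnhf


def simulate_cohort(cfg: CohortSimConfig, render: bool = True) -> CohortSim:
    """Simulate a whole group.

    Draws per-subject (resp_freq, ln HF target) from the correlated
    bivariate Gaussian, an independent Gaussian mean heart rate, maps the HF
    target to an RSA modulation depth via the A^2/2 identity, and (when
    ``render`` is true) renders the IPFM beats, the pulse waveform and the
    respiration trace for every subject. All randomness fans out
    deterministically from ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_latent, ss_hr, ss_subjects = root.spawn(3)
    rng_lat = np.random.default_rng(ss_latent)
    rng_hr = np.random.default_rng(ss_hr)

    resp, lnhf = _draw_latents(cfg, rng_lat)
    hr = np.clip(
        rng_hr.normal(cfg.mean_hr_mean, cfg.mean_hr_sd, size=cfg.n_subjects), 35.0, 180.0
    )
    subject_seeds = [
        int(s.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        for s in ss_subjects.spawn(cfg.n_subjects)
    ]

    rows = []
    records: Optional[list[SubjectRecords]] = [] if render else None
    for i in range(cfg.n_subjects):
        sid = f"{cfg.group_label}-{i:03d}"
        amp = rsa_amplitude_for_hf(float(np.exp(lnhf[i])), hr[i])
        row = dict(
            subject_id=sid,
            group=cfg.group_label,
            true_resp_freq_hz=resp[i],
            true_ln_hf=lnhf[i],
            true_mean_hr_bpm=hr[i],
            rsa_amplitude=amp,
            seed=subject_seeds[i],
        )
        rows.append(row)
        if render:
            sub_cfg = SubjectSimConfig(
                mean_hr=float(hr[i]),
                resp_freq=float(resp[i]),
                rsa_amplitude=amp,
                lf_amplitude=cfg.lf_amplitude,
                noise_sd_ms=cfg.noise_sd_ms,
                duration_s=cfg.duration_s,
                pulse_rate_hz=cfg.pulse_rate_hz,
                seed=subject_seeds[i],
            )
            ibis = simulate_beats(sub_cfg)
            pulse = render_pulse_waveform(
                ibis, pulse_rate_hz=cfg.pulse_rate_hz, duration_s=cfg.duration_s
            )
            breath = render_respiration(
                float(resp[i]),
                cfg.duration_s,
                sample_rate_hz=cfg.resp_sample_rate_hz,
                noise_sd=cfg.resp_noise_sd,
                seed=subject_seeds[i] ^ 0x5F5F5F,
            )
            records.append(
                SubjectRecords(subject_id=sid, true_ibis=ibis, pulse=pulse, respiration=breath)
            )
    return CohortSim(config=cfg, table=pd.DataFrame(rows), records=records)
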