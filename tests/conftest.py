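"""Shared fixtures.

The expensive Monte-Carlo campaigns (pulse round-trip recovery, posterior
credible-interval coverage, cohort-scale contrast replicates) are computed
once per session and shared between the module property tests and the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import cardioresp as cr
from cardioresp.bayes import SamplerConfig, fit_bayes_correlation, posterior_rho_contrast

#: Reduced sampler settings for bulk Monte-Carlo campaigns (hundreds of
#: fits). Single-fit tests use larger budgets where precision matters.
BULK_SAMPLER = dict(n_chains=3, n_iter=3000, n_burn=1000)


def bivariate_normal(rho: float, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Correlated standard-normal pairs via the Cholesky factor."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    return x, y


@pytest.fixture(scope="session")
def roundtrip_stats():
    """Full signal-path round trips for 20 seeded subjects.

    Each subject: IPFM beats -> pulse waveform -> trim -> upsample ->
    detect -> artifact flags, compared with metrics on the generator's true
    intervals over the same analysis window.
    """
    out = []
    for seed in range(20):
        cfg = cr.SubjectSimConfig(
            mean_hr=64.0,
            resp_freq=0.27,
            rsa_amplitude=0.05,
            lf_amplitude=0.02,
            noise_sd_ms=3.0,
            duration_s=420.0,
            seed=seed,
        )
        true = cr.simulate_beats(cfg)
        wf = cr.render_pulse_waveform(true)
        detected = cr.detect_beats(cr.upsample_waveform(cr.trim_record(wf)))
        flagged = cr.detect_artifacts(detected)

        t_true = true.beat_times_s[1:]
        window = (t_true >= 120.0) & (t_true <= 420.0)
        true_ibis = true.ibis_ms[window]
        true_rmssd = float(np.sqrt(np.mean(np.diff(true_ibis) ** 2)))
        true_hr = 60000.0 / float(np.mean(true_ibis))
        det_rmssd = cr.rmssd(detected)
        det_hr = detected.mean_hr_bpm
        out.append(
            dict(
                seed=seed,
                true_rmssd=true_rmssd,
                det_rmssd=det_rmssd,
                true_hr=true_hr,
                det_hr=det_hr,
                n_flags=int(flagged.artifact_flags.sum()),
            )
        )
    return out


@pytest.fixture(scope="session")
def coverage_run():
    """100 seeded replicates of the bivariate-t fit at n=55, true rho=-0.3.

    Returns per-replicate (ci_lo, ci_hi) of the 95% credible interval.
    """
    intervals = []
    for seed in range(100):
        x, y = bivariate_normal(-0.3, 55, seed=10_000 + seed)
        post = fit_bayes_correlation(
            x, y, sampler=SamplerConfig(seed=20_000 + seed, **BULK_SAMPLER)
        )
        intervals.append(post.rho_ci)
    return intervals


@pytest.fixture(scope="session")
def cohort_scale_fits():
    """50 seeded replicates at the study's group sizes and correlations.

    Each replicate draws a patients-like sample (n=55, rho=-0.29) and a
    controls-like sample (n=149, rho=-0.04) of latent (respiratory
    frequency, ln HF) pairs, fits both posteriors, and records the
    patient-group directional probability and the between-group contrast.
    """
    results = []
    for seed in range(50):
        xp, yp = bivariate_normal(-0.29, 55, seed=30_000 + seed)
        xc, yc = bivariate_normal(-0.04, 149, seed=40_000 + seed)
        post_p = fit_bayes_correlation(
            xp, yp, sampler=SamplerConfig(seed=50_000 + seed, **BULK_SAMPLER)
        )
        post_c = fit_bayes_correlation(
            xc, yc, sampler=SamplerConfig(seed=60_000 + seed, **BULK_SAMPLER)
        )
        contrast = posterior_rho_contrast(post_p, post_c, seed=70_000 + seed)
        results.append(
            dict(
                p_neg_patients=post_p.p_rho_lt_0,
                p_contrast=contrast.p_rho_a_lt_b,
                rho_patients=post_p.rho_mean,
                rho_controls=post_c.rho_mean,
            )
        )
    return results
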