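"""End-to-end orchestration: simulate -> process -> analyze -> report.

Each stage is a plain function over a validated :class:`RunConfig`, so the
numbered analysis scripts, the command-line interface and the tests all
drive exactly the same code. Stages communicate through files in the run
directory:

* ``simulate`` writes per-subject waveform CSVs, plain-text IBI files and a
  cohort manifest.
* ``process`` turns each subject's pulse waveform into artifact-corrected
  IBIs, spectral and time-domain HRV metrics and a respiratory peak
  frequency, writing one row per subject plus a per-subject QC JSON.
  Subjects whose records fail any processing step are quarantined (logged
  and skipped) rather than aborting the batch.
* ``analyze`` applies the respiratory band inclusion filter, fits the
  Bayesian bivariate-t correlation of each HRV metric against respiratory
  frequency per group, contrasts the group posteriors, and computes the
  Welch / Hedges group-comparison table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import bayes, groupstats, pulse, respiration, spectral, synthetic
from .records import IBISeries, WaveformRecord

__all__ = ["RunConfig", "run_simulate", "run_process", "run_analyze", "run_report"]

log = logging.getLogger("cardioresp")

#: HRV metrics correlated against respiratory peak frequency.
ANALYSIS_METRICS = ("ln_hf", "ln_rmssd", "mean_hr_bpm")


@dataclass(frozen=True)
class CohortSpec:
    """One group in the run configuration (subset of CohortSimConfig)."""

    group_label: str
    n_subjects: int
    mean_hr_mean: float
    mean_hr_sd: float
    ln_hf_mean: float
    ln_hf_sd: float
    target_rho: float
    resp_freq_mean: float = 0.29
    resp_freq_sd: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run.

    Defaults mirror the study conditions: two groups (55 patients-like,
    149 controls-like), 7-minute recordings trimmed to the final 5 minutes,
    1000 Hz upsampling, a 256 s Hann window at 4 Hz interpolation, and the
    0.15-0.4 Hz respiratory inclusion band.
    """

    out_dir: Path = Path("runs/default")
    seed: int = 0
    cohorts: tuple[CohortSpec, ...] = (
        CohortSpec("patients", 55, 71.3, 12.96, 6.18, 1.14, -0.29),
        CohortSpec("controls", 149, 64.31, 10.06, 6.65, 0.99, -0.04),
    )
    duration_s: float = 420.0
    drop_head_s: float = 120.0
    keep_s: float = 300.0
    upsample_rate_hz: float = 1000.0
    artifact_multiplier: float = pulse.DEFAULT_ARTIFACT_MULTIPLIER
    rejection_ceiling: float = pulse.DEFAULT_REJECTION_CEILING
    window_s: float = 256.0
    overlap: float = 0.5
    band: tuple[float, float] = spectral.HF_BAND
    n_chains: int = 3
    n_iter: int = 20000
    n_burn: int = 5000
    lf_amplitude: float = 0.03
    noise_sd_ms: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if not self.cohorts:
            raise ValueError("at least one cohort must be configured")
        for c in self.cohorts:
            if c.n_subjects < 1:
                raise ValueError(f"cohort {c.group_label!r}: n_subjects must be >= 1")
        if self.duration_s < self.drop_head_s + self.keep_s:
            raise ValueError(
                f"duration_s={self.duration_s} cannot cover drop_head_s + keep_s = "
                f"{self.drop_head_s + self.keep_s}"
            )
        if self.window_s > self.keep_s:
            raise ValueError("window_s must not exceed keep_s")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < lo < hi")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohorts = d.pop("cohorts", None)
        if cohorts is not None:
            d["cohorts"] = tuple(CohortSpec(**c) for c in cohorts)
        if "band" in d:
            d["band"] = tuple(d["band"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def sim_dir(self) -> Path:
        return self.out_dir / "simulated"

    @property
    def manifest_path(self) -> Path:
        return self.sim_dir / "manifest.csv"

    @property
    def cohort_csv(self) -> Path:
        return self.out_dir / "cohort.csv"

    @property
    def report_json(self) -> Path:
        return self.out_dir / "report.json"


def _sampler_cfg(config: RunConfig, seed: int) -> bayes.SamplerConfig:
    return bayes.SamplerConfig(
        n_chains=config.n_chains, n_iter=config.n_iter, n_burn=config.n_burn, seed=seed
    )


def run_simulate(config: RunConfig) -> pd.DataFrame:
    """Generate and write the synthetic cohort files; returns the manifest."""
    config.sim_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    rows = []
    for spec, ss in zip(config.cohorts, root.spawn(len(config.cohorts))):
        cohort_seed = int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        sim_cfg = synthetic.CohortSimConfig(
            n_subjects=spec.n_subjects,
            group_label=spec.group_label,
            resp_freq_mean=spec.resp_freq_mean,
            resp_freq_sd=spec.resp_freq_sd,
            mean_hr_mean=spec.mean_hr_mean,
            mean_hr_sd=spec.mean_hr_sd,
            ln_hf_mean=spec.ln_hf_mean,
            ln_hf_sd=spec.ln_hf_sd,
            target_rho=spec.target_rho,
            seed=cohort_seed,
            duration_s=config.duration_s,
            lf_amplitude=config.lf_amplitude,
            noise_sd_ms=config.noise_sd_ms,
        )
        sim = synthetic.simulate_cohort(sim_cfg, render=True)
        for rec, (_, row) in zip(sim.records, sim.table.iterrows()):
            sid = rec.subject_id
            pulse_path = config.sim_dir / f"{sid}_pulse.csv"
            resp_path = config.sim_dir / f"{sid}_resp.csv"
            ibi_path = config.sim_dir / f"{sid}_true_ibis.txt"
            rec.pulse.to_csv(pulse_path)
            rec.respiration.to_csv(resp_path)
            rec.true_ibis.to_text(ibi_path)
            rows.append(
                {
                    **row.to_dict(),
                    "pulse_path": str(pulse_path),
                    "resp_path": str(resp_path),
                    "ibi_path": str(ibi_path),
                }
            )
        log.info("simulated %d subjects for group %s", spec.n_subjects, spec.group_label)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(config.manifest_path, index=False)
    return manifest


def process_subject(
    pulse_record: WaveformRecord, resp_record: WaveformRecord, config: RunConfig
) -> tuple[spectral.HRVSummary, IBISeries, respiration.RespirationResult]:
    """Run the full per-subject signal chain and return its metrics."""
    trimmed = pulse.trim_record(pulse_record, config.drop_head_s, config.keep_s)
    up = pulse.upsample_waveform(trimmed, config.upsample_rate_hz)
    ibis = pulse.detect_beats(up)
    ibis = pulse.detect_artifacts(ibis, multiplier=config.artifact_multiplier)
    ibis = pulse.correct_artifacts(ibis, rejection_ceiling=config.rejection_ceiling)
    tach = spectral.resample_tachogram(ibis)
    tach = spectral.detrend_least_squares(tach)
    psd = spectral.welch_psd(tach, window_s=config.window_s, overlap=config.overlap)
    resp_trimmed = pulse.trim_record(resp_record, config.drop_head_s, config.keep_s)
    resp_result = respiration.respiratory_peak(resp_trimmed)
    summary = spectral.summarize(
        ibis, psd, resp_peak_hz=resp_result.peak_freq_hz, included=resp_result.in_band
    )
    return summary, ibis, resp_result


def run_process(config: RunConfig) -> pd.DataFrame:
    """Process every subject in the manifest into the cohort metrics table.

    Per-subject failures are quarantined: the error is logged and written to
    ``quarantine.json`` and the run continues with the remaining subjects.
    """
    if not config.manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {config.manifest_path}; run simulate first")
    manifest = pd.read_csv(config.manifest_path)
    qc_dir = config.out_dir / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    quarantined: dict[str, str] = {}
    for _, m in manifest.iterrows():
        sid = m["subject_id"]
        try:
            pulse_record = WaveformRecord.from_csv(m["pulse_path"])
            resp_record = WaveformRecord.from_csv(m["resp_path"])
            summary, ibis, resp_result = process_subject(pulse_record, resp_record, config)
        except Exception as exc:  # noqa: BLE001 - quarantine-and-continue policy
            log.warning("subject %s quarantined: %s", sid, exc)
            quarantined[str(sid)] = str(exc)
            continue
        with open(qc_dir / f"{sid}.json", "w") as fh:
            json.dump(pulse.qc_summary(ibis), fh, indent=2)
        rows.append(
            {
                "subject_id": sid,
                "group": m["group"],
                "ln_hf": summary.ln_hf,
                "hf_ms2": summary.hf_ms2,
                "ln_rmssd": summary.ln_rmssd,
                "rmssd_ms": summary.rmssd_ms,
                "mean_hr_bpm": summary.mean_hr_bpm,
                "resp_peak_hz": summary.resp_peak_hz,
                "included": summary.included,
            }
        )
    with open(config.out_dir / "quarantine.json", "w") as fh:
        json.dump(quarantined, fh, indent=2)
    cohort = pd.DataFrame(rows)
    cohort.to_csv(config.cohort_csv, index=False)
    log.info("processed %d subjects (%d quarantined)", len(rows), len(quarantined))
    return cohort


def _posterior_summary(post: bayes.CorrelationPosterior) -> dict:
    return {
        "rho_mean": post.rho_mean,
        "rho_ci_95": list(post.rho_ci),
        "p_rho_lt_0": post.p_rho_lt_0,
        "p_rho_gt_0": post.p_rho_gt_0,
        "rhat": post.rhat_rho,
        "ess": post.ess_rho,
        "warnings": list(post.warnings),
    }


def run_analyze(config: RunConfig, cohort: Optional[pd.DataFrame] = None) -> dict:
    """Correlations, posterior contrasts and group comparisons; writes JSON.

    Requires at least 4 included subjects per group. The report contains,
    per group, the Bayesian (bivariate-t) and frequentist Pearson
    correlation of each HRV metric against respiratory peak frequency; a
    between-group posterior contrast per metric; and the Welch t / Hedges g
    table over the continuous variables.
    """
    if cohort is None:
        if not config.cohort_csv.exists():
            raise FileNotFoundError(f"cohort table not found: {config.cohort_csv}")
        cohort = pd.read_csv(config.cohort_csv)
    cohort = respiration.apply_inclusion_filter(cohort)
    included = cohort[cohort["included"]]
    groups = [c.group_label for c in config.cohorts if c.group_label in set(cohort["group"])]
    report: dict = {
        "seed": config.seed,
        "n_total": int(len(cohort)),
        "n_included": int(len(included)),
        "exclusions": {
            g: int(((cohort["group"] == g) & ~cohort["included"]).sum()) for g in groups
        },
        "groups": {},
        "contrasts": {},
        "group_comparisons": {},
    }

    fits: dict[tuple[str, str], bayes.CorrelationPosterior] = {}
    seed_root = np.random.SeedSequence([config.seed, 0xC0FFEE])
    fit_seeds = iter(seed_root.generate_state(4 * len(groups) * len(ANALYSIS_METRICS)))
    for g in groups:
        sub = included[included["group"] == g]
        if len(sub) < 4:
            raise ValueError(f"group {g!r} has only {len(sub)} included subjects (need >= 4)")
        entry: dict = {"n_included": int(len(sub)), "correlations": {}}
        for metric in ANALYSIS_METRICS:
            x = sub["resp_peak_hz"].to_numpy(float)
            y = sub[metric].to_numpy(float)
            seed = int(next(fit_seeds) & 0x7FFFFFFF)
            post = bayes.fit_bayes_correlation(x, y, sampler=_sampler_cfg(config, seed))
            fits[(g, metric)] = post
            r, p, lo, hi = bayes.pearson_with_fisher_ci(x, y)
            entry["correlations"][metric] = {
                "bayes": _posterior_summary(post),
                "frequentist": {"r": r, "p": p, "ci_95": [lo, hi]},
            }
        report["groups"][g] = entry

    if len(groups) >= 2:
        ga, gb = groups[0], groups[1]
        for metric in ANALYSIS_METRICS:
            seed = int(next(fit_seeds) & 0x7FFFFFFF)
            contrast = bayes.posterior_rho_contrast(
                fits[(ga, metric)], fits[(gb, metric)], seed=seed
            )
            report["contrasts"][metric] = {
                "groups": [ga, gb],
                "p_rho_a_lt_b": contrast.p_rho_a_lt_b,
                "delta_mean": contrast.delta_mean,
                "delta_ci_95": list(contrast.delta_ci),
            }
        for var in ANALYSIS_METRICS + ("resp_peak_hz",):
            a = included[included["group"] == ga][var].to_numpy(float)
            b = included[included["group"] == gb][var].to_numpy(float)
            cmp_ = groupstats.welch_t(b, a)  # convention: (reference=controls-like, comparison)
            g_val, g_ci = groupstats.hedges_g(b, a)
            report["group_comparisons"][var] = {
                "reference": gb,
                "comparison": ga,
                "t": cmp_.t,
                "df": cmp_.df,
                "p": cmp_.p,
                "hedges_g": g_val,
                "g_ci_95": list(g_ci),
            }

    config.out_dir.mkdir(parents=True, exist_ok=True)
    with open(config.report_json, "w") as fh:
        json.dump(report, fh, indent=2)
    _write_report_tables(config, report)
    return report


def _write_report_tables(config: RunConfig, report: dict) -> None:
    """Flatten the JSON report into human-readable CSV tables."""
    corr_rows = []
    for g, entry in report["groups"].items():
        for metric, res in entry["correlations"].items():
            corr_rows.append(
                {
                    "group": g,
                    "n": entry["n_included"],
                    "metric": metric,
                    "pearson_r": res["frequentist"]["r"],
                    "pearson_p": res["frequentist"]["p"],
                    "ci_lo": res["frequentist"]["ci_95"][0],
                    "ci_hi": res["frequentist"]["ci_95"][1],
                    "bayes_rho_mean": res["bayes"]["rho_mean"],
                    "bayes_ci_lo": res["bayes"]["rho_ci_95"][0],
                    "bayes_ci_hi": res["bayes"]["rho_ci_95"][1],
                    "p_rho_lt_0": res["bayes"]["p_rho_lt_0"],
                }
            )
    pd.DataFrame(corr_rows).to_csv(config.out_dir / "correlations.csv", index=False)
    if report["group_comparisons"]:
        pd.DataFrame(
            [{"variable": k, **v} for k, v in report["group_comparisons"].items()]
        ).to_csv(config.out_dir / "group_comparisons.csv", index=False)


def run_report(config: RunConfig) -> str:
    """Render a plain-text summary of an existing analysis report."""
    if not config.report_json.exists():
        raise FileNotFoundError(f"no report at {config.report_json}; run analyze first")
    with open(config.report_json) as fh:
        report = json.load(fh)
    lines = [
        f"cardioresp run (seed {report['seed']}): "
        f"{report['n_included']}/{report['n_total']} subjects included",
    ]
    for g, entry in report["groups"].items():
        lines.append(f"\ngroup {g} (n={entry['n_included']}):")
        for metric, res in entry["correlations"].items():
            b = res["bayes"]
            f = res["frequentist"]
            lines.append(
                f"  {metric} ~ resp_peak_hz: rho = {b['rho_mean']:+.2f} "
                f"95% CI ({b['rho_ci_95'][0]:+.2f}, {b['rho_ci_95'][1]:+.2f}), "
                f"P(rho<0) = {100 * b['p_rho_lt_0']:.1f}%; "
                f"Pearson r = {f['r']:+.2f} (p = {f['p']:.3f})"
            )
    for metric, c in report.get("contrasts", {}).items():
        lines.append(
            f"\ncontrast {metric}: P(rho_{c['groups'][0]} < rho_{c['groups'][1]}) = "
            f"{100 * c['p_rho_a_lt_b']:.1f}%"
        )
    text = "\n".join(lines)
    print(text)
    return text
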