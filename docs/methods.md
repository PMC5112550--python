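# Methods

`cardioresp` implements a complete chain from raw cardiorespiratory signals
to a between-group difference-in-correlation statement: pulse waveform →
interbeat intervals (IBIs) → artifact-corrected tachogram → spectral
high-frequency heart-rate variability (HF-HRV), RMSSD and mean heart rate;
respiration trace → peak breathing frequency → band-inclusion filter; and a
robust Bayesian correlation of each HRV metric against breathing frequency,
compared across groups through the posterior difference of correlation
coefficients. Because the patient recordings the design is modelled on are
not distributable, the package ships a synthetic cohort generator whose
defaults reproduce the relevant population statistics, and all claims the
test suite makes are parameter-recovery and calibration claims on that
synthetic population.

## Synthetic cardiorespiratory cohorts

### Beat generation (IPFM)

Heart beats come from an integral pulse frequency modulation model: with
mean heart period `T` (s) and modulation

    m(t) = 1 + a_r sin(2π f_resp t) + a_l sin(2π f_lf t + φ),

beats fire at the times where `∫₀ᵗ m(s) ds / T` crosses successive
integers. The respiratory term injects respiratory sinus arrhythmia (RSA)
at the subject's breathing frequency `f_resp`; the low-frequency term
(default `f_lf` = 0.1 Hz, the baroreflex band) adds realistic out-of-band
variability. White Gaussian noise (default SD 3 ms) is added to the
intervals afterwards, emulating measurement jitter.

**Amplitude convention.** `rsa_amplitude` is defined in the IBI domain: a
depth `A` means the interbeat intervals oscillate with amplitude `A·T` ms.
Because a beat interval integrates the rate over one period, a rate-domain
sinusoid is attenuated by `sinc(f·T)` (≈ 0.90 at 0.25 Hz, 60 bpm) by the
time it appears in the intervals; the generator pre-compensates the
rate-domain amplitude by `1/sinc(f·T)` so the configured depth is the
realized one. This makes the closed-form oracle exact: a depth-`A` subject
carries HF power `(A·T·1000)²/2` ms², which the spectral stage recovers
within a few percent (the residual being Hann-window and interpolation
loss). The cohort generator inverts the same identity to choose a depth for
each subject from their target ln HF value.

### Cohort structure

Per subject, `(f_resp, ln HF)` is drawn from a bivariate Gaussian with a
configurable correlation `target_rho`, jointly truncated so `f_resp` stays
in (0.10, 0.45) Hz; the truncation deliberately leaves a small fraction of
subjects (≈ 1.7% at the default mean 0.29 Hz, SD 0.05 Hz) breathing outside
the 0.15–0.4 Hz inclusion band so the exclusion filter is exercised. Mean
heart rate is an independent Gaussian. Group defaults mirror the study
population: patients-like n = 55, heart rate 71.3 (12.96) bpm, ln HF
6.18 (1.14), ρ = −0.29; controls-like n = 149, 64.31 (10.06) bpm, ln HF
6.65 (0.99), ρ = −0.04; respiratory frequency 0.29 (0.05) Hz in both.
Treating ln HF as Gaussian within group is an assumption — only the mean
and SD of the log are constrained by the published summaries.

All randomness fans out deterministically from one cohort seed via
`numpy.random.SeedSequence` spawning, so identical configurations yield
bitwise-identical cohorts.

### What the generator does not emulate

No pulse-waveform morphology beyond a Gaussian bump per beat (no dicrotic
notch, no amplitude variability), no baseline drift by default, no
respiratory depth or tidal-volume structure, no arrhythmias or ectopic
beats, and no coupling between mean heart rate and HF beyond what the
configured marginals imply. Passing round-trip tests therefore show the
processing chain is internally correct and well calibrated, not that it
would be robust to every failure mode of real photoplethysmography.

## Signal processing

* **Trim:** drop the first 120 s (habituation), keep the following 300 s.
* **Upsampling:** cubic-spline interpolation of the 50 Hz pulse signal onto
  a 1000 Hz grid before peak picking, so peak times are not quantised to
  20 ms.
* **Beat detection:** local maxima with a 250 ms refractory period (a
  240 bpm physiological ceiling) and a prominence threshold of 0.3 of the
  signal's amplitude span; sub-sample refinement by parabolic interpolation
  through the peak and its neighbours.
* **Artifact detection:** an IBI is flagged when it differs from *both*
  neighbours by more than `multiplier ×` the quartile deviation (IQR/2) of
  the successive-difference distribution. The published description of this
  step names a quartile-based successive-difference criterion but not its
  constants; ours is an approximation in that spirit with the multiplier
  exposed (default 6.0, at which clean synthetic records produce zero false
  flags across seeds — roughly the `max/σ` of ~300 Gaussian differences).
  Requiring deviation from both neighbours keeps an isolated missed beat
  (doubled interval) from dragging its healthy successor into the flag set.
* **Artifact correction:** flagged intervals are replaced by a cubic spline
  fitted to the unflagged intervals *as a function of beat index* (the
  simplest faithful reading of interval-domain spline replacement); beat
  times are rebuilt by cumulative summation. Records with more than 20% of
  intervals flagged are rejected rather than patched. Where the study
  visually inspected flagged beats, the pipeline substitutes this
  configurable ceiling plus a per-record QC JSON.
* **Tachogram:** cubic-spline interpolation of interval-versus-beat-time
  onto a uniform 4 Hz grid, restricted to the interior of the beat span;
  least-squares linear detrend.
* **Spectrum:** Hann-windowed Welch periodogram, 256 s window, 50% overlap,
  density scaling with window-power compensation so the integral of the PSD
  recovers the signal variance (Parseval within windowing loss, ≤ 15%).
  A 300 s record fits only one complete 256 s window; in that case a single
  windowed periodogram is returned and reported as `n_segments = 1`, rather
  than zero-padding a second segment.
* **HF power:** trapezoidal integral over 0.15–0.4 Hz, bins whose centre
  lies in the closed band.
* **Transforms:** natural logarithms of HF power and RMSSD. Natural rather
  than base-10 log is forced by magnitude consistency: ln(772 ms²) ≈ 6.65
  matches the published group-mean scale, log₁₀ would give ≈ 2.9.
* **Respiratory peak:** linear detrend, Hann window, FFT magnitude, argmax
  over the full spectrum up to Nyquist (not band-restricted — out-of-band
  breathers must be seen to be excluded), then a closed-interval
  [0.15, 0.4] Hz inclusion test. Closed endpoints mirror the band's own
  definition; a peak exactly at 0.15 or 0.4 Hz is included.

## Robust Bayesian correlation

The correlation model is a bivariate Student-t likelihood over paired
observations with parameters (ρ, μ₁, μ₂, σ₁, σ₂, ν): scale matrix
`[[σ₁², ρσ₁σ₂], [ρσ₁σ₂, σ₂²]]`, degrees of freedom ν learned from the
data. Small ν fattens the tails and down-weights outlying pairs, so the
posterior for ρ is markedly less sensitive to gross outliers than the
frequentist Pearson r (verified: two gross outliers in an n = 55, ρ = 0.5
sample displace the posterior mean by less than half the displacement
of r).

Priors (all configurable): ρ ~ Uniform(−1, 1); μⱼ ~ Normal(sample mean,
(1000 × sample SD)²); σⱼ ~ Uniform(sample SD/1000, 1000 × sample SD);
ν − 1 ~ Exponential(mean 29). This is the standard weakly-informative
setup for robust correlation estimation.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs on the
unconstrained coordinates (atanh ρ, μ₁, μ₂, log σ₁, log σ₂, log(ν−1)),
with the uniform/exponential priors carried through the transforms by their
Jacobians. Step sizes adapt toward 0.44 acceptance in batches of 50 during
burn-in and are frozen afterwards (preserving detailed balance for the
retained draws). Default budget: 3 chains × 20 000 iterations, 5 000
burn-in, ~45 000 pooled draws. Diagnostics: split-chain R̂ (warning above
1.05, attached to the result) and a Geyer initial-positive-sequence
effective sample size for ρ. Identical data and seed give bitwise-identical
results; chains run in lockstep as vectorised numpy, so a study-sized fit
takes seconds.

**Summaries.** Posterior mean of ρ, central (equal-tailed) 95% credible
interval, and the directional probabilities P(ρ<0), P(ρ>0) as draw
fractions.

**Group contrast.** The two group posteriors are independent, so the
contrast pairs their pooled ρ draws by index after an independent shuffle
of each (subsampling the larger pool to the smaller) and reports the
fraction of pairs with ρ_A − ρ_B < 0 — the probability that the correlation
is more negative in group A.

## Frequentist statistics

Welch's t with Welch–Satterthwaite degrees of freedom, from raw samples or
(n, mean, SD) summaries interchangeably; Hedges' g = Cohen's d (pooled SD)
× (1 − 3/(4N − 9)) with a noncentral-t confidence interval (mirrored for
negative effects so the interval is exactly antisymmetric in group order;
normal approximation as fallback for extreme inputs); Pearson r with a
Fisher-z interval `tanh(atanh r ± z₀.₉₇₅/√(n−3))`; Pearson chi-squared for
2×2 tables without continuity correction by default (the published gender
test's counts are not recoverable, so the correction flag is exposed and
undecided by data). Sign convention throughout: (reference, comparison)
order, statistics carry the sign of comparison − reference.

## Calibration results the suite enforces

* Unmodulated IPFM at 60 bpm over 300 s yields exactly 300 intervals of
  1000 ms; beat count within ±2 of `duration × HR/60` generally.
* HF power of a depth-0.05 modulation at 60 bpm lands within 10% of the
  1250 ms² closed form (measured ≈ 1211 ms², −3%).
* Full pulse round trip (render → trim → upsample → detect) recovers RMSSD
  within 5% (measured ≤ 0.3%) and mean HR within 0.5 bpm (measured
  ≤ 0.03 bpm) across 20 seeded subjects, with zero artifact false flags.
* 95% credible intervals cover a true ρ = −0.3 in 90–99 of 100 replicates
  at n = 55 (measured 97).
* Self-contrast of two refits of the same data ≈ 0.5; contrast of
  well-separated posteriors (ρ = ∓0.6, n = 200) > 0.999.
* Cohorts simulated at the study's sizes and correlations (n = 55 at
  ρ = −0.29 vs n = 149 at ρ = −0.04, 50 replicates) give a median contrast
  probability of ≈ 0.92, inside the (0.80, 0.99) design bracket, and a
  median within-patients P(ρ<0) ≈ 0.97.

## Problem sizes and budgets

Single fits use the full 3 × 20 000 sampler budget. The Monte-Carlo
campaigns (interval coverage, 50-replicate cohort calibration) use a
reduced 3 × 3 000 budget (1 000 burn-in, ~9 000 pooled draws per fit),
chosen as the package's own trade-off between quantile precision (draw
noise on a 95% interval endpoint is ~0.01 at that size) and wall-clock
time; the calibration conclusions are insensitive to raising it. Round-trip
campaigns use 20 seeded 7-minute subjects; latent-structure checks use
n = 5 000 cohorts.

## Known limitations

* The artifact criterion approximates a published-by-citation algorithm
  whose exact constants are unavailable; agreement with the original
  toolchain is not claimed, and the Welch normalisation is declared
  (Parseval-checked) rather than claimed identical to any particular HRV
  package.
* The generator's stationarity (fixed breathing rate and modulation depth
  per subject) is idealised; real recordings drift.
* The published HF-HRV and BMI group rows are not exactly reproducible from
  their own printed summaries (recomputing the HF-HRV row's t from its
  printed means/SDs/ns gives ≈ −2.70 against a printed −2.11, most likely a
  typographical inconsistency); those cells are not targeted anywhere.
* The bivariate-t model assumes elliptical joint structure; it robustifies
  against outliers, not against nonlinear dependence.
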