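# Methods

This note documents the models implemented by `prosocial_effort`, the
assumptions behind the synthetic-data generator, the numerical choices,
and the limits of what the test suite can establish.

## The scientific setting

The package models a two-task paradigm for studying how physical effort
shapes the neural evaluation of rewards earned for oneself versus an
anonymous other person.

In the **effort task**, a participant exerts one of five calibrated
effort levels (10/30/50/70/90% of their maximum button-press count) to
earn one of five reward magnitudes (¥0.2–¥1.0), half the trials for
themselves and half for another person; successful effort is followed by
reward feedback (gain vs nongain, equiprobable). EEG epochs locked to
reward feedback yield the single-trial reward positivity (RewP, mean
voltage 300–400 ms over FC3/FCz/FC4); epochs locked to effort-completion
feedback yield the parietal P3 (300–440 ms over P3/Pz/P4).

In the **decision task**, the participant chooses between a no-effort
baseline (¥0.1) and a high-effort option drawn from the same 5×5
effort × magnitude grid, again for self or other. Choices identify each
participant's effort-discounting profile.

## Parabolic effort discounting

The high-effort option's subjective value is

    SV = R − K·E²

with reward `R` in yuan and a beneficiary-specific discount rate
(`K_self`, `K_other`). Choice follows a two-option softmax with inverse
temperature β:

    P(high) = exp(β·SV_high) / (exp(β·SV_high) + exp(β·SV_base))

implemented as a logistic of `β·(SV_high − SV_base)`, which is
overflow-safe. The per-participant likelihood is the Bernoulli product
over choice trials (catch and no-response trials excluded), maximized
jointly over `(K_self, K_other, log β)` by L-BFGS-B with 20 seeded
restarts, bounds `K ∈ [−1, 2]` and `log β ∈ [−4, 4]`.

Open choices and their resolutions:

* **Effort units.** The quadratic's units are not fixed by the model
  statement. The default codes effort as the level index `E ∈ {1..5}`:
  with group-typical discounting (`logK` around −4.5 to −3.8),
  `K·E²` then spans ≈ ¥0.01–0.3, commensurate with the ¥0.1–1.0 rewards.
  Proportion (0.1–0.9) or percent (10–90) coding would make the maximum
  discount either negligible (~¥0.01) or larger than any reward. The
  coding is configurable and always recorded in the fit.
* **β across beneficiaries.** β is participant-specific and shared
  across self/other conditions; the two conditions differ only in K.
* **Negative K.** A small minority of people show effort *adding* value
  (negative K). Fits are unconstrained in sign; since `logK = ln K` is
  undefined for `K ≤ 0`, such participants are excluded from logK-based
  group statistics (paired t-test of `logK_other − logK_self`, Pearson
  correlation of the two logKs) and the exclusion count is reported.
* **Identifiability.** With β near zero, K is weakly identified. The fit
  records the spread of each parameter across near-optimal restarts;
  a wide spread flags a poorly identified K rather than letting a single
  start masquerade as a precise estimate.

## Single-trial ERP quantification

Epochs are −200…1000 ms at 512 Hz. Processing starts from epochs —
filtering, re-referencing, interpolation and ICA belong to the upstream
recording pipeline and are out of scope here.

1. **Baseline**: the prestimulus mean (t < 0) is subtracted per
   trial/channel (idempotent).
2. **Artifact screening**, per trial over all channels, four rules:
   sample-to-sample step > 50 µV; within-trial range > 200 µV;
   a 100 ms window with range < 0.5 µV (flatline); and a slow drift.
   Two operationalizations needed pinning down:
   * the drift criterion carries no time denominator in common usage; we
     use |least-squares slope × epoch duration| > 100 µV, i.e. net drift
     across the epoch;
   * the flatline scan uses 100 ms windows with 50% overlap.
   A trial is rejected if any rule fires on any channel; per-rule counts
   are reported. Loosening a step/range/drift threshold can only shrink
   the rejected set; tightening the flatline threshold likewise.
3. **Component measurement**: channels of the cluster are averaged, then
   samples in the window averaged; windows are half-open `[start, stop)`
   in sample time so endpoint samples are never double-counted. The two
   means commute, and measurement is linear in the data.

## Mixed-effects analysis layer

Following standard practice for this design, binary factors are contrast
coded (recipient −0.5 self / +0.5 other; valence −0.5 gain / +0.5
nongain) and continuous predictors (effort, magnitude) z-scored within
participant (sample SD, n−1). The quadratic effort term used in the
decision-time model is the square of the z-scored effort, re-centered
within participant (not orthogonalized against the linear term — the two
are nearly orthogonal by construction in a balanced design).

The RewP model is
`amplitude ~ recipient * effort * magnitude * valence` with by-participant
random intercept and recipient/effort/magnitude slopes. Fitting is
delegated to established engines behind one surface:

* Gaussian models: statsmodels `MixedLM` (REML). p-values use the Wald-z
  reference by default. Satterthwaite degrees of freedom are available
  through an optional lme4/lmerTest backend driven via `Rscript`; with
  40 participants and ~8000 trials the two references agree to the
  printed precision (the backends also agree on estimates to ~1e-13,
  which the test suite uses as a cross-check).
* Binomial models (response success, choice): lme4 `glmer` via the same
  R bridge, Wald-z tests. The package default random structure for
  binomial models is intercept + effort slope, the term those inferences
  hinge on; Gaussian models default to the maximal stated structure.

**Random-structure simplification.** When a fit is singular or fails to
converge, the structure is reduced one step at a time: slope
correlations are dropped first (correlated → independent variance
components), then the slope with the smallest estimated variance, with
the by-participant intercept always retained. Every step is logged on
the result object. This smallest-variance-first policy is a documented
stand-in for rePCA-style SVD simplification, which requires access to
the fitted random-effect rotation and yields the same endpoint in the
balanced designs used here.

**Simple slopes.** The conditional effect of a focal predictor at fixed
moderator settings (±1 SD for continuous moderators, the two coded
levels for factors) is the linear combination of all fixed-effect terms
containing the focal predictor, weighted by the product of the moderator
settings of each term's remaining components; unlisted components sit at
their center (zero) and drop out. The SE is the quadratic form with the
fixed-effect covariance; the reference is normal (Wald). This equals the
coefficient obtained by refitting with shifted moderators — the suite
verifies that identity to 1e-6 relative tolerance on 50 random datasets.

**Cross-task moderation.** Each participant's discounting (mean of
`logK_self` and `logK_other`, z-scored across participants — the two are
substantially correlated, supporting a single domain-general moderator)
augments the RewP model:
`amplitude ~ recipient * effort * magnitude * logK_z + valence`.
Valence enters as a main effect only; its interactions with the
moderator are not of interest and omitting them keeps the augmented
model estimable at n = 40. The four-way interaction is decomposed into
effort simple slopes at recipient × (magnitude ±1 SD) × (logK ±1 SD).
A robustness variant replaces logK with the participant's overall
high-effort choice proportion. Participants without a defined logK
(negative K) are dropped from the moderation; an error is raised if more
than 20% are missing.

**Covariate control.** The RewP model is refitted with trial-level
response speed or subjective effort ratings (z-scored within
participant) added as a fixed effect, and the report states whether the
recipient × effort and recipient × effort × magnitude terms retain sign
and significance.

## The synthetic-data generator

The generator exists so that every stage is testable without any data
download; its defaults encode the study conditions: 40 participants, 200
effort-task trials and 150 decision trials (plus 20 catch trials) each.

* **Population.** `logK_self` and `logK_other` are bivariate normal
  (means −4.48 and −3.78, SD 0.8, correlation 0.52); β is lognormal
  (meanlog 1.6, sdlog 0.3). With probability 0.05 a participant's K in
  one condition is flipped to a small negative value, emulating the rare
  anti-discounting individuals. Maximum press count is normal
  (36.06 ± 4.95).
* **RewP.** Single-trial amplitude = fixed loadings × coded predictors
  + participant random effects + Gaussian residual (3 µV). Default
  loadings are the published estimates for this paradigm — recipient
  −0.68, valence −1.08, magnitude +0.42, recipient×effort −0.55,
  recipient×effort×magnitude −0.49, recipient×magnitude×valence +0.86 µV
  — used as simulator defaults, not as ground-truth claims; all are
  overridable. No variance components are published for this paradigm,
  so the random-effect SDs (intercept 2.0; recipient 0.5; effort and
  magnitude 0.3 µV) are free parameters chosen to be of the order seen
  in single-trial ERP regression work, documented here rather than
  asserted as fact.
* **P3.** Intercept 6 µV + 0.72 µV per SD of prior effort + residual.
* **Behavior.** Success follows a logistic declining steeply in effort,
  calibrated so marginal success lands near 96–97%; press speed is
  linear in effort (+0.56/SD), faster for self (recipient coefficient
  −0.07); decision times are lognormal around a linear predictor with
  linear + quadratic effort terms, magnitude facilitation, and their
  recipient/magnitude interactions; ratings come from a clipped linear
  latent model with the configured signs (difficulty and invested effort
  rising with effort, liking falling, other-beneficiary effects on
  effort and liking).
* **EEG.** Each trial's epoch is band-limited Gaussian sensor noise
  (10 µV, smoothed to emulate a ~35 Hz recording bandwidth — broadband
  white noise at 512 Hz would trip the 50 µV sample-to-sample rule on
  nearly every clean trial) plus the trial's RewP amplitude times a
  Gaussian temporal kernel (peak 350 ms, SD 35 ms, frontocentral
  cluster) and its P3 amplitude times a parietal kernel (peak 370 ms,
  SD 50 ms). Kernels are zero before feedback onset and normalized so
  the measurement-window mean recovers the amplitude parameter exactly.
  Artifacts (single-sample steps, channel flatlines, slow drifts) are
  injected at a configurable per-trial rate, default 2.5%, chosen to
  land retention in the high-90s range typical of epoch screening.
* **Failed trials.** A failed effort trial skips reward feedback in the
  real task. The generator still renders a reward-locked epoch for such
  trials (keeping the epoch array rectangular and trial-aligned) and the
  analysis layer excludes failed trials, mirroring the real exclusion.

Model-level simulations (sign recovery, power) generate single-trial
amplitudes directly from the generative linear model plus the analytic
window-noise floor of the epoch route (the SD of a cluster/window mean
of the band-limited noise, including the baseline-subtraction term).
This is exactly the quantity the epoch route measures, minus the cost of
rendering dense arrays; the epoch route itself is exercised end-to-end
at smaller scale in its own tests and in the acceptance script.

What the generator does **not** emulate: ocular/muscle artifacts and
line noise (the artifact kinds injected are the ones the screening rules
are defined over), realistic scalp topography beyond the two named
clusters, autocorrelated behavior (fatigue, learning), or any departure
from the fitted linear generative forms. Passing tests therefore show
that the pipeline recovers what this generative family encodes — not
that real EEG obeys it.

## Sensitivity analysis

Power for a fixed-effect term at a candidate effect size is estimated by
simulation: the term's generative loading is set to the candidate value
(all else at configured values), datasets are simulated and refitted,
and power is the fraction of converged fits with p < α. Refits reuse the
random-effects structure that converged on a template fit of the
configured generator — fitting a structure smaller than the generative
one would inflate the type-I rate and bias the curve. Every estimate
carries a Clopper–Pearson binomial CI, and estimates with more than 20%
non-convergent fits are flagged. The minimum detectable effect bisects
the effect magnitude until estimated power crosses 80% (α = 0.05),
to a default resolution of 5% of the initial bracket; defaults are 200
simulations per grid point.

## Numerical and engineering choices

* All randomness flows from explicit seeds; one master seed fixes every
  byte of a simulated dataset (per-participant generators are spawned
  from a `SeedSequence`).
* The likelihood uses `log_expit` for both choice outcomes; NLL is
  order-invariant and trials with model probability 1 contribute zero.
* MixedLM optimization tries lbfgs, then bfgs/powell/Nelder–Mead if an
  optimizer step fails or produces non-finite/absurd standard errors;
  singularity is declared when any random-effect variance (or eigenvalue
  of the slope covariance) falls below 1e-6 of the dominant variance
  scale.
* Epoch files are float32 little-endian with a JSON header; trial tables
  and all analysis outputs are CSV with a provenance comment line
  (package version, config hash, master seed).

## Known limitations

* Satterthwaite df require the R bridge; the pure-Python path reports
  Wald-z p-values, which are mildly anticonservative for small numbers
  of participants.
* The binomial GLMM path depends on an R installation with lme4; there
  is no pure-Python frequentist GLMM fallback.
* Simple-slope p-values always use the normal reference, including under
  the lme4 backend.
* The smallest-variance simplification policy can differ from rePCA on
  strongly unbalanced data (not the case in these designs).
* Power simulation sizes (200 sims/point) give ±3–7 percentage-point
  CIs near 80% power; the MDE inherits that resolution.
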