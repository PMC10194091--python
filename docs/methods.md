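# Methods

This note records the modeling assumptions, default parameter values,
numerical choices, and limitations of the package.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task model

A session consists of balloon trials in three color conditions with pump
caps 8 / 32 / 128 (30 trials each, 90 total, by default) and one coin per
successful pump.  The burst point of each balloon is drawn uniformly on the
integers `[1, max_pumps]` — the classic convention, which makes the expected
per-pump hazard condition-dependent; a constant-hazard alternative
(`1/max_pumps` per pump) sits behind the same `explosion_rule` field.
Explosion points are drawn independently per trial (not without replacement
from an array).  Practice trials can be simulated — they shape the agent's
belief — but never enter scoring or fitting.

The adjusted score of a condition is the mean pump count over its non-burst
trials; when every balloon of a condition burst the score is *missing*,
never zero, and group tables propagate that as NaN.

## Cognitive models

Both models share the belief/choice skeleton described in the README.  The
printed literature carries two ambiguous variants, both implemented behind
`ModelDialects`; the defaults and their rationale:

- **Target-pump rule (RFPM).** Default `v = γ / (−ln(1 − p_burst))`: the
  pump target falls as the believed hazard rises, which is the canonical
  four-parameter behavior.  The variant `v = −γ·ln(1 − p_burst)` (which
  rises with hazard) is kept as an explicit dialect for fidelity
  experiments.
- **Loss weight (EWMVM utility).** Default weights the loss of the
  accumulated stake by `p_burst` — the stake is lost exactly when the
  balloon bursts — with the `1 − p_burst` variant behind a flag.
- **Observed burst rate (EWMVM belief).** Default is explosions per *pump*:
  `p_burst` is a per-pump hazard, so the quantity blended with it must be
  one too, and only this choice produces simulated sessions whose adjusted
  scores sit in the empirically reported range (a per-trial frequency
  overstates the hazard by roughly the mean pump count and drives agents to
  near-immediate stopping).  Explosions per *trial* is available behind the
  same flag.
- **Belief sharing.** One belief state is threaded across all balloon
  colors, because one parameter set is fitted per subject.  Per-condition
  threading exists in the reference implementation (`bartfnirs.models`)
  only; the compiled estimation path refuses it.

Likelihood bookkeeping: a cashed-out trial with `n` pumps contributes `n`
pump decisions plus the stop decision at opportunity `n + 1`; a burst trial
contributes only the pump decisions (the burst censors the stop choice), as
does a cash-out forced by the pump cap.  All probabilities are clamped to
`[1e-12, 1 − 1e-12]` before logs; computation is in log space with stable
log-sigmoid forms.  A brute-force enumeration test confirms the outcome
tree integrates to probability 1 within 1e-10 for pump caps up to 4, and a
Monte-Carlo test confirms the forward simulator and the likelihood describe
the same process.

## Synthetic cohorts

Group-level parameter locations default to the reference case-control
values: patients η = 0.0016, τ = 5.32, γ = −0.010, λ = 2.32, prior burst
belief 0.044; controls η = 0.049, τ = 6.94, γ = 0.004, λ = 2.807, burst
belief 0.037 (19 and 32 subjects respectively).  The reported φ values are
burst-convention priors, so the generator uses `φ_not_burst = 1 − value`.
Population spread is normal on the unconstrained scale (logit for φ, log
for η/τ/λ and the RFPM γ, identity for the signed EWMVM γ) with SDs of
0.2–0.5 — chosen once as plausible inter-subject variability for parameters
spanning, respectively, fractions of a logit and up to a decade of learning
rates.  `recovery_group_specs()` provides the η/τ-separation cohort used by
the recovery checks: φ, γ, λ pooled across groups so that any group signal
found outside η and τ is a false positive.

The optical generator emits, per subject and channel, 50 Hz HbO series:
`amplitude × (HRF ⊗ pumping boxcar)` — the HRF convolution runs at unit DC
gain so amplitudes stay in micromolar — plus linear drift (0.02 µM/min),
cardiac (1 Hz, 0.08 µM), respiratory (0.3 Hz, 0.05 µM) and Mayer-wave
(0.1 Hz, 0.06 µM) oscillations with random phases, white noise (0.1 µM SD),
and sparse motion artifacts (0.1/min, split between smooth ~0.7 s spikes of
5× noise SD and step shifts).  Each trial's pumping period lasts
0.8 s per pump (the task literature does not state per-pump timing; 0.8 s
lands full sessions in the reported 8–12 min), feedback 0.5 s, recovery
uniform 1–2 s; 45 s of rest precede the task and ~20 s trail it so edge
trimming never clips events.  A patient-only amplitude reduction at channel
4 (default 0.25 µM) emulates a localized frontopolar/orbitofrontal deficit.

What the generator does **not** emulate: inter-subject variability of
vascular response amplitude and shape, spatially correlated physiology
across channels, HbR, optode-scalp coupling changes, or serial correlation
beyond the injected oscillations.  Passing recovery tests therefore show
that the pipeline is correct under its own assumptions, not that real
recordings meet them.

## Hierarchical estimation

Subject parameters are sampled non-centered:
`θ_sj = transform_j(μ_j + σ_j z_sj)` with `z ~ N(0,1)`,
`μ_j ~ N(0, 5)`, `σ_j ~ HalfNormal(1)` on the unconstrained scale.  The
mean hyperprior is deliberately wide: plausible group learning rates span
log-units from ~e⁻⁶·⁴ (0.0016) to ~e⁻³ (0.05), and a standard-normal prior
on the mean demonstrably biases such values toward the origin.

The joint posterior is sampled with an affine-invariant ensemble sampler
(emcee) using differential-evolution moves (`DEMove`/`DESnookerMove`
mixture — the default stretch move mixes poorly in these 60–170-dimensional
ridge-shaped posteriors).  Likelihoods are numba-compiled and evaluated for
the whole ensemble per call.  Initialization is stage-wise: each subject is
fitted by penalized maximum likelihood from two multistarts, the hierarchy
is assembled from the moments of those estimates, and a short joint L-BFGS
polish provides the walker seed — a single optimization from a neutral
point routinely stalls in a spurious mode of the γ/λ/φ ridge (the
accumulated-stake loss and the variance bonus trade off when the believed
hazard is small).

`n_chains` (default 4) independent, separately seeded ensembles play the
role of chains; `n_draws` (default 4000) retained draws are thinned from
the post-warmup ensemble.  Split R-hat and ESS (arviz) are recorded for
every sampled quantity; any R-hat above 1.05 flags the fit, and model
comparison refuses flagged fits unless explicitly allowed.  Because all
chains start from the same initialization, R-hat measures within-basin
mixing rather than global mode coverage; this is stated rather than hidden.

The LOO unit is the trial: the likelihood factorizes per trial once the
belief is threaded, and per-trial pointwise matrices feed arviz's PSIS-LOO.
`LOOIC = −2·elpd_loo`; Pareto-k diagnostics are retained and a warning is
attached when more than 10% of trials exceed k = 0.7.  Akaike-style weights
use the stable min-shift form.  Group parameter values are reported both as
the natural-scale transform of the group-mean draws and as means of
subject-level posterior means (the published convention is ambiguous);
reports print φ in both the not-burst and burst conventions.

## Behavioral statistics

Welch's unequal-variance t (two-tailed) is the default two-sample test,
accepting raw vectors or `(n, mean, sd)` summaries; recomputing the
published green-condition comparison from its summaries gives t = −2.32
under Welch versus −2.09 pooled, matching the printed −2.30 only under
Welch, which fixes the default.  The pooled variant sits behind a flag;
reports print Welch df next to the naive `n₁+n₂−2`.  The published
blue-condition t (0.53) is reproducible under neither variant (0.58 / 0.50)
and is flagged in reports, not force-matched.  The two-way ANOVA
(group × condition, statsmodels OLS with type-II sums of squares) serves as
the screen before per-condition tests and refuses incomplete designs.
Parameter comparisons run one Welch t per parameter on subject posterior
means, uncorrected — FDR is reserved for the optical channel family.  A
caveat stated here because it is easy to miss: hierarchical shrinkage
deflates within-group spread of subject estimates, so these t statistics
are anti-conservative whenever the two group fits settle on even slightly
different pooling; the recovery tests therefore use the cohort whose groups
differ only in η and τ.

## Optical pipeline

Fixed order trim (15 s each edge) → polynomial detrend (order 1) → TDDR →
Butterworth band-pass (3rd order, 0.01–0.1 Hz, forward–backward) → GLM;
stage order is recorded in each series' provenance and enforced.

TDDR departs from the earliest published recipe in three measured ways (see
the `tddr` docstring): the low/high split sits at 2 Hz so sub-second spike
artifacts fall inside the corrected band; Tukey-biweight screening of the
low-band derivative is used for *detection* only, with correction restricted
to dilated contiguous low-weight segments; and within a segment the
derivative is shrunk toward a baseline interpolated from the flanking
second of clean data, which preserves the signal's own trend through the
artifact (shrinking toward zero erases that trend and leaves a permanent
baseline offset).  On the package's fixtures this attenuates a 5×SD,
sub-second spike by ~90%, changes a 0.05 Hz task-band sinusoid by < 0.1%,
realigns step baselines, and leaves GLM amplitude recovery unbiased on
realistic series with no group-dependent distortion.

The GLM design is `[HRF ⊗ pumping boxcar, intercept, linear]`, ordinary
least squares, with the 45 s rest entering implicitly through the
intercept.  The canonical HRF is a double gamma with unit peak, response
mode pinned at 6 s and undershoot trough near 16 s (gamma shapes 7/17,
scale 1, ratio 6, 32 s support); note that the common toolbox kernel with
shape 6 peaks at 5 s.  When the data were band-pass filtered the same
filter must be applied to the task regressor (`band=` argument) — otherwise
the filter's attenuation of task-frequency content biases β downward;
trial-locked designs concentrate energy near 0.1 Hz, right at the band
edge.  Whether the regressor should span only pumping periods (default) or
whole trials is a config switch.  Rank-deficient designs are refused with a
condition-number report.  Group contrasts are channel-wise Welch t
(patients − controls; a paired test is undefined across distinct cohorts)
with Benjamini–Hochberg FDR across the 8 channels of one contrast.

## Problem sizes used by the test suite

The acceptance-style tests run at sizes chosen for a routine CI budget
(~10 min total on one CPU): parameter recovery uses 4 replicate seeds of
the 19+19 × 90-trial η/τ cohort with 2-chain, 800-draw fits (passing
threshold 3 of 4); model recovery uses 5 seeds per direction at 10 subjects
× 30 trials (threshold 4 of 5); channel-4 localization and null FDR
calibration use 25 seeds each at 12+12 subjects with 10-trial sessions; the
simulator/likelihood coherence check uses 10⁵ single-trial sessions.  The
full-scale study configuration remains available through the CLI's `study`
preset.

## Known limitations

- The ensemble sampler's R-hat cannot detect modes never visited; genuinely
  multimodal posteriors (small cohorts, EWMVM's γ/λ ridge) may need longer
  warmup, more chains, or externally supplied initializations.
- PSIS-LOO becomes unreliable when many Pareto k exceed 0.7 (short chains,
  heavy posterior tails); the warning is attached to the result and should
  be respected rather than filtered out.
- The prior-predictive of the wide hyperpriors puts non-negligible mass on
  degenerate behavior (never pumping, or riding every balloon to the cap);
  sanity checks are therefore run against the population generator
  distributions, which produce ~1% degenerate sessions.
- t-tests on shrunken subject estimates are anti-conservative (see above);
  a fully Bayesian group contrast on the hyperparameters is the principled
  alternative and is available from the stored group-level draws.
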