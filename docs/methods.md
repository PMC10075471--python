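# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data generator behind `serialdep`, together with the design
decisions taken where several defensible options existed.

## Behavioral model

Choices are modeled as a hierarchical Bernoulli-logit process.  For
participant *i*, trial *j*:

    Y_ij ~ Bernoulli(p_ij),
    logit(p_ij) = β0i + β1i·CurrentPitch_ij + β2i·PrevPitch_ij + β3i·PrevChoice_ij,
    β_i = γ + μ_i,   μ_i ~ N(0, Σ)

with a full (correlated) 4×4 random-effect covariance Σ.  Four nested models
are compared by AIC: Model 1 drops both history terms, Models 2/3 keep only
the previous-pitch / previous-choice term, Model 4 keeps both.  All four are
fitted on the same observation set (rows with defined previous-trial
history) so AICs are directly comparable; AIC = 2k − 2·logL with k = fixed
effects + Σ parameters.

**Covariate coding.**  Pitch levels 1–5 map to a centered equal-spaced score
(−2…+2); the previous choice maps to ±0.5.  The codings are configuration
options and are reported with every fit; with γ₁ ≈ 1.1–1.2 the five levels
produce percent-"high" rates near 0.1/0.3/0.5/0.7/0.9, matching the
titration logic of the paradigm.  First-trial history terms use a cold start
of 0 (the neutral value) at generation time; fitting drops those rows
instead, keeping the two concerns separate.

**Estimation.**  No installed Python library fits frequentist binomial
mixed models with correlated random slopes, so `serialdep.glmm` implements
the standard Laplace-approximation maximum-likelihood estimator (the same
strategy as lme4's default): Σ is parameterized by its Cholesky factor
(log-scale diagonal, bounded below at e⁻⁶), per-participant random-effect
modes are found by damped Newton iterations (batched across participants,
warm-started between outer evaluations, gradient tolerance 1e-9), and the
outer optimization runs L-BFGS-B with finite-difference gradients
(ftol 1e-9).  With cluster sizes in the hundreds-to-thousands the Laplace
approximation is essentially exact; the test suite cross-checks fixed
effects and log-likelihood against lme4::glmer on a shared dataset
(agreement ~1e-4).  Fixed-effect standard errors use the classical GLMM
information Σᵢ XᵢᵀVᵢ⁻¹Xᵢ with Vᵢ = Wᵢ⁻¹ + XᵢΣXᵢᵀ, reduced to p×p via the
Woodbury identity and evaluated at the conditional modes; Wald z tests and
95% CIs follow.  A near-boundary Σ (log-diagonal within 1 of the bound) is
flagged as singular.

**Per-participant bias indices.**  The default index is the Model-4
conditional mode (BLUP) of each participant's previous-pitch /
previous-choice coefficient; independent per-participant GLMs are available
as a configuration alternative.  The motor index is switch rate − stay rate.
The High/Low-bias split is an equal-size median split on the index oriented
by the group-level direction of each bias (pitch: more negative = more
biased; category and motor: more positive), with deterministic tie-breaks by
participant id.

**RT exclusion.**  Trials with reaction time above mean + 4·SD are excluded,
computed per participant (thresholds were individualized, so a pooled rule
would mix scales); pooled computation is available via `FilterSpec.rt_scope`.
With SD = 0 nothing is excluded.  After any exclusion, history columns are
re-derived by trial-index adjacency, so a removed trial leaves both
neighbors with undefined history ("chain break") — this prevents phantom
2-back pairings.  Analysis-level exclusions (e.g. dropping trials preceded
by the extreme pitches f1/f5) use the same semantics.

## Decoding

At time t, voltages over channels and a trailing window (2 samples = 20 ms
at 100 Hz; column order sample-major) form one pattern per trial.
Stratified k-fold cross-validation (default 8 folds, repeated 50× with fresh
fold randomness) proceeds per fold: the training trials are balanced by
subsampling every condition to the minimum per-condition count (asserted
equal each fold); templates are the balanced condition means; the noise
covariance is estimated from the condition-demeaned (pooled) training trials
with the Ledoit–Wolf shrinkage estimator (cross-checked against
scikit-learn; shrinkage can be fixed, with 0 giving the raw sample
covariance for oracle comparisons); each held-out trial's Mahalanobis
distance to every template is computed via Cholesky whitening.  Distances
are averaged over repetitions first, then scored: per trial, the OLS slope
of its template distances on dummy-coded dissimilarity (0 same / 1
different), which for balanced designs equals mean(other) − own; the score
is the mean slope over trials.  Chance level is 0 by construction.

Conditional decoding of past/future features fixes the corresponding
current feature: decode within each stratum, then average across strata with
equal weights (a weighted option exists).  Strata missing a target condition
or with fewer trials than folds are skipped and logged; decoding a feature
against itself therefore fails loudly.  A categorical confound (e.g. motor
response during pitch decoding) can be regressed out of the patterns first —
implemented exactly as per-level mean removal with the grand mean retained.

Timepoints without a full trailing window are trimmed, not padded.  The
150-ms Gaussian-weighted moving average (`smooth_for_display`, sigma =
window/5, edge-renormalized) exists for plotting only and never feeds
inference.

## Representational shift (Shift_dist)

For a multi-level feature and ordered level pair (a, b): with cross-validated
templates and distances from the decoder's fold machinery (identical seeds ⇒
identical folds, so shift and decoding are directly comparable), D1/D2 are a
trial's distances to templates a/b; M_diff = mean(D2 − D1) over trials
(current = a, previous = b); M_diff_baseline = the same over baseline trials
(current = a, previous = a); Shift_dist(a,b) = M_diff_baseline − M_diff.
Attraction toward the previous feature shrinks D2 and yields positive
values; repulsion yields negative values.  The participant timecourse
averages all ordered pairs with populated cells (an adjacent-pairs-only
option exists); per-pair bookkeeping (M_diff, baseline, cell sizes) is
returned.  Because baseline and test cells share the same current level,
current-trial encoding cancels by construction.

For binary features, the signed distance difference is oriented so that
attraction toward the previous level is positive, and orientation means are
computed within (previous × current) cells and averaged with equal cell
weights.  Under a balanced design this equals the classic trial-pooled
average, but it remains centered at zero when behavioral serial bias makes
current labels uneven across previous-label groups — without the cell
balancing, a purely behavioral choice bias would masquerade as a neural
shift.  The recovery tests verify this null explicitly.

## Group inference

Sign-flip permutation tests flip each participant's timecourse with
probability ½ (the observed statistic is included in the null, so
p ≥ 1/(n_perm+1)).  Cluster correction thresholds the group mean at the
pointwise permutation quantile (alpha 0.05), defines clusters as maximal
suprathreshold runs, uses the sum of the group mean as cluster mass (the
group mean, not t, is the tested statistic; a t-mass variant exists), and
compares observed masses against the permutation distribution of the
maximum cluster mass.  Tail conventions: decoding one-sided (greater), shift
two-sided at the whole-group level, one-sided within bias groups.

Cross-correlations are computed on demeaned group-mean timecourses with
full-series energy normalization (coefficients in [−1, 1]); the sign
convention is c(ℓ) = Σ x₁[t]·x₂[t−ℓ], so a negative peak lag means series 1
leads.  The permutation threshold shuffles both series across time and takes
the maximum coefficient over lags (95th percentile, max-corrected).  Note
that sample shuffling destroys autocorrelation and is anticonservative for
smooth series; a phase-randomization null that preserves the power spectrum
is provided as `method="phase"`.  Peak-lag confidence intervals bootstrap
participants (2.5/97.5 percentiles).

Behavior–brain correlations are Pearson after removing points beyond 3 SD on
either axis (one pass by default); the rule and the excluded ids are always
reported, and fewer than 5 surviving points is a refusal.

## Synthetic-data generator

The generator emulates the two-session auditory categorization paradigm:
trials in balanced blocks (equal counts of the 5 pitch levels per block,
shuffled), choices drawn sequentially from the hierarchical logit model
above, motor responses tied to choices through a response-cue mapping, and a
plantable motor switch probability (the cue sequence is biased so the motor
response switches sides with a set probability, independent of the choice
process).  Reaction times are truncated-normal with optional planted
outliers at mean + 10·SD (marked in a ground-truth column).

Epochs are trials × channels × samples at 100 Hz, time 0 = noise onset, tone
at 1.0 s and response cue at 1.25 s by default (annotations, not hard-coded,
so cue-first designs are a config change).  Each feature (pitch 5 levels,
category 2, motor 2) contributes

    envelope(t) · [ amplitude · ((1−|λ|)·T(cur) + λ·T(prev))
                    + reactivation_gain · T(prev) ]

with unit-norm, mutually orthogonal channel templates drawn reproducibly
from one seeded QR basis.  λ is the planted representational shift
(morphing along the inter-template chord, the minimal geometry consistent
with attraction/repulsion); the reactivation term re-expresses the previous
trial's template inside the current activation window (co-occurrence).
Trials with undefined history receive neither term (counts logged).
Envelopes are cosine-ramped trapezoids (default 50-ms rise, 150-ms fall):
evoked activation packets with a well-defined onset, which is what makes
onset-recovery tests meaningful.  Pitch/category envelopes are tone-locked,
motor is cue-locked.  Noise is Gaussian with an exponential-decay spatial
covariance over channel distance (lengthscale 5 channels), AR(1)-smoothed in
time (coefficient 0.5, variance-normalized), amplitude 2.0 per channel —
i.e. single-trial pattern separations of roughly 0.7 noise SD, a moderate
EEG-like regime in which effects are invisible in single trials but
recoverable across a few hundred trials and a group of participants.

What the generator does **not** emulate: volume conduction from dipolar
sources, 1/f spectra and oscillations, artifacts, non-stationary drift, or
latency jitter across trials.  Passing recovery tests therefore demonstrates
the correctness and calibration of the estimators, not their field
performance on raw recordings.

## Validation studies (problem sizes)

`serialdep.experiments` fixes the study designs; the test suite asserts on
them and `scripts/acceptance.py` re-runs reduced versions.  Sizes were
chosen so the full suite runs in well under half an hour on one CPU:

- **Mixed-model recovery**: 20 replicates of 30 participants × 2000 trials,
  γ = (0, 1.2, −0.8, 1.7), Σ = diag(0.09, 0.04, 0.04, 0.09); AIC winner and
  95%-CI coverage of all four fixed effects.
- **Type-I calibration**: 200 null simulations of 12 × 150 trials
  (γ₂ = γ₃ = 0); Wald rejections at 5% plus KS uniformity of p-values.
- **Oracle**: 40-trial, 6-feature toy; shrinkage path at γ=0 vs explicit
  inverse, tolerance 1e-8.
- **Cluster FWER**: 200 label-shuffled experiments, 20 participants × 200
  trials each, 16 channels, 2-s epochs at 100 Hz decoded every 200 ms,
  n_perm = 1000.
- **Timing recovery**: 20 runs of 8 participants × 200 trials, 16 channels,
  full 10-ms decoding grid; features decoupled (no stimulus-choice
  coupling) so each feature's information onset is exactly its envelope
  onset.  Feature entanglement is exercised separately by the
  reactivation-specificity study (8 × 300 trials, conditional decoding).
- **Shift recovery**: 20 runs (plus 20 null runs) of 6 participants × 240
  trials, 12 channels, λ = ∓0.3; dose-response over |λ| ∈ {0.1, 0.2, 0.3}.
- **Lag recovery**: 6 participants × 200 trials; envelopes share one shape,
  pitch vs motor separated by the 250-ms tone-to-cue interval, pitch vs
  category locked to the same event.
- **Group contrast**: 16 participants, half with strong behavioral category
  bias and λ = 0.35, half with weak bias and λ = 0 (planted between-group
  effect ≈ 1 SD); median split on fitted behavioral bias, one-sided cluster
  tests per group.

Channel counts below the 64 of a standard montage are used where the
spatial dimension is not the property under test; the estimators are
dimension-agnostic.

## Known limitations

- The Laplace likelihood (and hence AIC) is an approximation, excellent for
  large clusters but increasingly biased below ~50 trials per participant.
- Wald CIs on near-boundary variance components are unreliable (flagged).
- The sample-shuffle cross-correlation null is anticonservative for smooth
  timecourses; prefer the phase-randomization null when autocorrelation is
  strong.
- The binary-shift statistic assumes both (previous × current) cells exist;
  extremely biased designs may skip strata.
- File formats: the normative epoch container is the `.npy` + JSON sidecar
  pair; the MNE adapter is a convenience and drops event/key metadata into
  the caller's hands.
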