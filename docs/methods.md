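# Methods

This note documents the analysis pipeline, the synthetic-data model behind
its validation, the numerical choices that are not forced by the procedure
itself, and the limitations we know about.

## Session model

A session is a block-cued two-location orientation change-detection
experiment.  Trials are sequences of 400 ms Gabor flashes separated by
300–500 ms inter-stimulus intervals after a 300–500 ms fixation period; each
flash after the first is a target (an orientation change) with fixed
probability — a uniform hazard, so target timing is unpredictable.  One
hemifield is cued per block (90% of targets occur there); blocks switch
after 80 hits and open with unilateral *cue trials* until 5 hits.  Valid
targets change orientation by ±{1, 3, 6, 15}°, invalid ones by the
near-threshold ±3°.

Analysis epochs, in ms relative to flash onset and half-open `[start, end)`
so abutting epochs never double-count a spike:

| epoch    | window       | role                          |
|----------|--------------|-------------------------------|
| pre      | [−200, 0)    | anticipatory activity         |
| post     | [200, 400)   | sustained stimulus response   |
| baseline | [−100, 0)    | PSTH baseline                 |
| response | [−100, 600)  | time-resolved regression      |
| psth     | [−300, 700)  | display window                |

Spike times and onsets are integer milliseconds (1 ms binning).  All neural
data from target onset to trial end are excluded: a flash contributes an
epoch only if the window ends strictly before the trial's target onset (the
target flash itself therefore contributes its pre-stimulus interval but not
its response).  Smoothing uses a causal half-Gaussian kernel (σ = 20 ms,
support truncated at 4σ and renormalized to unit mass — mass loss below
0.01%); causality matters because anticipatory effects must not bleed
backward in time.

## Unit screening and PSTHs

Units are kept when the coefficient of variation (sample SD / mean) of
their firing rate across 10 equal-duration blocks of the session is ≤ 1
(stability against slow drift and sorting loss) and their whole-session
mean rate is ≥ 1 spike/s.  For the grand-average PSTH a unit must also be
visually responsive: some 50 ms window within the stimulus, slid in 10 ms
steps (a grid choice; the dense stepping trades a higher union false-positive
rate for sensitivity, and the type-I behavior of the whole screen is covered
by a dedicated test), must differ from the rate-matched per-flash baseline
by a paired two-tailed t-test at α = 0.05, uncorrected.  PSTHs are
baseline-subtracted and divided by the most extreme average deviation from
baseline over [0, 700) ms of the pooled (condition-collapsed) trace, so
facilitated and suppressed units are on a common scale; the divisor is
condition-independent by construction.  The grand comparison reports both
the first individually significant millisecond and the first *sustained*
(≥ 20 consecutive ms) significance, because isolated uncorrected
milliseconds flicker at the 5% rate by design.

## Attention axes

The core procedure.  Training intervals are those immediately preceding
validly cued, correctly detected targets — the intervals most likely to
have been genuinely attended.  Per cross-validation fold, a random half of
the training targets per cue condition (stratified so both conditions are
represented equally) defines:

* the post-stimulus axis: difference of condition means of the preceding
  flash's [200, 400) counts, unit-normalized, cue-in-RF positive;
* the raw pre-stimulus vector: difference of condition means of the target's
  [−200, 0) counts; the pre-stimulus axis is its Gram–Schmidt residual
  against the (held-fixed) post axis, normalized, with a second projection
  pass so ⟨w_pre, w_post⟩ vanishes to ~1e−16.

All intervals not used for training in a fold are projected on both axes
and normalized by the fold's affine map sending training condition means to
exactly ±1; final projections average over the folds in which the interval
was held out.  Intervals never eligible for training (misses, invalid
targets, sample flashes) are projected in every fold.

Numerical choices:

* a fold whose raw pre vector lies within 1° of the post axis (or whose
  condition means coincide) is degenerate; it is resampled with a logged
  warning, capped at 3× the requested folds.  Real data sit far from this
  regime (raw angles near 75–80°);
* the pre axis is sign-oriented per fold so the training cue-in-RF mean
  projects higher, making the normalization half-range positive;
* axes are unit-normalized before projection.  Whether the connecting line
  is normalized is irrelevant downstream because the per-fold affine
  normalization absorbs any scale — a property the tests assert.

**Known bias (orthogonalization leakage).**  With a finite training set the
estimated post axis ŵ differs from the true modulation direction d by an
angle θ, and the orthogonal complement then retains a component of any
modulation collinear with d: E[w_pre·d] ∝ E[sin²θ] > 0.  Consequently, when
baseline modulation is perfectly collinear with the stimulus gain pattern
(the stimulation-invariant-gain surrogate below) the held-out pre-axis
projections acquire a small systematic condition separation (measured mean
≈ +0.04 normalized units at realistic effect sizes; ~12% of sessions
individually significant versus the 5% nominal).  The bias shrinks with the
collinear modulation strength and with training-set size but cannot be
removed by more folds.  Pre-axis condition-separation results near the
detection floor should therefore be interpreted with this in mind; the
hit/miss and VAF readouts are far less sensitive to it because they compare
outcomes *within* cue conditions.

## Behavioral linkage

d′ uses the session false-alarm rate with all completed non-target flashes
as the opportunity denominator, and the log-linear correction (add 0.5 to
each cell, 1 to each denominator) whenever a rate is 0 or 1.  The 5×5 map
bins each session's target-preceding projections into rank-based quintiles
(stable ties to the lower bin), normalizes cell hit rates by the session's
overall hit rate, and excludes empty cells.  Rank correlations between
quintile index and hit rate are computed across the defined cells of the
25-cell map by default; because "bin index" could equally mean the 5
marginal bins, that variant is exposed (`variant="marginal5"`) without
asserting which is canonical — note exact ρ = 1 is attainable only in the
marginal variant, since the 25-cell quintile index has ties.  Session ρ
values are Fisher-z transformed (perfect correlations clipped at
1 − 1e−10), tested against zero with a two-tailed one-sample t-test, and
compared between axes with a paired t-test; the mean z is back-transformed
for reporting.  Normality checks (Lilliefors) warn rather than abort.

## Two-step VAF regression

Eligible flashes are samples preceded by another sample on the same trial
(targets are contaminated by the saccade; first flashes by the fixational
eye movement).  The stimulus-response axis connects the trial-averaged
baseline point to the trajectory point furthest from it; responses are
projected on it and mean-centered per time point.  Predictors (the
fold-averaged projections, which are the per-trial attention estimates) are
mean-centered per session so the no-intercept closed form
β̂ = ⟨a, r_t⟩/⟨a, a⟩ is exact; in-sample VAF then lies in [0, 1] at every
time point, and the sequential decomposition
`total = VAF_post + (1 − VAF_post)·VAF_pre` matches a joint two-predictor
fit when the predictors are sample-orthogonal (asserted against a
normal-equation oracle).  Where step 1 explains the response to numerical
precision, step 2's VAF is defined as 0 rather than fit to float noise.

The shuffled null permutes the projection/response pairing within session;
its mean matches the analytic 1/(n−1) for independent Gaussian variables.
Significance uses per-time one-sided t-tests across sessions against the
null level, corrected by a minimum run length calibrated on simulated null
experiments with AR(1)-matched autocorrelation (order configurable; a
non-stationary fit falls back to phase-randomized surrogates of the
observed series).  For independent tests at T = 700 and α = 0.05 the
calibrated threshold is 4 samples; smoothed VAF series yield thresholds of
a few tens.

**Window-overlap caveat.**  The pre-axis predictor is measured on
[−200, 0) while the response window starts at −100 ms, and the causal
kernel carries spikes forward 80 ms; for t < 80 ms the smoothed response
therefore shares spike counts with the predictor interval, and VAF_pre
exceeds the null there mechanically, even for a pure-noise axis.  Timing
claims about the pre-stimulus contribution (peak ordering, mask emptiness
in controls) are therefore evaluated for t ≥ 80 ms, the first time point
whose smoothed response contains no pre-onset data.

## Synthetic-data model

The generator emulates the statistical structure the analysis assumes, with
defaults set to the task constants above and population parameters chosen
to be realistic for V4 populations:

* 40 units per session, baseline rates log-normal (median 5 spikes/s,
  σ_log = 0.7); two 80-hit blocks per session (~250 trials), matching the
  order of valid-target counts per session in chronic-array experiments;
* a per-trial latent attention state a_k: AR(1) across trials
  (persistence 0.7, stationary SD 0.6) around ±1 by cue side, mapped to
  s_k = tanh(a_k) ∈ (−1, 1); plus an independent AR(1) "readiness" state
  q_k (mean 0) capturing within-condition anticipatory fluctuation;
* per-unit modulation patterns: stimulus gains g_i with mean 1.09
  (SD 0.12) and signed baseline modulations m_i with mean 0.02 (SD 0.15),
  drawn jointly Gaussian with correlation 0.46 — so post-stimulus effects
  average ≈ +9–14% while pre-stimulus effects are near-zero-mean and
  mixed-sign, positively related across epochs;
* rates: unit i fires Poisson around λ_i·template(t)·modulation, where the
  template is 1 between stimuli and transient (peak ≈ 60 ms, amplitude 1.5)
  plus sustained (amplitude 0.7) during RF stimuli.  The modulation factor
  is 1 + (g_i−1)·s_k on the sustained response, and 1 + m_i·(s_k + q_k)
  during inter-stimulus intervals *and* (scaled by `transient_pre_coupling`)
  on the onset transient — the anticipatory pattern carries into the
  earliest response, which is what gives the pre-stimulus attention estimate
  unique predictive power at short latencies;
* behavior: P(hit) is logistic in the state signed toward the target side
  and in ln(|Δθ|/3°); false alarms occur per non-target flash with a small
  state-dependent probability (so d′ is computable); hit RTs are shifted
  log-normal with an attention-dependent median.

The gain-only control (`generate_gain_only_session`) forces
m_i = 0.2·(g_i − 1): baseline modulation perfectly collinear with the
stimulus gains, at the slight relative magnitude (~0.2 of the stimulus
effect) that a stimulation-invariant-gain account of anticipation actually
reports.  Under this model no population direction orthogonal to the
post-stimulus axis carries attention information, so every pre-axis readout
should be null — up to the orthogonalization leakage discussed above, which
this control is precisely designed to expose.

What the generator does **not** emulate: correlated (shared) trial-to-trial
variability beyond the one-dimensional latent state, rate adaptation across
flashes, eye-position artifacts, non-Poisson spiking statistics, unit-count
asymmetries between hemispheres, and feature (orientation) tuning.  Passing
tests therefore show the pipeline recovers the *modeled* structure at
realistic scales, not that real cortical data satisfy the model.

The two-neuron population-coupling model (`simulate_coupled_pair`) couples
a strongly population-coupled neuron B to a weakly coupled neuron A through
a monotone function of a causal exponential moving average of A's rate
(τ = 200 ms).  The memory term is essential: it lets an attention gain on
A's stimulus response shift B's rate during the following inter-stimulus
interval while A itself is back at baseline, producing epoch-dependent
population patterns (A: post-only facilitation; B: pre-stimulus
suppression) from a single gain parameter.  With instantaneous monotone
coupling the sign of B's attention effect is tied to A's in every epoch, so
no such dissociation is possible.

## Pipeline scale choices

The default test/experiment profile uses 40–100 cross-validation folds and
sessions of two 80-hit blocks; the full procedure (1000 folds) is a CLI
profile away (`--profile paper`).  Validation experiments use 20 sessions
per replicate with reduced folds and 200–500 run-length simulations; these
sizes keep a complete validation run in minutes on one core while leaving
every statistical conclusion comfortably powered, and none of them change
the estimators — only their Monte-Carlo resolution.

## Known limitations

* Orthogonalization leakage (above): second-order, always toward the
  cue-in-RF pole, relevant only when baseline modulation is nearly
  collinear with the stimulus-gain pattern.
* Pre-window/response-window overlap (above): VAF_pre values before
  t = 80 ms are partially mechanical.
* The run-length null models the VAF series as Gaussian AR(1); heavier
  autocorrelation structure is handled only through the fallback spectral
  surrogates.
* Quintile binning needs enough targets per session; below ~25
  target-preceding intervals the 5×5 map is sparse and its rank-correlation
  p-values become discrete (the implementation warns).
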