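# attnaxes

Population-level analysis of **anticipatory visual attention** for block-cued
change-detection experiments, together with a synthetic spiking-session
generator so the entire pipeline can be exercised and validated without any
recordings.

## The scientific problem

In visual cortex, attending to a stimulus inside a neural population's
receptive field (RF) raises firing rates during the stimulus response — a
gain of roughly +9% on average.  Before a stimulus appears, however, the
population *average* barely moves, even though the subject is demonstrably
attending.  One resolution is that anticipatory attention is carried by a
**mixture of rate increases and decreases** across neurons — a population
pattern distinct from the gain pattern seen during stimulus processing, and
invisible to averaging.  This package implements the analysis that tests
that idea:

1. **Attention axes.**  With population activity as a point in
   *n*-dimensional firing-rate space (one axis per unit), an attention axis
   is the unit vector along the line connecting the trial-averaged activity
   of the two cue conditions (cue-in-RF vs cue-away),
   `w = (x̄_in − x̄_away) / ‖x̄_in − x̄_away‖`.  A **post-stimulus axis** is
   fit from spike counts 200–400 ms after onset of the sample flash
   preceding each correctly detected, validly cued target; a **pre-stimulus
   axis** is fit from the 200 ms immediately preceding the target and then
   **orthogonalized** (Gram–Schmidt) against the post axis, so it can only
   capture anticipatory structure linearly independent of the
   stimulus-response gain pattern.
2. **Cross-validation and normalization.**  Axes are re-fit on random half
   splits (1000 folds in the full procedure); held-out activity is projected
   and affinely normalized per fold so the training cue-in-RF mean maps to
   +1 and the cue-away mean to −1; each interval's projection is averaged
   over the folds that held it out.  Projections give a scalar
   moment-to-moment estimate of the attention state.
3. **Behavioral linkage.**  Projections preceding hits vs misses are
   compared within and across sessions; projections are binned into
   quintiles per axis (a 5×5 map of normalized hit rates) and the
   quintile/hit-rate rank correlation is tested through Fisher-z transformed
   Spearman ρ.  Behavior is summarized with d′ = Φ⁻¹(H) − Φ⁻¹(F)
   (log-linear corrected).
4. **Two-step variance-accounted-for (VAF) regression.**  The population
   response to each eligible sample flash is reduced to a scalar time series
   r_t by projection onto a stimulus-response axis.  At each millisecond,
   r_t is regressed on the post-axis projection of the *previous* stimulus
   (β̂ᵗ = argmin‖r_t − a·β‖², VAFᵗ = 1 − ‖r_t − a·β̂ᵗ‖²/‖r_t‖²), and the
   residual η_t on the pre-axis projection of the immediately preceding
   inter-stimulus interval.  Significance versus the trial-shuffled null
   (theory: 1/(n−1)) uses per-time t-tests across sessions with a run-length
   correction calibrated by autocorrelation-matched simulation.

Intended users: systems/computational neuroscientists analyzing population
recordings from cued attention tasks, and anyone needing a reference
implementation of cross-validated difference-of-means decoders with
orthogonalized secondary axes.

## Worked example

```python
import numpy as np
from attnaxes import GeneratorConfig, run_experiment

res = run_experiment(GeneratorConfig(), n_sessions=6, seed=7, n_folds=50)

r, p = res.effect_correlation
hm = res.hit_miss["RF"]
rc = res.rank_correlation
t = res.vaf_time_ms
late = t >= 80                      # past onset + causal-kernel support
vpost = res.vaf_post.mean(axis=0)
vpre = res.vaf_pre.mean(axis=0)
```

This simulates six sessions of the cued change-detection task (40 units,
two 80-hit blocks each, 30% per-flash target hazard, 90% cue validity),
runs every stage, and prints:

```
pooled pre/post effect correlation r = 0.24 (n = 240 units, p = 1.7e-04)
doubly significant units per sign quadrant: {('+', '+'): 36, ('+', '-'): 5,
  ('-', '+'): 12, ('-', '-'): 10} flip fraction 0.27
hit/miss separation (RF targets): pre axis p = 0.0302, post axis p = 0.0017
quintile rank correlation: pre rho = 0.20 (p = 0.092),
                           post rho = 0.29 (p = 0.013)
VAF_post peak 0.0193 at 246 ms; VAF_pre peak 0.0176 at 80 ms;
  shuffled null 0.0018
```

Reading the output: per-unit attention effects correlate positively between
epochs yet a sixth of the doubly significant units *flip sign* (suppressed
before the stimulus, facilitated during it — the upper-left quadrant), which
a stimulation-invariant gain cannot produce.  Both axis projections predict
whether the upcoming target will be detected (hits shifted toward the
cue-in-RF pole).  The post-axis attention estimate explains response
variance best during the sustained response (~250 ms), while the unique,
orthogonal pre-stimulus contribution peaks at the start of the onset
transient — anticipatory state matters most for the earliest part of the
sensory response.

A command-line interface mirrors the stages
(`attnaxes simulate|qc|effects|axes|behavior|vaf|run`); e.g.

```bash
attnaxes simulate --out session0 --seed 3
attnaxes axes --session session0 --folds 200 --seed 1 --out proj.csv
attnaxes run --sessions 6 --seed 7 --out report/ --profile test
```

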