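# Methods

This note records the modelling conventions, the synthetic-cohort design,
and the numerical choices behind `subwave`, in the spirit of a model
description a maintainer can audit.

## Wavelet smooth

The denoised feature at resolution level `j` is the Haar MODWT scaling
coefficient series. Two conventions matter and both were genuinely open:

* **Normalization.** The orthonormal Haar scaling function carries a
  `2^{j/2}` factor; we use MODWT (mean) normalization `2^{-j}` instead, so
  the level-`j` smooth is a plain 2^j-point moving average in the channel's
  physical units. Any fixed per-level rescaling is invisible to tree-based
  classifiers (they only compare thresholds within one feature), so
  predictions are unaffected; interpretability is better.
* **Alignment and boundary.** The window is *causal* — the coefficient at
  time `t` averages samples `t, t−1, …, t−2^j+1` — because a feature used
  to predict `y_{t+g}` must not read past `t`. The boundary is circular
  (standard MODWT), which preserves length, exact mean conservation and
  linearity; only the first `2^j − 1` positions of each series touch future
  samples through the wrap. The dataset builder exposes
  `drop_wrap_prefix` to exclude those rows; the default keeps them (all
  `T_n − g` rows per patient), matching the pooled-dataset definition.
  When `2^j` exceeds the series length a `BoundaryDominanceWarning` is
  raised; the computation remains well defined.

Implementation is the pyramid recursion
`V_j[t] = (V_{j-1}[t] + V_{j-1}[t − 2^{j-1}]) / 2` (O(T·j)); tests compare
it against a brute-force circular moving average at 1e-12.

## Subgroup discovery

Per numeric baseline variable (age, height, weight) a depth-2 regression
tree is fitted to per-patient state ratios: greedy SSE minimization, split
thresholds at midpoints between adjacent distinct covariate values, SSE
ties broken toward the smaller threshold. A split is accepted only if its
SSE reduction is ≥ `complexity` × root SSE (the cost-complexity convention
of rpart-style software, default 1e-4) and both children keep ≥ `min_leaf`
patients. `min_leaf` defaults to 20: with ~200-patient cohorts this blocks
degenerate subgroups that could not support their own classifier. Sex is a
fixed two-category split — a binary variable admits nothing else.
Intervals are half-open `[lo, hi)`, so a boundary value falls in the upper
interval. The published 13-rule scheme (age cuts 38/53/68, height
173/183/188, weight 63/93, sex M/F) can be authored directly with
`scheme_from_thresholds` and is used as a fixture in the tests.

## Models and aggregation

One XGBoost binary classifier per subgroup plus one global model.
Defaults: 200 rounds, depth 4, learning rate 0.1, logistic objective,
`tree_method=hist`, single thread, fixed seed — all exposed in
`BoostingParams`. Boosting's reweighting of misclassified observations is
the only imbalance handling by default; a `scale_pos_weight` option
exists. Train/validation is split **by patient** (70/30, seeded) so no
patient contributes to both sides; metrics are computed on the held-out
patients (in-sample evaluation would reward memorizing patient set
points). The aggregated probability is the unweighted mean over the m
matching subgroup models (no subgroup-size weighting); the label rule is
strictly `P > 0.5`, so exactly 0.5 maps to 0. Variable importance is the
share of internal split nodes per channel; for the aggregated method each
subgroup model's shares are averaged with equal model weight (the
combination rule was open; equal weight keeps small subgroups visible).

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes, not
the physiology of any real dataset. Per patient and channel, the latent
signal is the sum of

| component | default | role |
|---|---|---|
| patient set point `μ ~ N(0, 1)` | sd 1.0 | chronic baseline differences; predictable at any horizon |
| slow sinusoid, period ~U(180, 300) steps, amplitude √2 | var 1.0 | drifting trend over hours (5-min grid); survives moderate smoothing, killed by 256-point windows |
| AR(1), φ = 0.95 | sd 0.3 | short-range physiological variation |
| damped oscillation AR(2), r = 0.97, period 16 | sd 0.85 | narrowband rhythm *between* the 4-point and 16-point windows |
| white noise | sd 1.75 | monitor noise |

The damped oscillation is the load-bearing choice. A window-retention
analysis shows why: a 4-point average keeps ~73% of a period-16 narrowband
rhythm while cutting noise variance fourfold, a 16-point average keeps ~2%
of it, and a 256-point average also destroys the slow sinusoid. With the
noise level at 1.75 this makes level 2 the genuine optimum of the level
grid {0, 1, 2, 4, 8} — smaller windows under-denoise, larger ones erase
the band-limited signal. A latent process with only slow components would
instead make level 4+ strictly better (wider windows keep slow signal and
remove more noise), and a process with only fast components would make
long-gap prediction impossible. The set point and slow sinusoid are what
keep AUC at gap 20 within ~0.08 of gap 1.

The binary state at time `t` is Bernoulli with log-odds
`c + offset(n) + Σ_k coef_k(n) · L_{n,k,t−lag}` on the **noise-free**
latent channels, `lag = 1` by default, so a supervised dataset built at
gap `g = lag` is the correctly specified model and denoising genuinely
helps (the noise is pure nuisance). Heterogeneity enters through two age
bands (boundary 50): distinct coefficient vectors of equal Euclidean norm
(so both bands are equally predictable) and log-odds offsets ∓0.4 (so the
bands differ in prevalence, which is what the subgroup tree detects). The
global intercept `c` is solved with Brent's method on the realized risk
scores so the pooled state-1 fraction hits the prevalence target (0.08)
before states are drawn; baselines are uniform over plausible adult ICU
ranges with sex Bernoulli(1/2), which populates every subgroup interval.

What the generator does **not** emulate: named clinical variables, missing
measurements, irregular sampling, treatment feedback, non-Gaussian monitor
artifacts, or cross-channel correlation of the noise. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes
— not that the method works on real ICU data.

## Study conditions and problem sizes

The shipped study uses 200 patients, series lengths 240–360, K = 6
channels, ten independent cohort seeds, levels {0, 1, 2, 4, 8} and gaps
{1, 20} (the single-seed driver runs gaps {1, 5, 10, 20}). Boosting for
the study grid uses 80 rounds, depth 3, learning rate 0.15 — sized to the
6-channel synthetic panels, where deeper ensembles only slow the grid
without changing its ordering. These sizes are the package's scaled-down
stand-in for a cohort four orders of magnitude larger; medians and
win-fractions over seeds, not single AUCs, are the reported quantities.

## Numerical details and degenerate cases

* Seeds: every random stream is a `numpy` `default_rng` seeded from the
  configuration; derived seeds stay below 2^31.
* AUC: midrank Mann–Whitney (tie-safe, O(n log n)); undefined for
  single-class labels (error, never NaN).
* F1 = 2tp/(2tp+fp+fn); 0 when tp = 0 with errors present; the vacuous
  all-negative-and-correct case would report 1.0 with a warning but cannot
  occur once both classes exist.
* Tree SSE uses prefix sums of `y` and `y²`; a split must beat the current
  best by >1e-12 to replace it, keeping the smaller-threshold tie rule
  deterministic.
* Patients shorter than the gap contribute no rows; a subgroup whose
  training data is empty or single-class raises a `TrainingError` naming
  it, annotated with the (level, gap) cell inside the grid.
* Intercept calibration brackets the root in [−40, 40] and falls back to a
  closed-form logit shift in the degenerate constant-risk case.

## Known limitations

* Subgroups are single-variable by construction; interaction subgroups
  (e.g. age × sex) are out of scope.
* The aggregated method needs at least one non-missing baseline variable;
  patients with none can only be scored by the original method.
* Circular wrap rows are kept by default, so the first `2^j − 1` features
  of each series blend in end-of-series samples; at level 8 with T < 256
  the smooth degenerates toward the per-series mean (warned).
* Probabilities are not calibrated; with 8% prevalence the 0.5-threshold
  F1/sensitivity are near zero even when ranking (AUC) is strong —
  threshold choice is deliberately left to the user.
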