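# subwave

Subgroup-aggregated patient-state prediction on wavelet-denoised
physiological panels.

## The problem

In ICU-style monitoring, a patient's condition is summarized as a binary
state (e.g. stable vs. circulatory failure) observed on a fixed time grid
alongside K continuous physiological channels. Predicting the state `g`
steps ahead from the channel history is hard for two reasons: monitor noise
obscures the signal, and patients are heterogeneous — the channel–state
relationship differs with baseline characteristics (age, sex, weight,
height), so one model fitted to everyone underserves everyone.

`subwave` implements a pipeline that addresses both at once:

1. **Denoising.** Each channel is replaced by its Haar MODWT *scaling
   coefficients* at resolution level `j` — under mean normalization, the
   causal circular 2^j-point moving average

   `W_t(j) = 2^{-j} Σ_{l=0}^{2^j−1} x_{(t−l) mod T}`,

   a non-decimated smooth that keeps the series length (level 0 = raw
   signal).
2. **Subgroup discovery.** For each baseline variable, a depth-2 regression
   tree (complexity 1e-4, minimum leaf 20) is fitted to the per-patient
   *state ratio* (fraction of time in state 1); its accepted thresholds
   become half-open interval rules (sex contributes the fixed M/F split).
3. **Gap-lagged datasets.** For each subgroup `s`, the rows
   `(W_{n,·,t}(j), y_{n,t+g})` of its member patients are pooled,
   `t = 1..T_n − g`.
4. **Subgroup models.** One gradient-boosted tree classifier (XGBoost,
   logistic objective) per subgroup plus one *global* model on all data.
5. **Aggregated prediction.** A patient belongs to one subgroup per
   baseline variable (m ≤ 4 memberships); the aggregated probability is the
   unweighted mean `P(Ŷ=1) = (1/m) Σ_s XGBoost_s(W)`, thresholded strictly
   at 0.5. The global model alone is the *original* method.
6. **Evaluation grid.** AUC (midrank Mann–Whitney), F1, sensitivity and
   specificity over every (level, gap, method) cell, with a patient-level
   70/30 train/validation split, plus selection-frequency variable
   importance (a channel's share of all split nodes in the ensemble).

Real ICU data of this shape is access-restricted, so the package ships a
seeded synthetic cohort generator (`subwave.simulate`) with the statistical
structure the method assumes: heterogeneous series lengths, additive
channel noise, a rare state driven by the *noise-free* latent channels one
step earlier, and age-dependent risk dynamics. See `docs/methods.md` for
the generator's design and its limits.

## Worked example

The numbered drivers under `analysis/` run the study end to end; each
writes its tables under `results/`.

```bash
python analysis/01_simulate_cohort.py
```

```
cohort: 200 patients, 60822 time points, K=6 channels
pooled state-1 prevalence: 0.0798 (target 0.08)
mean state ratio, age <  50: 0.0570  (n=87)
mean state ratio, age >= 50: 0.0964  (n=113)
```

The state is rare (≈8% of time points) and the two age bands have visibly
different state ratios — the heterogeneity the subgroup tree then finds
(`analysis/03_discover_subgroups.py` yields 13 rules whose age cuts bracket
the true band boundary at 50).

```bash
python analysis/04_grid_single_seed.py
```

```
AUC by level (rows) and (method, gap) (columns):
method aggregated                      original
gap            1      5      10     20       1      5      10     20
level
0           0.696  0.647  0.617  0.636    0.649  0.600  0.567  0.587
1           0.718  0.659  0.638  0.647    0.677  0.615  0.580  0.594
2           0.732  0.659  0.663  0.662    0.689  0.606  0.604  0.613
4           0.723  0.699  0.708  0.694    0.684  0.659  0.669  0.649
8           0.630  0.624  0.615  0.626    0.581  0.566  0.560  0.550

best aggregated level at gap 1: 2
```

Reading the table: the aggregated method beats the original in every cell
(here by 0.04–0.06 AUC); moderate smoothing helps (level 2 best at gap 1)
while heavy smoothing destroys the predictive detail (level 8 worst); and
AUC decays only mildly as the prediction horizon grows from 1 to 20 steps.
`analysis/05_seed_study.py` repeats this over ten independent cohorts: all
three patterns held in 10/10 seeds, with a median gap-1 to gap-20 AUC
change of 0.082.

A shell interface mirrors the library (`subwave simulate | smooth |
build-subgroups | make-dataset | train | predict | evaluate | grid |
importance | run`); `subwave run --config configs/tiny.yaml --out-dir out`
is a seconds-long smoke run.

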