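# Methods

`penwatch` implements a pen-level early-warning analysis for tail-biting
(TB) outbreaks in grower-finisher pigs, built on per-visit records from
single-space electronic feeders. This note documents the data model, the
synthetic generator, the window framing, the preprocessing and model
benchmark, the evaluation design, and the numerical and design choices
made where the design was genuinely open.

## 1. Data model and daily observations

The raw unit is a *feeder visit*: (pen, pig, date, entry/exit time, grams
consumed). Three per-pig per-day variables are derived:

| variable | definition | units |
|---|---|---|
| DFV | number of visits whose entry time falls in the calendar day | n/day |
| DFC | total feed consumed over those visits | g/day |
| StdFC | sample SD (n−1) of per-visit intake within the day | g |

Conventions the raw definition leaves open, and how they are resolved:

* a visit belongs to the day of its **entry** time; visits spanning
  midnight are not split;
* **StdFC is missing** (not 0) with fewer than two visits — a single
  visit carries no dispersion information; the missing cell is later
  median-imputed like any other;
* a rostered pig-day with no visits is a **real observation** (0, 0,
  missing). Days on which the recorder was down are listed in a `gaps`
  table and become fully missing, so "present but ate nothing" and
  "absent/not recorded" stay distinguishable. For feeds where that
  distinction is unavailable, `daily_observations(..., zero_day="missing")`
  treats all empty days as missing instead (a documented dialect switch).

## 2. Synthetic feeder-data generator

No public feeder dataset accompanies this kind of analysis, so the
package ships a generator whose defaults emulate two herds: a
Swedish-style boar station (42 pens, 7–14 boars/pen, recorded 70 d
either side of day 0) and a Swiss-style experimental farm (23 pens,
11–55 pigs/pen, ±100 d). The marginal per-pig-day moments of DFV, DFC
and StdFC are calibrated to the control-class values of those herds
(e.g. Swedish DFC 2337 ± 757 g, DFV 24.9 ± 19.4 visits, StdFC
128.6 ± 85.9 g).

Per pig-day, with all multipliers combined into a mean shift:

* **visit count** — gamma-mixed Poisson (negative binomial). The gamma
  shape is derived once per profile so that structured variance
  (between-pig, between-pen, autocorrelated day effects) plus day-level
  NB variance reproduces the configured marginal SD; feeder visit counts
  are strongly over-dispersed (SD of the order of the mean), which a
  plain Poisson cannot represent.
* **intakes** — the daily total is a tight gamma around its expectation
  (day-level CV 0.12), split across visits by gamma weights whose
  dispersion matches the StdFC target. This decouples how stable a
  pig's daily ration is from how unevenly it is eaten.

Structured heterogeneity (log-normal, mean 1; documented constants in
`penwatch.simulate`):

| component | CV (DFV / DFC / StdFC) | emulates |
|---|---|---|
| between-pig baseline | 0.50 / 0.20 / 0.25 | stable individual feeding styles |
| between-pen baseline | 0.20 / 0.15 / 0.15 | batch, feeder-placement, group effects |

The attribution of much of the DFV variance to stable between-pig
differences, rather than to i.i.d. day noise, follows what
electronic-feeder studies consistently report about individual feeding
patterns. Day-to-day fluctuations around these baselines are drawn
independently per pig-day. Real feeding series additionally carry
within-pen temporal autocorrelation (weather, feed batches, growth);
this is deliberately **not** modelled, because the generator's null
configuration must satisfy a calibration contract: with all drift
multipliers at 1, nothing computed downstream may distinguish TB from
CTL material beyond chance. Autocorrelated day effects break that
contract in the window-level CV regime — overlapping windows of one pen
share their realized noise, so a flexible classifier can reconstruct
pen-and-date identity, and the time-contiguous labels then become
predictable with no outbreak signal at all (measured here as test kappa
≈ 0.6 under a null simulation). The persistent between-pig and
between-pen baselines already supply the pen-recognition mechanism that
separates the CV from the pen-held-out regime, without poisoning the
null calibration.

**Outbreak drift.** TB pens receive a multiplicative drift on the three
expectations: by default DFV ramps linearly from 1 at day −42 to 0.70 at
day 0, DFC and StdFC to 0.85, then all relax linearly back to 1 over 14
days. Onset six weeks before the event and a depression concentrated in
visit frequency reflect the published observations that visit frequency
declines 42–63 days before outbreaks while consumption reacts later and
less. The magnitudes themselves are **synthetic stand-ins** — no public
effect-size timeline exists — and are configuration, not estimates. The
TB date is placed uniformly in the middle third of the recording span so
default labeling horizons fit inside it.

What the generator does **not** emulate: within-day feeding rhythms
(timestamps are cosmetic), biter/victim identities, seasonal or
batch-calendar structure, herd-specific covariance between the three
variables, and real outbreak heterogeneity (mixed fast/slow onsets).
Passing tests therefore show that the pipeline detects a drift of the
assumed multiplicative form at realistic noise levels — not that any
model generalizes to real outbreaks.

## 3. Analysis windows and labeling

A sliding window (stride 1 day, configurable) covers `window_days`
(default 14) consecutive days for `pigs_per_window` (default 10) pigs
and all three variables: 3 × 10 × 14 = 420 cells, flattened
variable-major (variable, then pig slot, then day). The window's
`a_date` is its first day. Control-pen windows are always CTL; TB-pen
windows are TB exactly when `a_date` falls in the TB window around the
pen's TB date, default [−35, +10] **inclusive** on both ends (hence 46
TB-labeled a_dates in a fully recorded pen; 60 for [−49, +10], 16 for
[−10, +5]). Inclusive bounds are the natural reading of "day −35 to day
10"; nothing in the source material fixes open/closed ends.

Pens with more than 10 pigs contribute the 10 with the most non-missing
observation days (ties by pig id) — a deterministic, reproducible
substitute for an unspecified choice; pens with fewer get placeholder
slots whose cells are missing and later imputed.

## 4. Preprocessing

Three fitted transforms, applied in order and each stratified **by herd
× variable** (merging herds must not let one herd's scale leak into the
other's):

1. median imputation of missing cells;
2. centering and scaling to unit SD;
3. PCA, keeping the smallest leading set of components reaching
   `pca_variance_retained` (default 0.95) cumulative explained variance.

All three are sklearn transformers and compose in an sklearn `Pipeline`.
By default they are fitted on the **training** windows only and applied
frozen to test windows (`preprocessing_fit="train_only"`); a `global`
mode (fit on everything) exists for fidelity experiments, since the
original description is ambiguous about the fit scope. The retained-
variance default is likewise an open choice — the source pipeline's PCA
dimension is unreported — and is surfaced prominently in the config.
Zero-variance strata scale by 1 with a warning; a herd × variable
stratum with no observed values at all is an error, not a silent fill.

## 5. Model benchmark

Seven model families, addressed by their conventional names:

| name | family | tuned hyperparameters |
|---|---|---|
| glmnet | elastic-net logistic regression | C ∈ log[1e−3, 1e2], l1_ratio ∈ [0, 1] |
| rf | random forest | max_features ∈ [0.05, 1]; 300 trees fixed |
| svmRadial | RBF-kernel SVM | C ∈ log[1e−2, 1e3], γ ∈ log[1e−4, 1] |
| bayesglm | weak-prior (L2-regularized) logistic regression | none |
| nn | single-hidden-layer MLP | units ∈ [2, 16], α ∈ log[1e−4, 1] |
| knn | k-nearest neighbours | odd k ∈ [3, 31] |
| pls | PLS discriminant analysis | components ∈ [1, 10] |

PLS-DA is a thin classifier over PLS regression of a 0/1 class coding,
thresholded at 0.5 — the standard construction. Behavioural equivalence
with any particular R implementation is explicitly not a goal; the
benchmark is validated by properties (determinism, separable-data
sanity, permutation-null calibration), not by matching published tables.

Tuning is uniform **random search capped at a small budget** (default
10 points; finite spaces deduplicated), scored by mean fold-wise **TPR**
(positive class TB) under k-fold resampling of the training windows,
default k = 200, clamped with a warning when the training set is
smaller. Folds with no positive example contribute a missing TPR and
drop out of the mean. The winning point is refit on the full training
set; its fold-wise TPR vector (the *resampling profile*) is retained.
A k of 200 makes each validation fold 0.5 % of the training set; the
stated-elsewhere "1 %" does not match 1/200 and the k is what is
implemented. Optimizing TPR alone is deliberate (missed outbreaks are
the expensive error) but can select trigger-happy configurations; the
confusion report always carries TNR and PPV so this is visible.

## 6. Evaluation

Two split regimes with opposite leakage behaviour:

* **CV** — random window-level 75/25 split, stratified by class (with
  ~18 % TB prevalence an unstratified 25 % test set can lack positives
  entirely, leaving TPR undefined). Windows of one pen, overlapping in
  time, may appear on both sides: this estimates performance when a
  model is continuously updated with the pen's own history.
* **LOOP** — pen-held-out: ~25 % of pens, sampled within (herd, status)
  strata, contribute all their windows to the test side. Pen
  disjointness is asserted on every run. A strict single-pen mode
  exists. The number of pens per held-out fold is not specified by the
  source design; grouped hold-out matching the stated "randomly
  selecting pens" reading is the default.

Reports: confusion matrix with TB positive; TPR, TNR, PPV, accuracy;
exact Clopper–Pearson 95 % CI on accuracy; Cohen's kappa
(κ = (p_o − p_e)/(1 − p_e) with the standard two-class chance term) and
its Landis–Koch band; the no-information rate (majority-class accuracy);
and a one-sided exact binomial p-value for accuracy exceeding the NIR —
the conventional sharpening of "does the model beat always-predicting-
CTL". Ratios with zero denominators are reported missing, never 0.

Model-to-model comparison: paired t-tests on fold-wise TPR differences
of profiles sharing a fold structure (missing folds dropped listwise),
Bonferroni-adjusted by the number of pairs (21 for 7 models). Identical
profiles short-circuit to p = 1.

**Null calibration is regime-dependent.** Because a TB pen's windows
inside the TB window are labeled TB *by construction*, pen identity
alone predicts the label above chance even when behaviour carries no
signal at all. With heterogeneous pens, a window-level CV split
therefore cannot serve as a null reference: a classifier that merely
recognizes pens (and TPR-driven selection rewards exactly that) shows
substantially positive kappa on null data. Calibration is meaningful,
and is tested, in the pen-held-out regime, where pen recognition is
impossible and null kappa concentrates at 0. Likewise, "no difference
between models" is a true null only for profiles sharing a
distribution; different model families differ in their chance-level
fold TPR, so cross-family rejections on null data are real differences,
not false alarms.

The sensitivity sweep re-runs the full pipeline over a grid of analysis
window sizes {7, 14, 21} × TB windows {[−35,10], [−49,10], [−10,5]}
with identical seeds, one row per (cell, regime).

## 7. Problem sizes and numerical choices

The default herd profiles are full-size (42 + 23 pens). Tests and the
acceptance script run **scaled** conditions chosen as the package's own
desk-scale study design: 6–8 pens per herd (half TB), recording
half-spans of 42–63 days, 10–15 pigs per pen, 2 % recorder-gap rate,
resampling folds 2–8, search budgets 1–3, and forests of 100 trees with
max_features 0.3 (the tuned-space midpoint). Pens below 10 pigs are kept
the exception in these scaled profiles, mirroring the stated rarity of
under-10-pig pens in the emulated herds. The drift is always the default
above. Seeds are fixed in the tests; every simulation, split, and search
is a pure function of (config, seed).

Other numerical conventions: sample SDs use the n−1 denominator
throughout; imputation/scaling statistics are computed over all cells of
a variable within a herd (not per column), so the 30 columns of one
variable share one stratum; PCA uses a full SVD; hyperparameter ties
resolve to the first-sampled candidate; kappa is missing when both
vectors are constant and equal (p_e = 1).

## 8. Known limitations

* The generator's drift is a smooth multiplicative ramp; real outbreaks
  are heterogeneous and sometimes abrupt. Boundary windows — a_dates
  just outside the TB window whose 14 days overlap the ramp — are
  labeled CTL while genuinely abnormal, which bounds the achievable TNR
  of local distance-based classifiers (visible as kNN false positives
  concentrated at the label boundaries).
* Marginal moment calibration is approximate under drift and trends;
  only control-class moments are targeted exactly.
* The CV regime's optimism is a feature being studied, not corrected
  for; none of the reported CV metrics should be read as deployment
  performance on new pens — that is what LOOP estimates.
* With 200-fold resampling on small training sets, many folds lack
  positives and are excluded from tuning means; at very small n the
  profile carries few usable folds.
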