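# Methods

## Problem setting

Chronic kidney disease (CKD) screening from routine clinical tables is a
binary classification problem on small, messy data: a few hundred records,
two dozen mixed numeric/categorical attributes, heavy missingness (~10% of
cells), token-level typos (tab- and space-polluted category labels),
extreme laboratory values, and class imbalance.  `ckdso` packages the three
stages such a study needs — leakage-safe table preparation, wrapper feature
selection driven by a snake-optimization (SO) metaheuristic, and a
classifier evaluation harness — together with a synthetic cohort generator
so that every stage can be validated against known ground truth without any
external download.

## Preparation pipeline

All statistics are fitted on the training partition and frozen into a
`PrepState`; held-out data are transformed only.  Stage order:

1. token cleaning (typo map: whitespace stripping, level canonicalisation)
   and numeric re-kinding of mis-typed columns (`pcv`, `wc`, `rc` in the
   bundled clinical schema),
2. stratified shuffled 80/20 split,
3. imputation — numeric: training mean; categorical: backward fill on the
   training partition (a missing cell takes the next observed value in row
   order, trailing gaps take the previous one),
4. local-outlier-factor (LOF) screening on five configured columns
   (defaults `age, hemo, pcv, rc, sg`), training partition only,
5. exact-duplicate removal (training only),
6. 0/1 encoding (binary categoricals become one indicator; wider ones one
   column per training-observed level; unseen held-out levels produce a
   zero vector and a report entry),
7. SMOTE oversampling of the training minority class to exact balance,
8. z-scoring with training moments, population SD (`ddof=0`); constant
   columns map to 0 with a warning.

Splitting *before* any fitting is deliberate: preparing first and splitting
afterwards would leak held-out information into imputation values, scaler
moments and the resampler.  Two stages deserve notes:

* **Backward fill on held-out data.**  Literal backfill inside a test
  partition would consult other test rows.  We therefore use the training
  column's modal level for held-out missing categoricals; the training
  partition itself keeps the literal fill.  The fill is defined on input
  row order and is order-sensitive by construction.
* **LOF flagging rule.**  Scores follow the standard definition
  (k-distance neighbourhood with ties included, reachability distance,
  local reachability density `lrd = 1/(mean reach + 1e-10)`, score = mean
  neighbour-to-self density ratio, Euclidean metric, default k=20).  The
  columns are centred and scaled by their population SD before scoring so
  units do not dominate the metric.  Because no principled score threshold
  exists for small cohorts, the top `ceil(contamination * n)` rows by score
  are removed; the default contamination 0.065 corresponds to roughly 26
  flagged rows in a 400-row cohort.  The 1e-10 density regulariser keeps
  duplicate-heavy data finite and matches the reference implementation the
  tests compare against to 1e-9.

SMOTE is implemented directly from its definition: each synthetic row is
`x + u (x' - x)` with `u ~ Uniform(0,1)`, `x'` one of the `k=5` nearest
minority neighbours of a uniformly chosen minority row `x`, all draws from
one seeded generator.  Synthesised rows are therefore verifiably convex
combinations of two real minority rows, which the tests exploit.

## Snake-optimization feature selection

Each snake occupies a continuous position in `[0,1]^d`; a coordinate above
the box midpoint selects the corresponding feature (an all-below position
falls back to its maximal coordinate, so masks are never empty).  The swarm
of `Num` snakes (first half male, second half female) is driven by two
schedules over iterations `n = 1..N`:

    Q(n) = C exp((n - N)/N),   C = 0.5      (food quantity)
    T(n) = exp(-n/N)                         (temperature)

* `Q < 0.25` — **exploration**: each snake moves relative to a random
  same-sex snake, `Y' = Y_rand ± c2 · Bs · ((y_max - y_min)·rand + y_min)`
  with `c2 = 0.05` and the food-finding ability `Bs = exp(-f_rand / f_i)`
  (fitness values shifted positive before the ratio; exponent clamped).
* `Q ≥ 0.25`, `T > 0.6` — **approach food**: snakes jump around the
  incumbent best, `Y' = Y_food ± c3 · T · rand · (Y_food - Y)`, `c3 = 2`.
* `Q ≥ 0.25`, `T ≤ 0.6` — **fight**: males move toward the best female
  with capability `MF = exp(-f_best_female / f_i)` and symmetrically for
  females; optionally a **mate** event (probability 0.5 per iteration,
  off by default) resamples the worst snake of each sex uniformly, which
  restores diversity late in a run.  Whether mating was active is recorded
  in the run history.

Positions are clipped to the box after every update; a single seeded
generator drives all draws, so runs are bit-reproducible.  Incumbents
(best male, best female, best overall) update only on strict improvement —
ties keep the earlier holder — which makes the best-fitness trace
non-increasing by construction.  Since `Q` is monotone, exploration never
reappears once exploitation begins.

The wrapper objective, minimised, is

    f(mask) = ω · (1 - CV accuracy on selected columns) + (1-ω) · |mask|/d

with stratified k-fold cross-validation of a configurable base classifier
(default extremely-randomized trees, 5 folds) and default ω = 0.99.
Evaluations are memoised by mask bits.  The API reports both the objective
and its quality complement `1 - f`, so "best" is unambiguous even though
the optimum is a minimum.

### Wrapper overfitting and the recovery experiment

A wrapper selector can overfit the *realized* fold noise: with n samples
and r repeated fold assignments, CV accuracy moves in quanta of `1/(r·n)`,
and a noise feature whose sample correlation with the label happens to be
non-zero can buy one quantum and enter the mask.  The planted-feature
recovery experiment (tests and acceptance script) therefore uses:

* an SVM (RBF) wrapper — distance-based, so irrelevant dimensions dilute
  the kernel and genuinely reduce CV accuracy, unlike tree ensembles which
  can even benefit from extra split candidates;
* 5-fold CV averaged over 2 fold assignments (`cv_repeats = 2`);
* ω = 0.95 chosen by the rule `(1-ω)/d > 1/(r·n)`: the parsimony penalty
  for one feature (0.0025 at d = 20) must exceed one quantum of empirical
  accuracy (1/600 at n = 300, r = 2), otherwise selection cannot resist
  single-sample luck;
* population 40, 150 iterations, mate step enabled.

Experiment conditions: cohorts of n = 300 with 5 informative and 15 noise
features, a 2-SD class-conditional mean shift on every informative feature,
minority fraction 0.4, five seeds.  Under these conditions the selector
recalls ≥ 80% of informative features with ≤ 30% noise inclusion on
average; the acceptance script recomputes both rates.

## Evaluation harness

The confusion matrix takes CKD as the positive class.  Reported metrics:
accuracy, sensitivity TP/(TP+FN), `specificity_printed` TP/(TP+FP) — kept
under that name because the framework's evaluation sheet prints this
(precision) formula as specificity — alongside the textbook
`specificity_standard` TN/(TN+FP), FDR FP/(FP+TP) and F-score
2TP/(2TP+FP+FN).  Zero-denominator metrics surface as NaN markers rather
than silent zeros so degenerate folds cannot hide in aggregates.  ROC
curves come from a threshold sweep with tied scores grouped; AUC is the
trapezoidal area and equals the normalised Mann–Whitney statistic, which
the tests verify.  `kfold_cv` refits the scaler inside each training fold
(a pipeline), so fold evaluation is leakage-free, and `train_and_eval`
always labels metrics with their partition.

The two reference network topologies are carried as layer specifications
with parameter accounting (`dense` from `d` inputs to `u` units contributes
`u·(d+1)`; dropout and concatenation contribute nothing): an input(24) →
dense(32) → dense(32) trunk that splits into two mirrored
dropout(0.01)/dense branches, concatenated into a softmax(2) head; and a
strictly sequential eight-layer stack, also ending in softmax(2).  Hidden
widths are configurable (defaults 32-wide branches; 32/64/32/16 for the
sequential stack) and hidden activations are rectifiers; the attached
training contract is Adam, binary cross-entropy, 50 epochs, batch size 10.
Actually *training* these specifications requires registering a neural
backend via `register_network_backend`; none is bundled, and a clear
capability error is raised otherwise.  The three classical classifiers
(SVM, extremely-randomized trees, gradient-boosted trees) are always
available and are the evaluation surface.

## Synthetic cohorts

`synth.generate_cohort` draws numeric informative features from
class-conditional normals separated by `effect_size` SD (default 2.0),
binary informative features from class-dependent Bernoulli(0.8/0.2), and
noise features independently of the class, then injects — in order, each
fully logged with coordinates — duplicate rows (same-class copies, so
class counts stay exact), outlier rows (±8 SD shifts in the LOF-screened
columns), whitespace/tab typos on categorical tokens, and
missing-completely-at-random cells.  Defaults mirror the clinical table
the framework targets: 400 records, 24 features, 10% missing cells, ~1%
typos, 26 outlier rows, 37.5% minority.  `replay` re-applies the log to
the pre-corruption cohort and must reproduce the dirty table exactly; the
preparation report can therefore be checked cell-for-cell against ground
truth.

What the generator does *not* model: informative missingness (real CKD
tables plausibly miss labs more often for healthier patients; no mechanism
is documented, so missingness is MCAR), column-specific marginal
distributions of the real attributes, and correlated noise between
features.  Passing the recovery tests therefore demonstrates correctness
of the machinery under clean planted-signal conditions, not expected
performance on any particular real cohort.

## Numerical choices and degenerate inputs

* Population SD (`ddof = 0`) throughout standardisation; σ = 0 columns map
  to 0 with a warning.
* LOF densities regularised by 1e-10; LOF requires imputed data and
  n ≥ k+1 rows.
* Ability ratios: fitness shifted positive by the pair minimum plus 1e-12,
  exponent clamped to ±700.
* Binarization ties (coordinate exactly at the midpoint) are not selected;
  an empty mask falls back to the maximal coordinate, index ties resolved
  to the first.
* CV folds shrink automatically when a class is smaller than the fold
  count; a class below 2 is an error.
* SMOTE requires the minority class to have at least k+1 members and is
  the identity on balanced data.

## Known limitations

* The held-out categorical fill (training mode) is a deliberate deviation
  from literal backfill; columns with no clear modal level get the first
  by code order.
* The selection result depends on the wrapped classifier; tree-ensemble
  wrappers tolerate (and sometimes reward) noise features, which is why
  the recovery experiment wraps an SVM.
* Network specifications are contracts plus parameter accounting, not a
  training implementation.
* The optimizer treats features marginally through a box threshold; masks
  whose value is purely interactive (XOR-type signal) are found only
  through the CV signal of the wrapped classifier.
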