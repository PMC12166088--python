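# Methods

## The recommendation model

`pdcrec` predicts a new patient-derived culture's response to library drugs
from (i) a small probing panel actually screened on that culture and (ii) a
historical cell-line × drug response matrix. Let `A ∈ R^{m×p}` be the
historical matrix (m cell lines, p drugs) on the activity scale, `P` the
panel (|P| drugs, all measured on the new culture), and `y_d` the new
culture's measured activity for panel drug `d`.

Each drug is represented by its bioactivity fingerprint across the
historical cohort: feature vector `x_d = A[:, d] ∈ R^m`. A regression
ensemble `f` (random forest, 50 trees, implementation defaults otherwise;
gradient boosting available) is fitted on `{(x_d, y_d) : d ∈ P}` and applied
to every non-panel library drug; the library is ranked by `f(x_d)` under the
scheme's direction (higher pIC50 / inverse log2 fold-change is better; lower
viability is better). Predicted hits reuse the measured-hit rule on
predicted activities — no separate cutoff is introduced.

The setup assumes that drugs with similar response profiles across the
historical cohort act similarly on the new culture, i.e. cross-cell-line
response structure is low-dimensional enough that |P| ≪ p samples constrain
it. Tree ensembles cannot extrapolate beyond the panel's target range, so
predictions are bounded by the panel's min/max activity; panels must
therefore contain both active and inactive drugs to resolve the top of the
library (one reason diversity selection helps).

Feature importances of the fitted forest (normalised to sum to 1) quantify
which historical cell lines drive predictions; `tissue_composition` tallies
the tissues of origin among the top-k most influential lines. With a
constant target vector the forest has no splits; predictions equal the
constant, importances fall back to uniform, and the result is flagged
low-confidence.

## Activity schemes and hit rules

| scheme | transform | hit rule | better |
| --- | --- | --- | --- |
| `gdsc_pIC50` | pIC50 = log10(1 / IC50 [M]) | > 6 (IC50 ≤ 1 µM) | higher |
| `prism_neglog2fc` | −log2(fold-change) | > 1.7 | higher |
| `viability_percent` | identity (% of DMSO control) | ≤ 30 | lower |

Boundary conventions are deliberate: the pIC50 and fold-change rules are
strict (> threshold), the viability rule inclusive (≤ 30). log-transforms
with base 10 and molar units follow from the 6 ↔ 1 µM correspondence.
Non-positive values under a log transform and negative viabilities are
rejected with their locations.

## Pruning

Cell lines are filtered first (against the full drug set), drugs second
(against the remaining cell lines); limits are "strictly more than" in
either fractional or absolute mode. Conventional presets: 20%/20% for dense
IC50 panels, 10%/20% for the large repurposing screen, absolute 5/5 for the
small ex vivo screen. Pruning is idempotent and never mutates its input.

## Data completion

Training matrices must be complete before the per-drug feature vectors can
be built. Two methods:

* **zero-fill** — missing activities become 0, i.e. "inactive" on the log
  activity scales; cheap and conservative.
* **TML imputation** — for each drug with gaps, a
  `GradientBoostingRegressor(n_estimators=50, max_depth=1)` is fitted on the
  cells where the drug was measured, with features taken from all *other*
  drugs having fewer than 20 missing entries (their own gaps zero-filled),
  and predicts the missing cells. Each drug is modelled from the original
  matrix; freshly imputed columns are never chained as features. Drugs with
  no observations or no eligible features fall back to zero-fill with a
  warning.

Feature-drug missingness is counted *after* removing held-out cells, which
are excluded everywhere: never used as samples, never filled, returned
untouched. Observed entries are bit-identical before and after either
method. Per-drug learner seeds are derived by hashing (seed, drug id) so
column order cannot alter results; note that with the boosted ensemble's
default full-sample fitting the procedure is deterministic even across
seeds.

## Panel selection

The diversity sweep removes redundant entities along one axis:

1. drop the lowest-variance entities, keeping `variance_keep_fraction`
   (variance over non-missing entries; ties broken by id);
2. Pearson correlation matrix over survivors, pairwise-complete; pairs with
   fewer than 3 common observations, or a zero-variance member, get r = 0;
3. rank survivors by median correlation to the others, ascending (ties by
   id);
4. walk the ranking: each not-yet-excluded entity becomes a reference and
   excludes every remaining entity with correlation ≥ the threshold.

References in processing order are the panel; every selected pair therefore
correlates strictly below the threshold. The comparison is inclusive (≥) so
that duplicated entities (r = 1) collapse even at threshold 1.0.
`fit_panel_to_size` bisects the threshold (60 iterations on [0, 1]) until
the sweep returns at least the target size, then truncates in processing
order; if even threshold 1.0 cannot reach the target, the maximum achievable
panel is returned with a warning. Random selection is a uniform draw without
replacement from a seeded generator.

## Evaluation

All metrics are computed on the *evaluable* set: non-panel library drugs
with a finite measurement for that cell line. Rankings break activity ties
by drug id, making every metric deterministic.

* **top-n overlap** — |top-n(predicted) ∩ top-n(measured)| / n, positions
  within the top-n ignored (7 of 10 → 0.70). Symmetric in its arguments.
* **top-k hit rate** — the count of true hits among the k best-predicted
  drugs, reported alongside the theoretical maximum min(k, hits available).
  Cell lines with no hits available are non-evaluable for hit analysis and
  are reported both ways (averaged over all cells, and over evaluable cells
  only, suffix `_evaluable`).
* **regression metrics** — Pearson r, Spearman r (scipy), RMSE; at least 3
  pairs required; zero-variance sides yield NaN correlations.
* **subsets** — every cell line is scored on the full library and again on
  the selective drugs (hit prevalence < 20% among non-missing measurements
  of the reference cohort), with the subset's baseline prevalence attached.

Aggregation follows the repeated-experiment convention: per-repeat means
over cell lines (NaN-ignoring), then mean and population std (ddof = 0, so
a single repeat reports std 0) across repeats.

## Experiment protocols

**Hold-out** (`run_holdout`): per repeat r, cells are partitioned
80/10/10 (largest-remainder rounding; seeded permutation with seed
`seed_base + r`); the training matrix is completed (held-out cells excluded
by construction); the probing panel is chosen on the completed training
matrix (diversity by default, target size 30) and the historical cohort is
drawn at random (100 cells by default); each test cell is recommended for
from its measured panel entries only and scored on its remaining
measurements. Panel drugs missing on a given test cell are dropped from
that cell's panel with a warning. Every random draw (split, panel, cohort,
forest) is seeded from the repeat seed, so runs are bit-reproducible.

**Leave-one-out** (`run_leave_one_out`): for each cell line and each drug
measured on it, the drug is predicted from the cell's remaining measured
drugs (the panel) and the completed matrix of all other cell lines,
assembling a full predicted profile per cell. Per-cell outputs: Spearman R
over the measured library, mean measured activity of the library and of the
top-5 predicted drugs, and hit counts (available / predicted / identified,
with identified ≤ min of the other two). `hit_precision` is
identified/predicted and `hit_recall` identified/available, averaged over
cells with at least one hit available. Cells with fewer than 3 measured
drugs are skipped. Repeats vary only the stochastic components. A
`predictor` hook allows substituting the forest (used in tests to inject
oracles).

## Synthetic screens

The generator produces the minimal structure the recommender exploits:

* cell factors `u_i = c_{t(i)} + e_i` with tissue centroids
  `c_t ~ N(0, s·I_k)` and individual deviations `e_i ~ N(0, (1−s)·I_k)`
  (`s` = `cluster_strength`, `k` = `latent_rank`);
* drug factors `v_j ~ N(0, I_k)`; surface `Z = U Vᵀ/√k`, standardised;
* calibration: `Z` is shifted so that exactly a `target_hit_prevalence`
  fraction of entries falls on the active side of the scheme's threshold
  (quantile shift), then scaled to `activity_scale` (1.0 on log-activity
  scales, 25 viability points); viability surfaces are clamped at 0;
* observation: Gaussian noise (`noise_sd`) and a uniform missing-at-random
  mask; the returned truth (factors, noiseless surface, true hits, tissue
  labels) is noise-free and complete.

Default conditions were fixed once to emulate pruned public screens at desk
scale: 300 cells × 300 drugs, rank 6, 5 tissue clusters sharing half the
factor variance, noise at 10% of signal SD, 10% missingness, and
family-specific prevalences (17.8%, 13.2%, 5.2%). `make_rx_like` emits a
synthetic 24 × 35 viability screen (prevalence 4.36/35 ≈ 12.5%, noise 3
viability points, 4% missingness capped at five entries per row and column
so absolute 5/5 pruning leaves it unchanged) as a stand-in for small ex vivo
datasets in leave-one-out tests.

What the generator does **not** emulate: dose–response curve shape (values
arrive as summary activities), block missingness (a drug untested at an
entire site), batch effects, and the strong right-skew of real viability
distributions — real ex vivo libraries cluster near 100% viability with a
small active tail, whereas the symmetric latent surface spreads mass on
both sides of the threshold, so library-mean viability of the synthetic
screen is lower than in real screens. Passing tests therefore demonstrate
correct mechanics and recoverability of planted structure, not clinical
performance.

## Numerical choices and problem sizes

* Ties anywhere (variance, median correlation, rankings, importances) break
  by lexicographic id; determinism is a hard requirement.
* Sub-seeds derive from a BLAKE2 hash of labelled parts (below 2³¹), so
  results do not depend on iteration order.
* Correlations with fewer than 3 paired observations are treated as 0 in
  panel selection; regression metrics instead require ≥ 3 pairs outright.
* The acceptance script runs the hold-out protocol at 300 × 300 with five
  repeats and the leave-one-out protocol at 24 × 35 with five repeats —
  sizes chosen as the smallest at which the pipeline's behaviour (rank
  transfer, hit enrichment, selective-drug degradation) is stable across
  seeds.
* Panel size interacts with library size: on small noiseless screens a
  12-drug panel plateaus near Spearman 0.85, while 30 drugs exceed 0.93;
  the recommender cannot rank what the panel's activity range does not
  span.

## Known limitations

* Tree ensembles interpolate: a new culture more sensitive than every panel
  drug suggests cannot be ranked above the panel's best observed activity.
* TML imputation models drugs independently; correlated missingness across
  drugs is not exploited.
* The diversity sweep optimises redundancy, not information about any
  particular new culture (no optimal-design criterion).
* Immunomodulatory and microenvironment-dependent drugs fall outside what
  cell-autonomous response profiles can capture; nothing in the model
  corrects for that.
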