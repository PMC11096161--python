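# Methods

## The comparison being made

The package studies one question on horizontally partitioned tabular data:
how a *distributed* model — a weighted soft-voting ensemble of models
trained independently inside each of nine data silos — compares with the
silo-level *local* models and with a *centralized* model trained on the
pooled data. The distributed model sees no raw rows: its inputs are the
fitted member models and one scalar training score per member.

For members $i = 1..m$ with training scores $s_i$, weights are
score-proportional, $w_i = s_i' / \sum_j s_j'$ where $s' = s - \min(s)$
when any score is negative (regression scores are negative MAE). All-equal
or all-zero score vectors fall back to uniform weights. The ensemble output
is the convex combination of member outputs, so every prediction lies in
the members' convex hull; predicted labels are the arg-max with a
lowest-class-code tie-break. Federated and peer-to-peer aggregation differ
only in where the weight computation runs; the package simulates both and
asserts they coincide.

The score-proportional rule is the simplest mathematics consistent with a
"weighted soft vote whose weights come from training-set scores"; because
scores are shifted by the minimum, the weakest member of a regression
ensemble receives weight 0 (documented behaviour, not a bug). Weights are
deliberately *not* sharpened (e.g. softmax with temperature); no claim of
optimality is made.

## Pipeline stages and fixed parameters

| parameter | default | meaning |
|---|---|---|
| sparse_drop_fraction | 0.90 | drop a column when its pooled missing fraction is **strictly** above this |
| target_null_fraction | 0.50 | select a target when its pooled missing fraction is **strictly** below this |
| missing tokens | `-1`, `missing`, `""` | raw dialects unified to one marker (trimmed, case-insensitive) |
| min_class_count | 25 | per-class floor after repair; guarantees ≥2 instances per split of 2×10 stratified CV |
| smote_neighbors_cap | 5 | SMOTE uses k = min(5, c−1) same-class nearest neighbours |
| CV layout | 2 repeats × 10 splits | training-score estimation |
| n_repetitions | 10 | stochastic train/test repetitions per silo (3 in desk-scale runs) |
| test_fraction | 0.2 | held-out share per silo per repetition |
| alpha | 0.05 | two-sample t-test significance level |

Boundary conventions follow the words "more than 90%" and "below 50%":
both thresholds are strict, and the drop/selection fractions are **pooled**
over the concatenated silos, not per-silo. The ordinal vocabulary is the
lexicographically sorted union of categories over all silos with the
imputation category `NULLIMP` coded last; the same map is applied to every
silo and to the pool, so identical raw categories always share a code. An
unmapped category at encode time is a loud error naming column, category
and silo — the central hazard of multi-site training is an unknown class,
and it must never be silently absorbed. The token `-1` is treated as
missing only in token-sensitive columns (all, by default) so that data
with legitimate negative numerics can opt columns out.

Within-site imputation uses the silo's own column mean; a column entirely
missing within one silo falls back to the cross-silo mean with a logged
warning. Imputation is idempotent and row-conserving.

### Class repair

Per training session and per classification target: classes absent from a
silo receive `min_class_count` identical dummy rows (within-silo mean /
modal code predictors); classes with count `c < 25` are raised to exactly
25 by SMOTE interpolation `x_i + u (x_nn − x_i)`, `u ~ U(0,1)`, on the
ordinal-encoded matrix. Singleton classes are duplicated (interpolation is
undefined). Interpolated categorical codes are rounded to the nearest
integer code, which keeps every coordinate inside the parents' range, so
the convexity check remains exact coordinate-wise. The dummy-row count (25)
is chosen so repaired classes also satisfy the CV-coverage argument; both
repairs add information that is not in the silo, and the `PrepReport` and
the logs say so whenever they fire. SMOTE is implemented in the package
(the interpolation rule above, with scikit-learn's `NearestNeighbors` for
the neighbour search); no SMOTE-NC variant is used, matching the uniform
ordinal encoding of the pipeline.

### Learners

Six families, fixed library-default hyperparameters, no tuning: decision
tree; Gaussian naive Bayes (classification) with Bayesian ridge as the
regression analogue of the Bayesian family; logistic regression by SGD /
SGD regression; k-NN (k = 5); AdaBoost (50 estimators); MLP with one
100-unit hidden layer (a deliberately modest network — underfitting is an
accepted property, not a target of optimisation). Scale-sensitive learners
(SGD, MLP, k-NN) run behind a standard scaler. The training score is the
mean held-out metric over the 2×10 CV; the deployed model is a refit on the
full training partition (keeping one of the 20 fold models would be
arbitrary).

### Metrics

Weighted one-vs-rest AUROC uses the Mann–Whitney rank formulation with
midrank ties; weighted AUPRC uses step-wise average precision
$\sum_k (R_k − R_{k−1}) P_k$ over distinct score thresholds. Both average
per-class values with true-class-prevalence weights; classes absent from a
test slice are skipped and the weights renormalized (the alternative —
scoring absent classes 0 — would punish a model for the slice's
composition). A metric undefined on a slice (a single distinct true class)
is recorded as NaN and excluded pairwise downstream, with undetermined
cells counted, never silently dropped. Both metrics are verified against
brute-force oracles (O(n²) pair counting; threshold-sweep AP) and against
scikit-learn on tie-free fixtures.

### Leakage regimes

The literal protocol ordering builds the distributed and centralized models
once per target *before* the per-repetition splits, letting them train on
rows later held out. The default mode (`per_rep_retrain`) retrains all
three model kinds inside each repetition and asserts, by global row-id
bookkeeping, that no test row of any silo enters any training partition of
its own repetition. `paper_literal` reproduces the literal ordering for
comparison. Seeds stream from the master seed into per-(target, algorithm,
silo, repetition) substreams, so any grid cell is reproducible in
isolation; splits and class repair are shared across algorithms within a
(target, repetition).

### Comparison statistics

The relation machinery uses the pooled-variance Student t (the
conventional reading of a "standard independent two-sample t-test"); Welch
is available by flag. Identical constant samples give (t=0, p=1, equal);
constant samples with different means give p=0 and the mean decides. The
driver metric per contingency cell is AUROC (classification) and MAE
(regression). 95% CIs use the normal approximation mean ± 1.96·SD/√n. No
multiple-testing correction is applied across the >1000 cells, matching
the protocol being reproduced; a Holm adjustment is exposed but off by
default. Under a simulated true null the "equal" relation frequency is
95% ± 3 points (verified at 1000 cells × 10 repetitions).

## The synthetic generator

The generator emulates a nine-hospital obstetrics extract: silo sizes
(8039, 8566, 4989, 2364, 18177, 12002, 8258, 6693, 11786 — 80,874 rows at
scale 1), ~36 mixed columns whose marginal means/SDs and category counts
sit in the ranges of the source silos (mother's age ≈ N(31.1, 5.6²), BMI ≈
N(25.1, 7²), blood group with 14 levels, …), per-column missing rates that
leave exactly 13 categorical and 6 continuous columns under the 50% target
filter, six columns above the 90% drop line, a globally rare Robson-group
class (15 intended instances), and one delivery-type class withheld from
silo 3. Missing cells carry a token drawn uniformly from the silo dialect
(`-1`, `missing`, blank).

Only marginal summaries of the real data are public, so silos are
independent silo-shifted marginals — Gaussian for continuous columns,
multinomial for categorical — with an explicit latent signal layer: a few
designated targets are driven by standardized predictor combinations
through a linear (continuous, R² ≈ 0.5–0.6) or multinomial-logit
(categorical) link, so models can beat chance and the three-way comparison
is non-trivial. Silo shift perturbs continuous means and categorical
log-odds by `shift_strength × SD` (default 0.3; 0 gives IID silos for
degeneracy tests). The master seed streams into per-silo, per-column
substreams, so editing one silo's profile leaves the others byte-identical,
and generation is a pure function of the config.

What the generator does **not** emulate: joint dependence beyond the
signal layer, clinical plausibility of obstetric co-occurrences, temporal
structure, or informative missingness (masking is independent of values).
Passing tests therefore demonstrate that the machinery is correct and that
the distributed-vs-centralized comparison behaves as theory predicts under
controlled heterogeneity — not that any clinical effect size would
reproduce on real hospital data.

## Problem sizes used in the shipped runs

Desk-scale runs use scale 0.02 (1,618 rows across nine silos, 47–364 per
silo), three targets (one binary, one 8-level categorical, one continuous),
the three fastest learner families (SGD, NB, DT) and three repetitions —
81 comparison cells, chosen as the smallest design that still exercises
every stage including multi-class repair, absent-class handling and both
task types. The full design (six algorithms × nineteen targets × nine
silos = 1026 cells) is enumerated analytically and exercised per-stage.

## Known limitations

* Ordinal encoding imposes an artificial order on nominal categories; the
  pipeline accepts this (uniformly across all model kinds) rather than
  one-hot expanding, trading bias for dimensionality.
* Dummy rows and SMOTE inject synthetic information; with very small silos
  and many-class targets the repaired training set can be dominated by
  synthetic rows. The `PrepReport` quantifies this per session.
* The score-proportional weight rule is one defensible reading of a
  weighted soft vote; alternatives (rank-based, softmax) are not explored.
* The normal-approximation CI understates width at small n; with n ≥ 54
  records per summary row the error is negligible for reporting purposes.
* Generated data cannot validate clinical conclusions; see the generator
  section above.
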