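# Methods

This note documents the models, conventions and design choices behind
`gaitpath`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A subject is a set of 12 functional foot angles (Heidelberg Foot
Measurement Method vocabulary, `gaitpath.angles.CANONICAL_ANGLES`), each
carried as a stride-averaged **mean** series and a stride-variability
**std** series on a fixed 101-point grid over 0–100 % of the gait cycle,
plus the foot-off timing (mean and std, % cycle) and a condition label.
Series are assumed already cycle-normalized and stride-averaged; no
resampling or smoothing is performed. Missing grid values are NaN in
memory and empty cells on disk. Cohort files are long-format CSV with a
row-count checksum footer so truncated files are rejected rather than
silently accepted.

## Derived series

Per angle, two series are derived from the mean series `U`:

* first gradient `V[k] = (U[k+1] − U[k−1]) / 2`. The central difference
  is undefined at the grid endpoints; `V` therefore lives on k = 1…99 and
  phase windows are intersected with that domain rather than padded with
  invented one-sided values.
* deviation from normative `DN[k] = |U[k] − U_norm[k]|`, with `U_norm`
  the per-angle, per-point arithmetic mean over typical-feet subjects.
  In the default leakage-safe mode `U_norm` is computed from the training
  partition only.

## Feature scheme

The cycle is split at `r = round-half-up(foot_off_mean)` into stance
`[0, r]` and swing `[r, 100]`. The boundary index belongs to both phases:
the foot-off instant ends stance and starts swing, and sharing it removes
empty-window edge cases. Per angle: 4 statistics (max, timing of max,
min, timing of min) on the mean and gradient series, 2 on the std series,
5 on the deviation series (the four plus its phase average), per phase,
plus one full-cycle range of motion on the mean series — 31 per angle,
372 over 12 angles, 374 with the foot-off mean and std. Timings are
reported in % gait cycle (equal to the grid index on this grid) and ties
go to the earliest occurrence, which is deterministic and
order-independent. Feature names are encoded
`angle|series|phase|statistic` (bijective with the tuple) and decoded to
clinical prose (e.g. "Timing of Min of First Gradient of Tibiotalar
flexion (Stance)") in reports.

## Preprocessing

Missing series values are filled with the median (middle-pair average for
even counts) of the other training subjects' values at the same grid
index — per condition where the subject's label may be used, with a
pooled-median fallback for cells a small class never observed. Test
subjects are imputed with the pooled medians, because a deployed
classifier cannot condition on the label it is asked to predict; a
`paper_mode` applies class-conditional imputation to the whole cohort,
mirroring the retrospective setting this pipeline descends from, which is
leakage-prone and is shipped only for comparability. Imputation never
alters observed values. Features are min–max scaled to [0, 1] with
training-derived parameters; constant training features map to 0 and are
flagged; test values outside the training range are deliberately not
clipped. An optional natural-log transform (after shifting each column
strictly positive) is off by default — skewing the distributions brought
no measurable benefit in the workflow this package implements.

## Feature selection

Two selectors run independently on the scaled training features and their
subsets are intersected (an empty intersection warns and falls back to
the union so the pipeline can proceed):

* RFE-CV with a linear SVM: one feature eliminated per step, ranked by
  the sum of squared one-vs-rest coefficients; the kept subset size
  maximizes mean 5-fold stratified CV balanced accuracy, ties toward the
  smaller subset. Balanced accuracy is used because the cohort's class
  sizes are strongly imbalanced (20–100 subjects per class).
* A random forest (500 trees by default) on all features, keeping those
  with impurity-decrease importance at or above the mean importance. The
  threshold is exposed (`"mean"`, `"median"`, or a float); mean importance
  is the default because no principled cohort-specific value exists.

## Classification

Stratified 0.85/0.15 split, per class: test count = round-half-up(0.15 ×
class size), at least 1, sampled without replacement by a seeded
generator. Four base classifiers with class-probability output:

* SVM with cross-validated sigmoid calibration (3 folds) to obtain
  probabilities for soft voting;
* random forest;
* logistic regression in an explicit one-vs-rest wrapper (consistent with
  the coefficient-based RFE);
* k-nearest neighbours.

Iterative learners use a loss-change stopping tolerance of 1e-4; the
logistic regression is capped at its tuned maximum iterations. SVM, RF
and KNN are tuned by randomized search (default budget 10 draws, 3-fold
CV, balanced-accuracy objective); the logistic regression uses an
exhaustive grid, which its solvers need for stable convergence. A
`preset="paper"` bypasses the search with the hyperparameters tuned on
the original clinical cohort (linear SVM C = 70; RF with 6984 trees, GINI,
depth 40, sqrt features, bootstrap; logistic regression C = 0.7, SAG,
5000 iterations; KNN with Manhattan metric, 6 neighbours, uniform
weights, KD-tree leaf size 10). The default pipeline searches instead of
loading the preset because a 6984-tree forest is a tuning outcome specific
to data this package does not have.

Soft voting predicts `argmax Σ w_m P_m` with ties broken toward the
lexicographically first class label. The weights live on the 4-simplex
and are chosen by randomized search — seeded Dirichlet draws plus the four
vertices and the barycenter, so single-model votes are always considered —
maximizing macro balanced accuracy on an internal stratified 15 %
validation split of the training partition (the base models are fitted on
the remaining 85 %). The weight search needs data the members were not
fitted on; reusing training data would systematically favour the most
overfit member.

Metrics follow the one-vs-rest confusion-count formulas — balanced
accuracy `(TP/(TP+FN) + TN/(TN+FP)) / 2`, recall, precision, F1 — per
class, macro-averaged as the unweighted mean over classes. Ratios with a
zero denominator are reported as 0 and flagged. Note this balanced
accuracy (mean of sensitivity and specificity) is not the same statistic
as scikit-learn's multiclass `balanced_accuracy_score` (macro recall);
the latter is used only as an internal search objective.

Repeated cross-validation (default 3 × stratified 5-fold with fresh seeds
per repeat; leave-one-out available below a size cap, above which the
error message advises k-fold) and learning-curve traces are provided for
model diagnostics. Leave-one-out at the full cohort size is supported but
quadratically expensive, hence the cap.

### Leakage policy

`leakage_safe` (default) fits the normative reference, imputation
medians, scaler and feature selection on the training partition only, and
wraps the held-out labels in an access guard that raises unless opened by
the scoring step — the test suite asserts the guard is opened exactly
once per fit. `paper_mode` performs feature engineering and selection on
the whole cohort before the split, reproducing the stated order of the
retrospective workflow; the two modes genuinely select different subsets
and both are first-class, tested paths.

## Local surrogate explanations

The explainer is a tabular LIME-family method implemented in the package:
per feature, quartile bins of the background (training) table are fitted;
perturbed instances draw a bin by its empirical frequency and a uniform
value within it; instances are weighted by `exp(−d²/w²)` with `d` the
Euclidean distance in background-z-scored units and kernel width
`w = 0.75·√d_features`; a weighted ridge surrogate (α = 1) is fitted to
the model's predicted probability of the target class. The ridge is fitted
on the z-scored design and its coefficients divided by the per-feature
scale, which makes the penalty unit-invariant and the returned weights
exactly equivariant under linear rescaling of the features — explanations
in scaled units equal original-unit weights times each feature's training
span. Explanations are computed and reported in original units, with the
min–max scaler composed inside the prediction function. Constant
background features cannot be perturbed and are excluded (weight 0,
noted). Each explanation targets the subject's **true** condition, and
subjects are sampled without replacement from the full cohort of that
condition (up to 20 per condition); per model, features are ranked by
mean absolute weight — signs are kept in per-subject output but only
magnitudes drive the ranking — and the top five are reported together
with the number of sampled subjects whose personal top-5 contains each
feature. Ties break by canonical feature order.

## Synthetic cohort simulator

The clinical cohort this pipeline was designed around is not publicly
deposited, so the simulator emulates its structure: the reference class
counts (58/64/20/40/41/25 patients + 100 controls = 348), 101-point
series, a foot-off drawn from N(60, 2²) % of cycle, per-class demographics
(age/height/weight, metadata only — they are never classifier inputs),
and injectable uniformly-random missingness (default rate 0.02).

Waveforms: each angle has a fixed 3-harmonic template (constant plus two
sinusoids with angle-specific amplitudes and phases) — smooth, periodic
and cheap; templates are package constants, not fits to real data.
Subjects add a Gaussian offset (sd 1.5°), ±10 % amplitude jitter and
±2 %-cycle phase jitter; std series are |N(1.5°, 0.5°)| envelopes.

Planted condition effects follow each condition's clinical picture:
medial-arch offsets of opposite sign for planovalgus (−8°) and cavovarus
(+8°); forefoot abduction/supination offsets for clubfoot (−10°, +8°);
reduced hallux and tibiotalar motion amplitude for hallux rigidus (×0.45,
×0.70); a subtalar offset (+6°) plus std-envelope inflation (×2.5) for
consolidated calcaneal fracture; reduced tibiotalar amplitude (×0.55)
plus a small medial-arch offset (+4°) for osteoarthritis with ankle
replacement. A timing-shift effect kind (circular shift by % cycle) is
also implemented. Each (subject, effect) pair draws a severity factor
uniform on [0.15, 1.85] (offsets and shifts scale linearly; amplitude
factors are exponentiated): disease expression varies across patients,
some barely expressing one component of their condition. This
heterogeneity is what makes *every* planted angle informative — with
fixed magnitudes a single strongly-expressed angle can make a condition
separable on its own, and a parsimonious selector will rightly discard
the rest. Magnitudes and the severity range are calibrated for signal
recoverability, not biofidelity.

What passing tests on this generator do show: the pipeline recovers
planted, clinically-shaped group differences through the full chain of
imputation, derivation, feature construction, selection, classification
and explanation, reproducibly under seeding. What they do not show:
performance on real HFMM waveforms, whose shapes, covariances,
left/right structure and artefacts the harmonic templates do not model.
Scores on synthetic cohorts (macro balanced accuracy ≈ 0.95 in the
shipped configuration) should not be read as clinical performance
estimates.

## Numerical conventions and problem sizes

* round-half-up for the foot-off index and per-class test counts;
  middle-pair average for even-count medians; first occurrence for
  extremum-timing ties; lexicographic first class for probability ties.
* On-disk values carry 6 decimals; round-trips are exact at that
  precision.
* All randomness flows through explicit seeds (split, selection, tuning,
  models, voting, explanation, simulation); identical configuration and
  seeds reproduce metrics JSON byte-for-byte.
* The test suite runs its multi-seed selection-recovery property on a
  scaled-down cohort (16 per condition, 40 controls) and light search
  budgets in integration tests; the end-to-end checks and the acceptance
  script use the full 348-subject default cohort with 1000-sample
  explanations.

## Known limitations

* The simulator's severity model is independent per effect; real
  condition severity is correlated across joints.
* Class-conditional imputation for test data (paper_mode) requires true
  labels and exists only to mirror the retrospective design.
* SVM probability calibration uses 3-fold sigmoid calibration; with very
  small classes the calibrated probabilities are coarse.
* One record per affected foot; bilateral involvement and left/right
  asymmetry are not modelled.
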