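# Methods

## The analysis model

`repgeom` compares representations — of computational vision models and of
neural populations — at the level of their representational dissimilarity
matrices (RDMs). An RDM over n stimuli is the symmetric n×n matrix of
pairwise dissimilarities between the stimulus-evoked response patterns,
with a zero diagonal. Two dissimilarity metrics are implemented:

- **correlation distance**, d_ij = 1 − r(pattern_i, pattern_j), in [0, 2];
- **squared Euclidean distance of mean-centered, unit-norm patterns**,
  which equals 2(1 − r) and is used wherever the weighted-combination
  algebra matters (see *Reweighting*).

Single-feature representations (classifier decision values) have scalar
patterns, for which a correlation across features is undefined; they are
z-scored across stimuli and compared by squared Euclidean distance of the
scalars, which preserves the squared-Euclidean algebra.

Missing cells (e.g. a 92-stimulus matrix embedded into a 96-stimulus
frame) are carried as NaN plus an explicit mask in the vectorized form;
every statistic pairwise-deletes them.

## Kendall tau-a

RDMs are compared by Kendall's τ_A: the number of concordant minus
discordant pairs of dissimilarities divided by the all-pairs denominator
m(m−1)/2, ties counting as neither. The all-pairs denominator penalizes
candidates that predict ties (e.g. category-cluster RDMs) for genuinely
distinct dissimilarities, which is the property that makes τ_A the right
statistic here. Pair counting uses Knight's O(m log m) merge-sort
algorithm; an O(m²) enumeration serves as the oracle in the tests, never
in the analysis path.

## Inference

- **Relatedness** of a candidate to a reference RDM: stimulus-label
  randomization — simultaneous row/column permutations of the candidate,
  p = (1 + #{τ_null ≥ τ_obs}) / (n_perm + 1). The add-one convention is
  used for all resampling p-values; it keeps p > 0 and the tests valid.
- **Uncertainty and model comparison**: stratified bootstrap of the
  stimulus set. Stimuli are resampled with replacement within category
  strata (preserving category proportions); cells that would duplicate a
  stimulus are masked, never recorded as spurious zero dissimilarities.
  Pairwise candidate differences get two-sided add-one bootstrap
  p-values; Benjamini–Hochberg step-up controls the expected FDR (0.05
  by default) across all pairs.
- One calibration consequence of the masking rule worth knowing: even
  with a candidate identical to the reference, bootstrap τ_A sits
  slightly below 1, because duplication creates tied pairs and τ_A counts
  ties against agreement.

## Noise ceiling

Inter-subject variability bounds the correlation any model can reach.

- **Upper bound**: a consensus RDM is initialized as the element-wise
  mean of rank-transformed subject RDMs and refined by a greedy local
  search over cell orderings (τ_A depends only on the candidate's
  ordering): values of cells adjacent in the candidate's sorted order are
  swapped whenever the mean τ_A across subjects improves, until a full
  pass accepts no swap or `max_iter` (default 50) passes. Because this
  consensus is fitted to the very subjects it is scored on, its mean
  correlation overestimates the true model's. The search objective is
  expressed through a precomputed antisymmetric sign-coefficient matrix,
  making each proposal an O(m) update; matrices up to 8000 cells
  (~0.5 GiB workspace) are supported.
- **Lower bound**: leave-one-subject-out — each subject against the mean
  of the rank-transformed others.

The bounds are computed for any ensemble of ≥ 2 subjects; below 3
subjects a warning is attached, as two-subject ceilings are unreliable.
For S mutually independent subjects the overfit upper bound is not 0 but
≈ (2/π)·arcsin(1/√S) (0.33 at S = 4), vanishing only as S grows; the
test suite checks this analytic behavior.

## Category-cluster model and categoricality

Ten hierarchical categories (animate, inanimate, face, human face,
non-human face, body, human body, non-human body, natural inanimate,
artificial inanimate) each contribute one predictor RDM: −1 for
within-category pairs, 0 elsewhere, plus an all-ones constant confound.
With this coding a larger positive coefficient means a tighter cluster;
the coding is recorded in every fit's metadata, since the +1 coding with
negated coefficients is observationally equivalent. Ordinary least
squares on the valid cells gives the coefficients; a rank-deficient
design falls back to the minimum-norm solution and is flagged. The
categoricality index (CCI) is the squared Pearson correlation between
fitted and observed cells, the proportion of RDM variance the category
structure explains.

Inference: CCI significance by category-label randomization (whole label
tuples are permuted across stimuli so the hierarchy's containment
invariants survive); per-category coefficient CIs by the stratified
stimulus bootstrap, with an optional Bonferroni factor when many
representations are screened at once.

## Noise equating

To compare model categoricality against noisy brain data on an equal
footing, Gaussian noise is added to the model features — per-feature sd
α × sd(feature) — and α is found by bisection so that the mean pairwise
Pearson correlation among `n_instances` (default 4) noisy-instantiation
RDMs matches the target (e.g. the mean pairwise correlation of the
subjects' brain RDMs) within `tol` (default 0.01). The inter-instantiation
correlation is Pearson over jointly valid vectorized cells. The noise
unit variates are drawn once and rescaled during the search, so the
objective is a deterministic, effectively monotone function of α and the
bisection bracket is meaningful. The returned RDM is the element-wise
mean of the instantiation RDMs; α and the achieved correlation are
recorded on the estimator.

## Combination, remixing, reweighting

- **Combination**: each model is projected onto its leading principal
  components (default min(n_stimuli − 1, 95); with n stimuli the feature
  covariance has at most n − 1 non-zero eigenvalues) and each block is
  rescaled to unit total variance before concatenation, so every model
  contributes the same number of features and the same variance.
- **Remixing**: linear maximum-margin classifiers (soft margin, C
  configurable, default 1.0) are trained on a separate labeled stimulus
  set and their signed decision values on the analysis stimuli become
  single-feature representations. A guard rejects any overlap between
  training and analysis stimulus ids.
- **Reweighting**: the key identity is that with squared Euclidean
  distances of normalized patterns, the RDM of the concatenation of
  √w_k-scaled feature blocks equals Σ_k w_k RDM_k. Weights are therefore
  fitted entirely at the RDM level: min_{w≥0} Σ_pairs (d_ref − Σ_k w_k
  d_k)², solved by the Lawson–Hanson active-set algorithm
  (`scipy.optimize.nnls`), which satisfies the KKT conditions exactly at
  termination.
- **Crossvalidation**: to avoid overfitting the stimulus set, each fold
  holds out a stratified random subset (default 8 stimuli, split equally
  across strata, e.g. 4 animate + 4 inanimate from 96), fits the weights
  on the cells among the remaining stimuli only, and predicts the cells
  *within* the holdout. An 8-stimulus holdout predicts 28 cells, so folds
  are repeated with fresh draws until every valid pair has at least one
  out-of-sample prediction (a few thousand folds for 96 stimuli;
  `max_folds` defaults to 50 000); multiply-predicted cells are averaged.
  A leakage assertion inside the fold loop verifies that no training cell
  touches a held-out stimulus.

## Category decoding

Decodability of a dichotomy is the mean held-out accuracy of a linear
soft-margin SVM under stratified k-fold crossvalidation (default k = 12;
96 balanced stimuli → folds of 8, 4 per class; 48-stimulus subtasks →
folds of 4, 2 per class). Features are divided by the training fold's
overall standard deviation, which makes accuracy invariant to rescaling
the representation by a positive constant. The fold assignment is seeded
and can be shared across models so their accuracies are paired. Chance
level comes from category-orthogonalized random dichotomies: each random
class takes exactly half of each true class (nearest-balanced with a
warning when a class count is odd), so the null labels are uncorrelated
with the true ones by construction; the classifier is retrained from
scratch for each.

## Synthetic data

The generator emulates the study's data structure, not its content:

- **Stimulus composition**: n stimuli (default 96, any multiple of 8) in
  the fixed hierarchy — half animate; animates split into faces and
  bodies, each half human/non-human; inanimates half natural, half
  artificial.
- **Model features**: each category contributes a shared Gaussian
  direction scaled by a per-category *tightness*; each stimulus adds an
  idiosyncratic exemplar direction plus i.i.d. feature noise (sd default
  1.0). Zero tightness everywhere yields CCI ≈ 0; raising a category's
  tightness pulls its members together.
- **Subject ensembles**: a shared true RDM plus independent symmetric
  zero-diagonal Gaussian cell noise per subject (default 4 subjects,
  cell-noise sd 0.1 on the correlation-distance scale), clipped to the
  metric's range. This is the simplest model of inter-subject RDM
  variability; it does not model voxel sampling, measurement filtering,
  or subject-specific geometry, so passing tests demonstrate the
  *estimators'* behavior, not properties of any real recording.
- **Mixtures**: ground-truth references Σ_k w_k RDM_k with optional cell
  noise, the oracle for weight-recovery checks.

All generators are deterministic given their seed.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately modest sizes chosen to make
the statistical properties visible quickly: 16 stimuli / 4 subjects / 500
runs for noise-ceiling bracketing, 10 stimuli / 999 permutations / 500
runs for permutation calibration, 24 stimuli / 5 components / 100 draws
for weight recovery, 24 stimuli / 4 components / 100 seeds for the
crossvalidated-reweighting gain. "Small" cell noise in mixture recovery
is defined as 10% of the noise-free reference's cell standard deviation.
Structural checks (combined feature width 95 × 27 = 2565, the 11-column
category design, the 92→96 embedding, the 8-stimulus holdout geometry)
run at the study's full 96-stimulus shape.

Other numerical conventions: RDM symmetry is validated to 1e−8 on load
and symmetrized; correlations are clipped to [−1, 1] before distances;
ranks use the average-rank convention for ties; the noise-equating
bisection expands its upper bracket geometrically before bisecting (60
iterations, tol 0.01); percentile bootstrap CIs at 95%; seeds are
accepted per operation call and recorded in outputs, with derived seeds
drawn from `numpy.random.SeedSequence`.

## Known limitations

- The greedy consensus refinement is a local search over orderings; it
  guarantees improvement over the rank-mean initializer, not a global
  optimum of the mean-τ_A objective.
- The upper/lower ceiling ordering is enforced by construction only
  statistically, not algebraically; in all simulations (500 runs at the
  default conditions) no inversion was observed.
- The lower bound with exactly 2 subjects degenerates to their mutual
  τ_A and is flagged as unreliable.
- Cell-level subject noise is a simplification; a feature-level
  subject-noise mode can be emulated by generating per-subject feature
  matrices and computing their RDMs.
- The crossvalidated reweighting assumes strata sizes allow an equal
  split of the holdout; unequal strata require choosing a compatible
  holdout size.
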