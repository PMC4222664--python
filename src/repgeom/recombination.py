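"""Combining, remixing, and reweighting model representations.

Three ways of building a representation that better matches a reference
(brain) RDM from existing model feature sets:

combination
    Concatenate many models after projecting each onto its leading
    principal components and equating each block's total variance, so
    every model contributes the same number of features and the same
    variance.

remixing
    Train linear maximum-margin classifiers (e.g. animate/inanimate) on a
    *separate* labeled training set and use their signed decision values
    on the analysis stimuli as new single-feature representations.

reweighting
    Fit one non-negative weight per component representation so that the
    weighted combination's RDM best matches the reference RDM in the
    least-squares sense. With squared Euclidean distances of normalized
    patterns (= 2x correlation distance), the RDM of weight-scaled
    concatenated features equals the weighted sum of component RDMs, so
    the fit can be done entirely at the RDM level with non-negative least
    squares (Lawson-Hanson active set). To avoid overfitting the stimulus
    set, weights are fitted on random stimulus subsets and dissimilarities
    predicted only for held-out stimuli, repeated until every cell of the
    reweighted RDM has been estimated out-of-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .rdm import RDM, FeatureMatrix, compute_rdm, pair_index


@dataclass(frozen=True)
class ComponentSet:
    """Named component representations over a shared stimulus set.

    Components given as features are converted once to RDMs with the
    squared-Euclidean-normalized metric, which makes the weighted-sum
    algebra of the reweighting fit exact.
    """

    names: tuple[str, ...]
    rdms: tuple[RDM, ...]
    kinds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rdms) or not self.rdms:
            raise ValueError("need one name per component RDM")
        ids = self.rdms[0].stimulus_ids
        for r in self.rdms:
            if r.stimulus_ids != ids:
                raise ValueError("all components must cover the same stimulus ids")
        if self.kinds and len(self.kinds) != len(self.names):
            raise ValueError("one kind tag per component required")

    @classmethod
    def from_items(cls, items: Sequence[tuple[str, FeatureMatrix | RDM]],
                   kinds: Sequence[str] | None = None) -> "ComponentSet":
        names, rdms = [], []
        for name, obj in items:
            names.append(name)
            if isinstance(obj, FeatureMatrix):
                rdms.append(compute_rdm(obj, "sqeuclidean_normalized"))
            else:
                rdms.append(obj)
        return cls(tuple(names), tuple(rdms), tuple(kinds) if kinds else ())

    @property
    def stimulus_ids(self) -> tuple[str, ...]:
        return self.rdms[0].stimulus_ids

    def __len__(self) -> int:
        return len(self.rdms)

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_pairs, n_components) stack of vectorized component RDMs and the
        jointly-valid cell mask."""
        vecs = [r.vectorize() for r in self.rdms]
        X = np.column_stack([v.values for v in vecs])
        mask = np.logical_and.reduce([v.mask for v in vecs])
        return X, mask


@dataclass(frozen=True)
class WeightVector:
    names: tuple[str, ...]
    w: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (len(self.names),):
            raise ValueError("one weight per component required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "w", w)


def combine_models(models: Sequence[FeatureMatrix], n_pcs: int | None = None) -> FeatureMatrix:
    """Concatenate models after PCA to ``n_pcs`` components per model, with
    each block rescaled to unit total variance.

    The default ``n_pcs`` is min(n_stimuli - 1, 95): with n stimuli the
    feature covariance has at most n - 1 non-zero eigenvalues.
    """
    if not models:
        raise ValueError("need at least one model")
    ids = models[0].stimulus_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    if n_pcs is None:
        n_pcs = min(n - 1, 95)
    if n_pcs > n - 1:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds the {n - 1} non-zero covariance eigenvalues "
            f"available for {n} stimuli"
        )
    blocks = []
    for m in models:
        if m.stimulus_ids != ids:
            raise ValueError("all models must share stimulus ids")
        if m.n_features < n_pcs:
            raise ValueError(
                f"model '{m.model_name}' has {m.n_features} features, fewer than "
                f"n_pcs={n_pcs}"
            )
        scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(m.values)
        if scores[:, -1].std() == 0:
            raise ValueError(
                f"model '{m.model_name}' has fewer than {n_pcs} non-degenerate "
                "principal components"
            )
        total_var = scores.var(axis=0, ddof=1).sum()
        blocks.append(scores / np.sqrt(total_var))
    name = f"combi{len(models)}"
    return FeatureMatrix(ids, np.hstack(blocks), name)


def train_discriminant(
    train: FeatureMatrix,
    train_labels: np.ndarray,
    test: FeatureMatrix,
    regularization: float = 1.0,
    name: str = "discriminant",
) -> FeatureMatrix:
    """Linear maximum-margin classifier decision values as a new feature.

    The classifier is trained on a labeled stimulus set that must be
    disjoint from the analysis stimuli (a leakage guard enforces this) and
    evaluated on the analysis stimuli; the signed decision value per
    stimulus forms a single-feature representation.
    """
    overlap = set(train.stimulus_ids) & set(test.stimulus_ids)
    if overlap:
        raise ValueError(
            f"training and test stimuli overlap ({sorted(overlap)[:5]}): "
            "discriminant training must not see the analysis stimuli"
        )
    labels = np.asarray(train_labels)
    if np.unique(labels).size < 2:
        raise ValueError("training labels contain a single class")
    if train.n_features != test.n_features:
        raise ValueError("train and test must share the feature space")
    clf = SVC(kernel="linear", C=regularization)
    clf.fit(train.values, labels)
    dv = clf.decision_function(test.values)
    return FeatureMatrix(test.stimulus_ids, dv[:, None], name)


class NonNegativeRDMRegression(BaseEstimator, RegressorMixin):
    """Non-negative least-squares fit of component RDMs to a reference RDM.

    Solves min_{w >= 0} sum_pairs (d_ref - sum_k w_k d_k)^2 over jointly
    valid cells with the Lawson-Hanson active-set algorithm, so at
    termination the KKT conditions hold exactly: any component whose RDM is
    negatively correlated with the residual at the optimum receives weight
    exactly zero.

    Attributes
    ----------
    coef_ : ndarray          fitted non-negative weights
    residual_norm_ : float   L2 norm of the residual at the solution
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NonNegativeRDMRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_pairs, n_components) aligned with y")
        if X.shape[0] == 0:
            raise ValueError("no valid cells to fit")
        w, rnorm = nnls(X, y)
        self.coef_ = w
        self.residual_norm_ = float(rnorm)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_


def nnls_weights(components: ComponentSet, reference: RDM) -> WeightVector:
    """Non-negative weights over component RDMs best matching ``reference``."""
    if components.stimulus_ids != reference.stimulus_ids:
        raise ValueError("components and reference must share stimulus ids")
    X, mask = components.design_matrix()
    ref = reference.vectorize()
    both = mask & ref.mask
    if not both.any():
        raise ValueError("no jointly valid cells between components and reference")
    reg = NonNegativeRDMRegression().fit(X[both], ref.values[both])
    return WeightVector(components.names, reg.coef_)


def mixture_rdm(components: ComponentSet, weights: WeightVector | np.ndarray) -> RDM:
    """Weighted sum of component RDMs (the reweighted model's RDM)."""
    w = weights.w if isinstance(weights, WeightVector) else np.asarray(weights, float)
    X, mask = components.design_matrix()
    vals = X @ w
    return RDM.from_vector(components.stimulus_ids, np.where(mask, vals, 0.0),
                           components.rdms[0].metric, mask=mask)


class CrossValidatedReweighting(BaseEstimator):
    """Stimulus-crossvalidated reweighting of component RDMs.

    Each fold draws a stratified random holdout (default 8 stimuli, e.g. 4
    animates + 4 inanimates, from 96), fits the non-negative weights on the
    cells among the remaining stimuli only, and predicts the dissimilarities
    *within* the holdout with those weights. Folds are repeated with fresh
    random holdouts until every off-diagonal pair has been predicted at
    least once (cells predicted in several folds are averaged), so the
    assembled RDM is estimated entirely out-of-sample.

    Parameters
    ----------
    holdout_size : int, default=8
        Stimuli held out per fold, split equally across strata.
    max_folds : int, default=50_000
        Fold budget before coverage failure is reported.
    seed : int or None
        Seed for the holdout draws.

    Attributes
    ----------
    rdm_ : RDM                    assembled crossvalidated RDM
    fold_weights_ : ndarray       (n_folds, n_components) per-fold weights
    n_folds_ : int
    coverage_counts_ : ndarray    per-pair prediction counts
    """

    def __init__(self, holdout_size: int = 8, max_folds: int = 50_000,
                 seed: int | None = None):
        self.holdout_size = holdout_size
        self.max_folds = max_folds
        self.seed = seed

    def fit(self, components: ComponentSet, reference: RDM,
            strata: np.ndarray | None = None) -> "CrossValidatedReweighting":
        if components.stimulus_ids != reference.stimulus_ids:
            raise ValueError("components and reference must share stimulus ids")
        if self.holdout_size < 3:
            raise ValueError("holdout_size must be at least 3")
        n = reference.n_stimuli
        strata = (np.zeros(n, dtype=int) if strata is None else np.asarray(strata))
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        per_stratum, rem = divmod(self.holdout_size, len(groups))
        if rem or per_stratum < 1 or any(g.size <= per_stratum for g in groups):
            raise ValueError(
                f"holdout_size={self.holdout_size} cannot be split equally "
                f"across {len(groups)} strata with the given stratum sizes"
            )
        rng = np.random.default_rng(self.seed)
        iu, ju = pair_index(n)
        X, comp_mask = components.design_matrix()
        ref_vec = reference.vectorize()
        fit_mask_base = comp_mask & ref_vec.mask
        sums = np.zeros(iu.size)
        counts = np.zeros(iu.size, dtype=int)
        weights = []
        n_folds = 0
        while counts.min() == 0 and n_folds < self.max_folds:
            hold = np.concatenate([
                rng.choice(g, size=per_stratum, replace=False) for g in groups
            ])
            in_hold = np.zeros(n, dtype=bool)
            in_hold[hold] = True
            train_cells = fit_mask_base & ~in_hold[iu] & ~in_hold[ju]
            test_cells = in_hold[iu] & in_hold[ju] & comp_mask
            # leakage guard: no training cell may touch a held-out stimulus
            assert not np.any(in_hold[iu[train_cells]] | in_hold[ju[train_cells]])
            if not train_cells.any() or not test_cells.any():
                n_folds += 1
                continue
            w, _ = nnls(X[train_cells], ref_vec.values[train_cells])
            pred = X[test_cells] @ w
            sums[test_cells] += pred
            counts[test_cells] += 1
            weights.append(w)
            n_folds += 1
        uncovered = int(np.sum((counts == 0) & fit_mask_base))
        if np.any(counts[fit_mask_base] == 0):
            raise RuntimeError(
                f"coverage not achieved within {self.max_folds} folds: "
                f"{uncovered} of {int(fit_mask_base.sum())} valid pairs unpredicted"
            )
        covered = counts > 0
        vals = np.zeros(iu.size)
        vals[covered] = sums[covered] / counts[covered]
        self.rdm_ = RDM.from_vector(reference.stimulus_ids, vals,
                                    components.rdms[0].metric, mask=covered)
        self.fold_weights_ = np.array(weights)
        self.mean_weights_ = WeightVector(components.names,
                                          self.fold_weights_.mean(axis=0))
        self.n_folds_ = n_folds
        self.coverage_counts_ = counts
        return self


def crossvalidated_weighted_rdm(
    components: ComponentSet,
    reference: RDM,
    holdout_size: int = 8,
    strata: np.ndarray | None = None,
    seed: int | None = None,
    max_folds: int = 50_000,
) -> RDM:
    cv = CrossValidatedReweighting(holdout_size, max_folds, seed)
    return cv.fit(components, reference, strata).rdm_
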