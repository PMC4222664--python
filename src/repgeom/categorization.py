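"""Linear decodability of category dichotomies from a representation.

Categorization performance is the mean held-out accuracy of a linear
maximum-margin classifier under stratified k-fold crossvalidation
(default k = 12: with 96 balanced stimuli each fold holds out 8, 4 per
class; the 48-stimulus face/body and natural/artificial tasks hold out 4,
2 per class). Chance level is assessed with a category-orthogonalized
dichotomy null: random balanced relabelings that take exactly half of
each true class, so the null dichotomies carry no information about the
true one, retrained from scratch for each relabeling.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .inference import TestResult
from .rdm import FeatureMatrix


def _check_labels(features: FeatureMatrix, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (features.n_stimuli,):
        raise ValueError("one label per stimulus required")
    if np.unique(labels).size != 2:
        raise ValueError("labels must form a binary dichotomy")
    return labels


def kfold_accuracy(
    features: FeatureMatrix,
    labels: np.ndarray,
    k: int = 12,
    seed: int | None = None,
    C: float = 1.0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Mean held-out accuracy of a linear classifier over stratified k folds.

    ``folds`` lets callers reuse one fold assignment across the models
    being compared, making model accuracies paired.
    """
    labels = _check_labels(features, labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} members, "
            f"fewer than k={k} folds"
        )
    if folds is None:
        folds = make_folds(labels, k, seed)
    accs = []
    X = features.values
    for train_idx, test_idx in folds:
        # normalize by the training data's overall spread so accuracy is
        # invariant to rescaling the representation by a positive constant
        scale = X[train_idx].std() or 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train_idx] / scale, labels[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx] / scale)
                                  == labels[test_idx])))
    return float(np.mean(accs))


def make_folds(labels: np.ndarray, k: int, seed: int | None):
    """Seeded stratified fold assignment, reusable across models."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((labels.size, 1)), labels))


def orthogonal_dichotomy(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random balanced dichotomy orthogonal to the true one: each random
    class takes exactly half of each true class (nearest-balanced split,
    with a warning, when a class has an odd count)."""
    labels = np.asarray(labels)
    out = np.zeros(labels.size, dtype=int)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size % 2:
            warnings.warn(
                f"class {cls!r} has an odd count ({members.size}); using the "
                "nearest-balanced split", UserWarning,
            )
        half = members.size // 2
        chosen = rng.choice(members, size=half, replace=False)
        out[chosen] = 1
    return out


def dichotomy_null(
    features: FeatureMatrix,
    labels: np.ndarray,
    n_dichotomies: int = 10_000,
    k: int = 12,
    seed: int | None = None,
    C: float = 1.0,
) -> TestResult:
    """Permutation test of categorization accuracy against the
    category-orthogonalized dichotomy null.

    Returns the observed k-fold accuracy, the add-one p-value against the
    null accuracies, and the null mean (the expected chance-level bar).
    """
    labels = _check_labels(features, labels)
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    obs = kfold_accuracy(features, labels, k=k, seed=fold_seed, C=C)
    null = np.empty(n_dichotomies)
    for i in range(n_dichotomies):
        rand = orthogonal_dichotomy(labels, rng)
        null[i] = kfold_accuracy(features, rand, k=k,
                                 seed=int(rng.integers(2**31)), C=C)
    p = (1 + int(np.sum(null >= obs))) / (n_dichotomies + 1)
    return TestResult(
        statistic=obs, p_value=p, n_resamples=n_dichotomies,
        method="category-orthogonalized dichotomy permutation",
        extra={"seed": seed, "null_mean": float(null.mean())},
    )
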