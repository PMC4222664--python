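"""Category-cluster models of representational geometry.

A category-cluster model predicts that stimuli belonging to the same
category are representationally closer than the grand mean. Each of the
ten hierarchical categories contributes one predictor RDM with entry -1
for within-category pairs and 0 elsewhere, plus a constant all-ones
confound predictor; with this coding a larger positive coefficient means
a more tightly clustered category. Ordinary least squares on the valid
cells of a vectorized RDM gives the per-category clustering strengths,
and the categoricality index (CCI) — the squared Pearson correlation
between fitted and observed dissimilarities — measures the proportion of
RDM variance the category structure explains.

Inference: category-label randomization for the CCI (permute whole label
tuples across stimuli, refit, add-one p-value) and a stratified stimulus
bootstrap for per-category coefficient confidence intervals.

`NoiseEquating` makes model RDMs comparable to noisy brain RDMs: Gaussian
noise is added to the model features, scaled so that the mean pairwise
correlation between several noisy-instantiation RDMs matches the mean
pairwise correlation among the subjects' brain RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .inference import TestResult, _resampled_vector, _stratified_indices
from .rdm import RDM, FeatureMatrix, compute_rdm, pair_index
from .stimuli import CATEGORY_NAMES, StimulusSet


@dataclass(frozen=True)
class CategoryModel:
    """Ordered (category name, predictor vector) pairs plus a constant."""

    names: tuple[str, ...]
    design: np.ndarray = field(repr=False)  # (n_pairs, n_predictors)
    stimulus_ids: tuple[str, ...] = ()
    includes_constant: bool = True

    @property
    def n_predictors(self) -> int:
        return self.design.shape[1]


def build_category_model(stimuli: StimulusSet) -> CategoryModel:
    """One -1/0 predictor per category, in canonical order, plus a constant.

    Entry -1 where both stimuli of a pair belong to the category, 0
    otherwise; the pair order matches the canonical upper-triangle
    vectorization.
    """
    n = len(stimuli)
    iu, ju = pair_index(n)
    cols = []
    for name in CATEGORY_NAMES:
        member = stimuli.members(name)
        if not member.any():
            raise ValueError(f"category '{name}' has no members")
        cols.append(np.where(member[iu] & member[ju], -1.0, 0.0))
    cols.append(np.ones(iu.size))
    design = np.column_stack(cols)
    return CategoryModel(CATEGORY_NAMES + ("constant",), design, stimuli.ids, True)


class CategoryClusterFit(BaseEstimator, RegressorMixin):
    """Least-squares fit of the category-cluster model to an RDM.

    ``fit(rdm, stimuli)`` regresses the RDM's valid cells on the ten
    category predictors plus a constant, minimizing the sum of squared
    dissimilarity deviations.

    Attributes
    ----------
    coef_ : ndarray of shape (11,)
        Per-predictor coefficients (the last is the constant). Positive
        category coefficients mean tighter clustering.
    cci_ : float
        Categoricality index: squared Pearson correlation between fitted
        and observed dissimilarities over valid cells, in [0, 1].
    fitted_rdm_, residual_rdm_ : RDM
        fitted + residual = observed on valid cells.
    rank_deficient_ : bool
        True when the design was rank-deficient and the minimum-norm
        solution was used.
    """

    def fit(self, rdm: RDM, stimuli: StimulusSet | CategoryModel) -> "CategoryClusterFit":
        model = (
            stimuli if isinstance(stimuli, CategoryModel) else build_category_model(stimuli)
        )
        if model.stimulus_ids and model.stimulus_ids != rdm.stimulus_ids:
            raise ValueError("RDM and category model must share stimulus ids")
        vec = rdm.vectorize()
        valid = vec.mask
        if int(valid.sum()) < 12:
            raise ValueError("need at least 12 valid dissimilarity cells")
        X = model.design[valid]
        y = vec.values[valid]
        beta, fitted_valid, rank_deficient = _ols(X, y)
        self.coef_ = beta
        self.predictor_names_ = model.names
        self.rank_deficient_ = rank_deficient
        self.cci_ = _cci(fitted_valid, y)
        fitted = np.full(len(vec), np.nan)
        fitted[valid] = fitted_valid
        self.fitted_rdm_ = RDM.from_vector(rdm.stimulus_ids, np.nan_to_num(fitted),
                                           rdm.metric, mask=valid)
        resid = np.full(len(vec), np.nan)
        resid[valid] = y - fitted_valid
        self.residual_rdm_ = RDM.from_vector(rdm.stimulus_ids, np.nan_to_num(resid),
                                             rdm.metric, mask=valid)
        self.coding_ = "within-category pairs = -1 (positive coef = tighter cluster)"
        return self


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return beta, X @ beta, rank < X.shape[1]


def _cci(fitted: np.ndarray, observed: np.ndarray) -> float:
    if fitted.std() == 0 or observed.std() == 0:
        return 0.0
    r = np.corrcoef(fitted, observed)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


def fit_category_model(rdm: RDM, model: StimulusSet | CategoryModel) -> CategoryClusterFit:
    return CategoryClusterFit().fit(rdm, model)


def categoricality_index(rdm: RDM, stimuli: StimulusSet) -> float:
    return fit_category_model(rdm, stimuli).cci_


def categoricality_test(
    rdm: RDM, stimuli: StimulusSet, n_rand: int = 10_000, seed: int | None = None
) -> TestResult:
    """Category-label randomization test of the categoricality index.

    Each randomization permutes the stimuli's full label tuples (so the
    category-tree containments are preserved), rebuilds the predictors and
    refits; p is the add-one fraction of null CCIs at or above the
    observed one.
    """
    rng = np.random.default_rng(seed)
    obs = categoricality_index(rdm, stimuli)
    null = np.empty(n_rand)
    for k in range(n_rand):
        perm = rng.permutation(len(stimuli))
        null[k] = categoricality_index(rdm, stimuli.permuted(perm))
    p = (1 + int(np.sum(null >= obs))) / (n_rand + 1)
    return TestResult(
        statistic=obs, p_value=p, n_resamples=n_rand,
        method="category-label randomization",
        extra={"seed": seed, "null_mean": float(null.mean())},
    )


def clustering_strength_ci(
    rdm: RDM,
    stimuli: StimulusSet,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci: float = 0.95,
    bonferroni_m: int = 1,
) -> dict:
    """Stratified stimulus bootstrap of per-category clustering strengths.

    Returns per-category coefficient, percentile CI, and two-sided add-one
    bootstrap p-value (optionally Bonferroni-adjusted by ``bonferroni_m``,
    e.g. n_representations * 10 when many representations are screened).
    Duplicated stimuli within a resample produce masked cells, never
    spurious zero dissimilarities.
    """
    rng = np.random.default_rng(seed)
    strata = stimuli.leaf_of()
    obs = fit_category_model(rdm, stimuli)
    # resampling within leaf strata leaves every stimulus's label tuple in
    # place, so the design matrix is identical across resamples; only the
    # dissimilarities (and the duplicate-cell mask) change
    model = build_category_model(stimuli)
    n_cat = len(CATEGORY_NAMES)
    betas = np.empty((n_boot, n_cat))
    for b in range(n_boot):
        idx = _stratified_indices(strata, rng)
        vals = _resampled_vector(rdm.values, idx)
        valid = np.isfinite(vals)
        beta, _, _ = _ols(model.design[valid], vals[valid])
        betas[b] = beta[:n_cat]
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    out = {}
    adj = max(1, int(bonferroni_m))
    for j, name in enumerate(CATEGORY_NAMES):
        dist = betas[:, j]
        p_lo = (1 + int(np.sum(dist <= 0))) / (n_boot + 1)
        p_hi = (1 + int(np.sum(dist >= 0))) / (n_boot + 1)
        p = min(1.0, 2.0 * min(p_lo, p_hi) * adj)
        out[name] = {
            "beta": float(obs.coef_[j]),
            "ci_low": float(np.quantile(dist, lo_q)),
            "ci_high": float(np.quantile(dist, hi_q)),
            "p": p,
        }
    return {"categories": out, "cci": obs.cci_, "n_boot": n_boot, "seed": seed,
            "coding": obs.coding_}


class NoiseEquating(BaseEstimator):
    """Find the feature-noise scale at which a model matches a target
    inter-instantiation RDM correlation.

    Gaussian noise with per-feature standard deviation ``alpha * sd(feature)``
    is added to the model features; ``n_instances`` independent noisy
    instantiations give ``n_instances`` RDMs whose mean pairwise Pearson
    correlation q_m is matched to ``target_q`` (e.g. the mean pairwise
    correlation of the human-IT subject RDMs) by bisection on ``alpha``.
    The noise unit variates are drawn once and rescaled during the search,
    so q_m is a deterministic function of ``alpha``.

    Attributes
    ----------
    alpha_ : float          fitted noise scale
    achieved_q_ : float     q_m at ``alpha_``
    rdm_ : RDM              element-wise average of the noisy-instantiation RDMs
    """

    def __init__(
        self,
        target_q: float,
        n_instances: int = 4,
        tol: float = 0.01,
        max_iter: int = 60,
        metric: str = "correlation",
        seed: int | None = None,
    ):
        self.target_q = target_q
        self.n_instances = n_instances
        self.tol = tol
        self.max_iter = max_iter
        self.metric = metric
        self.seed = seed

    def fit(self, features: FeatureMatrix, y=None) -> "NoiseEquating":
        if not (0.0 < self.target_q <= 1.0):
            raise ValueError("target_q must lie in (0, 1]")
        if self.n_instances < 2:
            raise ValueError("need at least 2 noisy instantiations")
        rng = np.random.default_rng(self.seed)
        X = features.values
        feat_sd = X.std(axis=0)
        noise_units = rng.standard_normal((self.n_instances,) + X.shape)

        def instantiate(alpha: float) -> list[RDM]:
            return [
                compute_rdm(
                    FeatureMatrix(features.stimulus_ids,
                                  X + alpha * feat_sd * noise_units[i],
                                  features.model_name),
                    self.metric,
                )
                for i in range(self.n_instances)
            ]

        def q_of(rdms: list[RDM]) -> float:
            vecs = [r.vectorize() for r in rdms]
            rs = []
            for a in range(len(vecs)):
                for b in range(a + 1, len(vecs)):
                    both = vecs[a].mask & vecs[b].mask
                    rs.append(stats.pearsonr(vecs[a].values[both],
                                             vecs[b].values[both]).statistic)
            return float(np.mean(rs))

        if self.target_q >= 1.0:
            rdms = instantiate(0.0)
            self.alpha_, self.achieved_q_ = 0.0, 1.0
        else:
            lo, hi = 0.0, 1.0
            q_hi = q_of(instantiate(hi))
            grow = 0
            while q_hi > self.target_q:
                hi *= 2.0
                q_hi = q_of(instantiate(hi))
                grow += 1
                if grow > 40:
                    raise RuntimeError(
                        f"could not bracket target_q={self.target_q}: "
                        f"q_m({hi})={q_hi:.4f}"
                    )
            alpha, q_m = hi, q_hi
            for _ in range(self.max_iter):
                mid = 0.5 * (lo + hi)
                q_mid = q_of(instantiate(mid))
                alpha, q_m = mid, q_mid
                if abs(q_mid - self.target_q) <= self.tol:
                    break
                if q_mid > self.target_q:
                    lo = mid
                else:
                    hi = mid
            else:
                raise RuntimeError(
                    f"noise equating did not reach target_q={self.target_q} "
                    f"within {self.max_iter} iterations "
                    f"(bracket q_m in [{q_of(instantiate(hi)):.4f}, "
                    f"{q_of(instantiate(lo)):.4f}])"
                )
            rdms = instantiate(alpha)
            self.alpha_, self.achieved_q_ = float(alpha), float(q_m)

        from .rdm import average_rdms

        self.rdm_ = average_rdms(rdms)
        self.instantiation_rdms_ = tuple(rdms)
        return self


def equate_noise(
    features: FeatureMatrix,
    target_q: float,
    n_instances: int = 4,
    tol: float = 0.01,
    max_iter: int = 60,
    seed: int | None = None,
) -> RDM:
    """Noise-equated RDM: average of noisy-instantiation RDMs whose mean
    pairwise correlation matches ``target_q`` within ``tol``."""
    eq = NoiseEquating(target_q, n_instances, tol, max_iter, seed=seed).fit(features)
    return eq.rdm_
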