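"""Inference for RDM comparisons.

Statistics are Kendall tau-a correlations between vectorized RDMs.
Significance of a single model-to-reference correlation comes from a
stimulus-label randomization test (simultaneous row/column permutation of
the candidate RDM). Uncertainty and model-to-model comparisons come from a
stratified bootstrap of the stimulus set: stimuli are resampled with
replacement within category strata so every resample preserves the
category proportions, and cells that would duplicate a stimulus (diagonal
zeros landing off-diagonal) are masked out before any correlation is
computed. All resampling p-values use the add-one convention
p = (1 + #extreme) / (n + 1), so p is never zero and the tests are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rdm import RDM, pair_index
from .tau import kendall_tau_a, tau_a_against_many

# vector lengths up to this use the O(m^2)-memory vectorized tau for nulls
_VECTORIZED_TAU_LIMIT = 1500


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_resamples: int
    method: str
    ci_low: float | None = None
    ci_high: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def _check_aligned(reference: RDM, candidates: list[RDM]) -> None:
    for c in candidates:
        if c.stimulus_ids != reference.stimulus_ids:
            raise ValueError("reference and candidate RDMs must share stimulus ids")


def rdm_correlation(reference: RDM, candidate: RDM) -> float:
    """Kendall tau-a between two RDMs over jointly valid cells."""
    _check_aligned(reference, [candidate])
    return kendall_tau_a(reference.vectorize(), candidate.vectorize())


def permutation_test(
    reference: RDM,
    candidate: RDM,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Stimulus-label randomization test of the RDM correlation.

    The null distribution applies a random simultaneous row/column
    permutation to the candidate RDM ``n_perm`` times; the p-value is the
    add-one fraction of null tau-a values at or above the observed one.
    """
    _check_aligned(reference, [candidate])
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    ref_vec = reference.vectorize()
    obs = kendall_tau_a(ref_vec, candidate.vectorize())
    n = reference.n_stimuli
    iu, ju = pair_index(n)
    C = candidate.values
    complete = bool(ref_vec.mask.all() and np.isfinite(C[iu, ju]).all())
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    if complete and iu.size <= _VECTORIZED_TAU_LIMIT:
        Y = np.empty((n_perm, iu.size))
        for k in range(n_perm):
            p = perms[k]
            Y[k] = C[np.ix_(p, p)][iu, ju]
        null = tau_a_against_many(ref_vec.values, Y)
    else:
        null = np.empty(n_perm)
        for k in range(n_perm):
            null[k] = kendall_tau_a(ref_vec, candidate.permute(perms[k]).vectorize())
    p = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
    return TestResult(
        statistic=obs,
        p_value=p,
        n_resamples=n_perm,
        method="stimulus-label randomization",
        extra={"seed": seed, "null_mean": float(null.mean())},
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Per-candidate bootstrap distributions of tau-a."""

    candidate_names: tuple[str, ...]
    taus: np.ndarray = field(repr=False)  # (n_boot, n_candidates)
    seed: int | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.taus.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        return self.taus.std(axis=0, ddof=1)


def _stratified_indices(strata: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample stimulus indices with replacement within each stratum,
    preserving stratum sizes and positions."""
    idx = np.arange(strata.size)
    out = np.empty_like(idx)
    for s in np.unique(strata):
        members = idx[strata == s]
        if members.size < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 members")
        out[members] = rng.choice(members, size=members.size, replace=True)
    return out


def _resampled_vector(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Upper-triangle vector of values[idx][:, idx], with duplicated-stimulus
    cells (which would be diagonal zeros) set to NaN."""
    iu, ju = pair_index(idx.size)
    v = values[idx[iu], idx[ju]]
    v = np.where(idx[iu] == idx[ju], np.nan, v)
    return v


def bootstrap_stimuli(
    reference: RDM,
    candidates: list[RDM],
    strata: np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
    candidate_names: list[str] | None = None,
) -> BootstrapResult:
    """Stratified bootstrap of the stimulus set for tau-a(reference, candidate).

    Each resample draws stimuli with replacement independently within each
    stratum; both the reference and every candidate RDM are re-indexed by
    the same resample, and duplicate-stimulus cells are masked before the
    correlation is computed.
    """
    _check_aligned(reference, candidates)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    strata = np.asarray(strata)
    if strata.size != reference.n_stimuli:
        raise ValueError("strata must assign one label per stimulus")
    rng = np.random.default_rng(seed)
    names = tuple(
        candidate_names
        if candidate_names is not None
        else [f"candidate_{k}" for k in range(len(candidates))]
    )
    cand_vals = [c.values for c in candidates]
    taus = np.empty((n_boot, len(candidates)))
    for b in range(n_boot):
        idx = _stratified_indices(strata, rng)
        ref_v = _resampled_vector(reference.values, idx)
        for k, cv in enumerate(cand_vals):
            taus[b, k] = kendall_tau_a(ref_v, _resampled_vector(cv, idx))
    return BootstrapResult(names, taus, seed)


def compare_candidates(
    reference: RDM,
    candidates: list[RDM],
    strata: np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    candidate_names: list[str] | None = None,
) -> dict:
    """Pairwise bootstrap comparison of candidate RDMs against one reference.

    For each candidate pair the bootstrap distribution of the tau-a
    difference gives a two-sided add-one p-value; Benjamini–Hochberg
    step-up controls the expected FDR at ``alpha`` across all pairs.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to compare")
    boot = bootstrap_stimuli(
        reference, candidates, strata, n_boot=n_boot, seed=seed,
        candidate_names=candidate_names,
    )
    K = len(candidates)
    pmat = np.ones((K, K))
    pairs, raw = [], []
    for a in range(K):
        for b in range(a + 1, K):
            diff = boot.taus[:, a] - boot.taus[:, b]
            p_lo = (1 + int(np.sum(diff <= 0))) / (n_boot + 1)
            p_hi = (1 + int(np.sum(diff >= 0))) / (n_boot + 1)
            p = min(1.0, 2.0 * min(p_lo, p_hi))
            pmat[a, b] = pmat[b, a] = p
            pairs.append((a, b))
            raw.append(p)
    reject, _, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    sig = np.zeros((K, K), dtype=bool)
    for (a, b), r in zip(pairs, reject):
        sig[a, b] = sig[b, a] = bool(r)
    return {
        "bootstrap": boot,
        "p_matrix": pmat,
        "significant": sig,
        "alpha": alpha,
        "method": "two-sided stratified bootstrap + BH FDR",
    }


def correlate_scores(x, y, method: str = "pearson") -> float:
    """Correlation of paired model-level scores (e.g. IT-resemblance vs.
    categorization accuracy across models)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length score lists with at least 3 entries")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("scores have zero variance")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")
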