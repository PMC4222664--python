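"""Noise-ceiling estimation from multi-subject RDM ensembles.

Inter-subject variability limits the RDM correlation any model — even the
unknown true model — can achieve with single-subject data. The ceiling is
bracketed by two bounds, both on the *average* Kendall tau-a correlation
with the single-subject RDMs:

upper bound
    A consensus RDM is initialized as the element-wise mean of the
    rank-transformed single-subject RDMs and then refined by a greedy
    local search over cell orderings (tau-a depends only on the ordering
    of the candidate's cells) to maximize the mean tau-a with the
    subjects. Because this consensus is fitted to the very subjects it is
    correlated with, its mean correlation overestimates the true model's:
    an upper bound.

lower bound
    Leave-one-subject-out: each subject's RDM is correlated with the mean
    of the rank-transformed RDMs of the *other* subjects. No overfitting,
    but the held-out mean is noisier than the true model's RDM, so the
    average underestimates the ceiling: a lower bound.

Missing cells (e.g. a 92-stimulus subject embedded in a 96-stimulus
frame) are pairwise-deleted per subject throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .rdm import RDM, average_rdms
from .tau import kendall_tau_a

# cell counts above this would need >1 GiB of sign-matrix workspace
_MAX_CELLS = 8000


@dataclass(frozen=True)
class SubjectEnsemble:
    """Per-subject RDMs over a shared stimulus set."""

    rdms: tuple[RDM, ...]
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rdms = tuple(self.rdms)
        if len(rdms) < 2:
            raise ValueError("need at least 2 subjects")
        ids = rdms[0].stimulus_ids
        for r in rdms:
            if r.stimulus_ids != ids:
                raise ValueError("all subject RDMs must share stimulus ids")
        subject_ids = tuple(self.subject_ids) or tuple(
            f"subject_{k}" for k in range(len(rdms))
        )
        if len(subject_ids) != len(rdms):
            raise ValueError("one subject id per RDM required")
        object.__setattr__(self, "rdms", rdms)
        object.__setattr__(self, "subject_ids", subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.rdms)

    @property
    def stimulus_ids(self) -> tuple[str, ...]:
        return self.rdms[0].stimulus_ids


def _subject_vectors(ensemble: SubjectEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """(values, mask) arrays of shape (n_subjects, n_cells)."""
    vecs = [r.vectorize() for r in ensemble.rdms]
    return np.array([v.values for v in vecs]), np.array([v.mask for v in vecs])


def _mean_objective_matrix(Y: np.ndarray, M: np.ndarray, cand_mask: np.ndarray) -> np.ndarray:
    """A[a, b] = mean over subjects of sgn(y_a - y_b)/n0_s for cell pairs valid
    in both the subject and the candidate; the greedy objective is then
    sum_{a<b} sgn(c_a - c_b) * A[a, b] = mean tau-a."""
    m = Y.shape[1]
    if m > _MAX_CELLS:
        raise ValueError(
            f"{m} RDM cells exceeds the consensus-refinement limit ({_MAX_CELLS})"
        )
    A = np.zeros((m, m))
    for y, msk in zip(Y, M):
        valid = msk & cand_mask
        m_s = int(valid.sum())
        if m_s < 2:
            continue
        n0 = m_s * (m_s - 1) / 2
        W = np.sign(y[:, None] - y[None, :]) / n0
        W[~valid, :] = 0.0
        W[:, ~valid] = 0.0
        A += W
    return A / Y.shape[0]


def _greedy_refine(
    cand: np.ndarray, A: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, int]:
    """Bubble local search over candidate cell orderings: propose swapping the
    values of cells adjacent in the candidate's sorted order, accept if the
    mean tau-a objective improves by more than ``tol``."""
    c = cand.copy()
    m = c.size
    order = np.argsort(c, kind="stable")
    n_swaps = 0
    for _ in range(max_iter):
        improved = False
        for k in range(m - 1):
            p, q = order[k], order[k + 1]
            u, v = c[p], c[q]
            if u == v:
                continue
            # swapping the values at cells p and q changes their relations
            # with every other cell t and with each other; with the
            # antisymmetric coefficient matrix A the full-row dot products
            # below include the (p, q) pair term exactly once each, which
            # together give its 2*sgn(v-u)*A[p,q] change
            s_v, s_u = np.sign(v - c), np.sign(u - c)
            delta = float((s_v - s_u) @ A[p] + (s_u - s_v) @ A[q])
            if delta > tol:
                c[p], c[q] = v, u
                order[k], order[k + 1] = q, p
                n_swaps += 1
                improved = True
        if not improved:
            break
    return c, n_swaps


class NoiseCeiling(BaseEstimator):
    """Estimator for the [lower, upper] noise-ceiling interval.

    Parameters
    ----------
    max_iter : int, default=50
        Maximum full passes of the greedy consensus refinement.
    tol : float, default=0.0
        Minimum mean-tau-a improvement to accept a swap.

    Attributes
    ----------
    lower_, upper_ : float
        Leave-one-subject-out and overfit-consensus bounds.
    consensus_rdm_ : RDM
        The refined consensus RDM (rank-valued cells).
    per_subject_upper_, per_subject_lower_ : ndarray
        The per-subject correlations averaged into each bound.
    """

    def __init__(self, max_iter: int = 50, tol: float = 0.0):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, ensemble: SubjectEnsemble | list[RDM], y=None) -> "NoiseCeiling":
        if not isinstance(ensemble, SubjectEnsemble):
            ensemble = SubjectEnsemble(tuple(ensemble))
        if ensemble.n_subjects < 3:
            warnings.warn(
                "noise ceiling from fewer than 3 subjects is unreliable",
                UserWarning,
            )
        Y, M = _subject_vectors(ensemble)
        rank_mean = average_rdms(ensemble.rdms, rank=True)
        init_vec = rank_mean.vectorize()
        cand_mask = init_vec.mask
        A = _mean_objective_matrix(Y, M, cand_mask)
        cand, n_swaps = _greedy_refine(init_vec.values, A, self.max_iter, self.tol)

        def per_subject_tau(c: np.ndarray) -> np.ndarray:
            out = np.empty(ensemble.n_subjects)
            for s in range(ensemble.n_subjects):
                valid = M[s] & cand_mask
                out[s] = kendall_tau_a(c[valid], Y[s][valid])
            return out

        self.per_subject_upper_ = per_subject_tau(cand)
        self.init_upper_ = float(per_subject_tau(init_vec.values).mean())
        self.upper_ = float(self.per_subject_upper_.mean())
        self.n_refinement_swaps_ = n_swaps

        los = np.empty(ensemble.n_subjects)
        for s in range(ensemble.n_subjects):
            others = [r for k, r in enumerate(ensemble.rdms) if k != s]
            held = average_rdms(others, rank=True).vectorize()
            valid = M[s] & held.mask
            los[s] = kendall_tau_a(Y[s][valid], held.values[valid])
        self.per_subject_lower_ = los
        self.lower_ = float(los.mean())

        self.consensus_rdm_ = RDM.from_vector(
            ensemble.stimulus_ids, np.where(cand_mask, cand, np.nan),
            ensemble.rdms[0].metric, mask=cand_mask,
        )
        self.n_subjects_ = ensemble.n_subjects
        return self

    @property
    def interval_(self) -> tuple[float, float]:
        return (self.lower_, self.upper_)


def upper_bound(
    ensemble: SubjectEnsemble | list[RDM], max_iter: int = 50, tol: float = 0.0
) -> float:
    """Overfit-consensus upper bound on the group-average tau-a."""
    return NoiseCeiling(max_iter=max_iter, tol=tol).fit(ensemble).upper_


def lower_bound(ensemble: SubjectEnsemble | list[RDM]) -> float:
    """Leave-one-subject-out lower bound on the group-average tau-a."""
    return NoiseCeiling(max_iter=0).fit(ensemble).lower_
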