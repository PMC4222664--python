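"""Representational dissimilarity matrices and their core manipulations.

An RDM is a square symmetric matrix of pairwise dissimilarities between
stimulus-evoked response patterns, with a zero diagonal. Cells may be
missing (e.g. after embedding a 92-stimulus matrix into a 96-stimulus
frame); missing cells are carried as NaN in storage and as an explicit
validity mask in the vectorized form, and every downstream statistic
pairwise-deletes them.

Two metrics are supported:

``correlation``
    1 minus the Pearson correlation between the two response patterns
    (rows of the feature matrix); entries lie in [0, 2].
``sqeuclidean_normalized``
    Squared Euclidean distance between mean-centered, unit-norm response
    patterns. Equals 2 * (1 - r), i.e. twice the correlation distance,
    and makes the weighted-combination algebra of RDM reweighting exact:
    the squared-Euclidean RDM of concatenated, weight-scaled feature
    blocks is the weighted sum of the per-block RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRICS = ("correlation", "sqeuclidean_normalized")


@dataclass(frozen=True)
class FeatureMatrix:
    """One representation: an (n_stimuli, n_features) real matrix."""

    stimulus_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    model_name: str = "model"

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.stimulus_ids)
        object.__setattr__(self, "stimulus_ids", ids)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (stimuli x features)")
        if v.shape[0] != len(ids):
            raise ValueError("row count must match number of stimulus ids")
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus ids must be unique")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 stimuli")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DissimilarityVector:
    """Canonical upper-triangle serialization of an RDM.

    Pairs are ordered row-major: (0,1), (0,2), ..., (0,n-1), (1,2), ...
    ``mask`` flags valid entries; masked-out entries are excluded from all
    statistics.
    """

    pairs: tuple[tuple[int, int], ...]
    values: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if v.shape != m.shape or v.ndim != 1:
            raise ValueError("values and mask must be aligned 1-D arrays")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    def __len__(self) -> int:
        return self.values.size

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle in canonical pair order."""
    return np.triu_indices(n, k=1)


@dataclass(frozen=True)
class RDM:
    """Square symmetric dissimilarity matrix over an ordered stimulus set."""

    stimulus_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    metric: str = "correlation"

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.stimulus_ids)
        object.__setattr__(self, "stimulus_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus ids must be unique")
        d = np.array(self.values, dtype=float)
        n = len(ids)
        if d.shape != (n, n):
            raise ValueError(f"values must be ({n}, {n})")
        if not np.allclose(np.nan_to_num(np.diag(d)), 0.0):
            raise ValueError("diagonal must be exactly 0")
        np.fill_diagonal(d, 0.0)
        finite = np.isfinite(d)
        if not np.array_equal(finite, finite.T):
            raise ValueError("missingness must be symmetric")
        both = finite & finite.T
        if not np.allclose(d[both], d.T[both], atol=1e-8):
            raise ValueError("matrix must be symmetric where defined")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d[~both] = np.nan
        d.setflags(write=False)
        object.__setattr__(self, "values", d)

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix of valid (non-missing) cells."""
        return np.isfinite(self.values)

    # -- canonical serialization -------------------------------------------------

    def vectorize(self) -> DissimilarityVector:
        """Upper triangle in canonical pair order, with a validity mask."""
        n = self.n_stimuli
        iu, ju = pair_index(n)
        vals = self.values[iu, ju]
        pairs = tuple(zip(iu.tolist(), ju.tolist()))
        return DissimilarityVector(pairs, np.nan_to_num(vals, nan=0.0), np.isfinite(vals))

    @classmethod
    def from_vector(
        cls,
        stimulus_ids: Sequence[str],
        vector: DissimilarityVector | np.ndarray,
        metric: str = "correlation",
        mask: np.ndarray | None = None,
    ) -> "RDM":
        n = len(stimulus_ids)
        if isinstance(vector, DissimilarityVector):
            vals, msk = vector.values, vector.mask
        else:
            vals = np.asarray(vector, dtype=float)
            msk = np.ones(vals.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
        iu, ju = pair_index(n)
        d = np.zeros((n, n))
        v = np.where(msk, vals, np.nan)
        d[iu, ju] = v
        d[ju, iu] = v
        return cls(tuple(stimulus_ids), d, metric)

    # -- structural operations ---------------------------------------------------

    def embed(self, target_ids: Sequence[str]) -> "RDM":
        """Embed into a larger stimulus set, filling the gaps with missing cells.

        Cells involving stimuli absent from this RDM become missing; present
        cells are unchanged. This is how a 92-stimulus matrix is placed into
        a 96-stimulus frame for comparison.
        """
        target_ids = tuple(str(i) for i in target_ids)
        pos = {s: k for k, s in enumerate(target_ids)}
        missing = [s for s in self.stimulus_ids if s not in pos]
        if missing:
            raise ValueError(f"ids absent from target set: {missing[:5]}")
        n = len(target_ids)
        d = np.full((n, n), np.nan)
        np.fill_diagonal(d, 0.0)
        idx = np.array([pos[s] for s in self.stimulus_ids])
        d[np.ix_(idx, idx)] = self.values
        return RDM(target_ids, d, self.metric)

    def subset(self, keep: Callable[[str], bool] | np.ndarray | Sequence[str]) -> "RDM":
        """Principal submatrix over the stimuli selected by ``keep``."""
        if callable(keep):
            sel = np.array([bool(keep(s)) for s in self.stimulus_ids])
            idx = np.flatnonzero(sel)
        else:
            arr = np.asarray(keep)
            if arr.dtype == bool:
                idx = np.flatnonzero(arr)
            elif np.issubdtype(arr.dtype, np.integer):
                idx = arr
            else:  # sequence of ids
                pos = {s: k for k, s in enumerate(self.stimulus_ids)}
                idx = np.array([pos[str(s)] for s in arr])
        if idx.size < 3:
            raise ValueError("a subset must keep at least 3 stimuli")
        ids = tuple(self.stimulus_ids[i] for i in idx)
        return RDM(ids, self.values[np.ix_(idx, idx)], self.metric)

    def rank_transform(self) -> "RDM":
        """Replace valid cells by their average ranks among valid cells."""
        vec = self.vectorize()
        vals = vec.values.copy()
        vals[vec.mask] = rankdata(vec.values[vec.mask], method="average")
        return RDM.from_vector(self.stimulus_ids, vals, self.metric, mask=vec.mask)

    def permute(self, perm: Sequence[int]) -> "RDM":
        """Simultaneous row/column permutation (stimulus-label randomization)."""
        perm = np.asarray(perm)
        return RDM(self.stimulus_ids, self.values[np.ix_(perm, perm)], self.metric)


def compute_rdm(features: FeatureMatrix, metric: str = "correlation") -> RDM:
    """Pairwise dissimilarity matrix of a representation's response patterns.

    For ``correlation``, d[i, j] = 1 - PearsonCorr(pattern_i, pattern_j).
    For ``sqeuclidean_normalized``, each pattern is mean-centered and scaled
    to unit norm before squared Euclidean distance, giving d = 2 * (1 - r).
    A single-feature representation (e.g. a classifier decision value) has
    scalar patterns, for which correlation across features is undefined; it
    is handled by z-scoring the feature across stimuli and taking squared
    Euclidean distances of the resulting scalars.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    X = features.values
    if X.shape[1] == 0:
        raise ValueError("representation has no features")
    if X.shape[1] == 1:
        if metric == "correlation":
            raise ValueError(
                "correlation distance is undefined for single-feature "
                "representations; use metric='sqeuclidean_normalized'"
            )
        z = X[:, 0] - X[:, 0].mean()
        sd = z.std()
        if sd > 0:
            z = z / sd
        d = (z[:, None] - z[None, :]) ** 2
        np.fill_diagonal(d, 0.0)
        return RDM(features.stimulus_ids, d, metric)

    const = np.ptp(X, axis=1) == 0
    if np.any(const):
        bad = [features.stimulus_ids[i] for i in np.flatnonzero(const)[:5]]
        raise ValueError(
            f"constant response pattern(s) for stimuli {bad}: "
            "correlation-based dissimilarity is undefined"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    U = Xc / norms
    r = np.clip(U @ U.T, -1.0, 1.0)
    d = (1.0 - r) if metric == "correlation" else 2.0 * (1.0 - r)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return RDM(features.stimulus_ids, d, metric)


def average_rdms(rdms: Iterable[RDM], rank: bool = False) -> RDM:
    """Element-wise mean of RDMs over a shared stimulus set, ignoring missing
    cells; optionally rank-transform each RDM first."""
    rdms = list(rdms)
    ids = rdms[0].stimulus_ids
    for r in rdms:
        if r.stimulus_ids != ids:
            raise ValueError("all RDMs must share the same stimulus ids")
    stack = np.array([(r.rank_transform() if rank else r).values for r in rdms])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return RDM(ids, mean, rdms[0].metric)


# -- delimited-text I/O ---------------------------------------------------------


def write_rdm(rdm: RDM, path) -> None:
    """Write as delimited text: first row/column are stimulus ids, missing
    cells are the token NaN."""
    df = pd.DataFrame(rdm.values, index=list(rdm.stimulus_ids), columns=list(rdm.stimulus_ids))
    df.to_csv(path, sep="\t", na_rep="NaN")

def read_rdm(path, metric: str = "correlation") -> RDM:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise ValueError("row and column stimulus ids must match")
    return RDM(ids, df.to_numpy(dtype=float), metric)


def write_features(features: FeatureMatrix, path) -> None:
    """Delimited text: header = feature names, first column = stimulus id."""
    cols = [f"f{j}" for j in range(features.n_features)]
    df = pd.DataFrame(features.values, columns=cols)
    df.insert(0, "stimulus_id", list(features.stimulus_ids))
    df.to_csv(path, sep="\t", index=False)


def read_features(path, model_name: str | None = None) -> FeatureMatrix:
    """Read a feature table; also accepts an HDF5 container with datasets
    ``stimulus_ids`` and ``values`` for large inputs."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["stimulus_ids"][:]]
            vals = f["values"][:]
        return FeatureMatrix(tuple(ids), vals, model_name or "model")
    df = pd.read_csv(path, sep=None, engine="python")
    ids = tuple(df.iloc[:, 0].astype(str))
    return FeatureMatrix(ids, df.iloc[:, 1:].to_numpy(dtype=float), model_name or "model")
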