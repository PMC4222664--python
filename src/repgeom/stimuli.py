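"""Stimulus sets with hierarchical category labels.

The stimulus hierarchy mirrors the standard object-vision layout used in
RSA studies of inferior temporal cortex: every stimulus is animate or
inanimate; animates split into faces and bodies, each of which splits into
human and non-human; inanimates split into natural and artificial. The ten
named categories (the six leaves plus the four internal nodes) are the
predictors of the category-cluster model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The ten category-cluster names, in canonical order.
CATEGORY_NAMES: tuple[str, ...] = (
    "animate",
    "inanimate",
    "face",
    "human_face",
    "nonhuman_face",
    "body",
    "human_body",
    "nonhuman_body",
    "natural_inanimate",
    "artificial_inanimate",
)

#: The six mutually exclusive leaves of the category tree.
LEAF_NAMES: tuple[str, ...] = (
    "human_face",
    "nonhuman_face",
    "human_body",
    "nonhuman_body",
    "natural_inanimate",
    "artificial_inanimate",
)

#: Internal node -> leaves it contains.
_TREE: dict[str, tuple[str, ...]] = {
    "face": ("human_face", "nonhuman_face"),
    "body": ("human_body", "nonhuman_body"),
    "animate": ("human_face", "nonhuman_face", "human_body", "nonhuman_body"),
    "inanimate": ("natural_inanimate", "artificial_inanimate"),
}


@dataclass(frozen=True)
class StimulusSet:
    """An ordered stimulus list with boolean membership in the ten categories.

    Parameters
    ----------
    ids
        Unique, ordered stimulus identifiers.
    labels
        Mapping category-name -> boolean membership array aligned to ``ids``.
        Must contain all ten :data:`CATEGORY_NAMES`.
    """

    ids: tuple[str, ...]
    labels: Mapping[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus ids must be unique")
        labels = {k: np.asarray(v, dtype=bool) for k, v in self.labels.items()}
        object.__setattr__(self, "labels", labels)
        missing = [c for c in CATEGORY_NAMES if c not in labels]
        if missing:
            raise ValueError(f"missing category labels: {missing}")
        n = len(ids)
        for name, v in labels.items():
            if v.shape != (n,):
                raise ValueError(f"label '{name}' has shape {v.shape}, expected ({n},)")
        self._check_tree(labels)

    @staticmethod
    def _check_tree(labels: Mapping[str, np.ndarray]) -> None:
        if not np.array_equal(labels["animate"], ~labels["inanimate"]):
            raise ValueError("animate and inanimate must be complementary")
        for parent, leaves in _TREE.items():
            union = np.zeros_like(labels[parent])
            for leaf in leaves:
                if np.any(labels[leaf] & ~labels[parent]):
                    raise ValueError(f"'{leaf}' members must all belong to '{parent}'")
                if np.any(labels[leaf] & union):
                    raise ValueError(f"children of '{parent}' must be disjoint")
                union |= labels[leaf]
            if not np.array_equal(union, labels[parent]):
                raise ValueError(f"children of '{parent}' must cover it")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_stimuli(self) -> int:
        return len(self.ids)

    def members(self, category: str) -> np.ndarray:
        """Boolean membership vector for ``category``."""
        return self.labels[category]

    def leaf_of(self) -> np.ndarray:
        """Leaf-category name per stimulus (object array)."""
        out = np.empty(len(self), dtype=object)
        for leaf in LEAF_NAMES:
            out[self.labels[leaf]] = leaf
        return out

    def permuted(self, perm: Sequence[int]) -> "StimulusSet":
        """Reassign the full label tuple of each stimulus according to ``perm``.

        Permuting whole label tuples preserves every containment invariant,
        which is what a category-label randomization test requires.
        """
        perm = np.asarray(perm)
        labels = {k: v[perm] for k, v in self.labels.items()}
        return StimulusSet(self.ids, labels)

    def subset(self, keep: np.ndarray) -> "StimulusSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        ids = tuple(self.ids[i] for i in idx)
        # Subsetting can break complementarity of internal nodes, so rebuild
        # from the leaves, which always remain a partition.
        return from_leaves(ids, self.leaf_of()[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({k: self.labels[k] for k in CATEGORY_NAMES})
        df.insert(0, "stimulus_id", list(self.ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSet":
        """Build from a table with a ``stimulus_id`` column and either the ten
        boolean category columns or a single ``leaf`` column."""
        ids = tuple(df["stimulus_id"].astype(str))
        if "leaf" in df.columns:
            return from_leaves(ids, df["leaf"].to_numpy())
        labels = {c: df[c].to_numpy(dtype=bool) for c in CATEGORY_NAMES}
        return cls(ids, labels)


def from_leaves(ids: Iterable[str], leaves: Sequence[str]) -> StimulusSet:
    """Construct a :class:`StimulusSet` from a leaf-category assignment."""
    ids = tuple(str(i) for i in ids)
    leaves = np.asarray(leaves, dtype=object)
    unknown = set(leaves) - set(LEAF_NAMES)
    if unknown:
        raise ValueError(f"unknown leaf categories: {sorted(unknown)}")
    labels: dict[str, np.ndarray] = {
        leaf: leaves == leaf for leaf in LEAF_NAMES
    }
    for parent, children in _TREE.items():
        labels[parent] = np.any([labels[c] for c in children], axis=0)
    return StimulusSet(ids, labels)


def default_stimulus_set(n_stimuli: int = 96) -> StimulusSet:
    """The study-shaped stimulus composition, scaled to ``n_stimuli``.

    Half the stimuli are animate; animates split equally into faces and
    bodies, each half human / non-human; inanimates split equally into
    natural and artificial. ``n_stimuli`` must be a multiple of 8. The
    default 96 gives 48 animates (12 human faces, 12 animal faces, 12 human
    bodies, 12 animal bodies) and 48 inanimates (24 natural, 24 artificial).
    """
    if n_stimuli % 8 != 0 or n_stimuli < 8:
        raise ValueError("n_stimuli must be a positive multiple of 8")
    u = n_stimuli // 8
    leaves = (
        ["human_face"] * u
        + ["nonhuman_face"] * u
        + ["human_body"] * u
        + ["nonhuman_body"] * u
        + ["natural_inanimate"] * (2 * u)
        + ["artificial_inanimate"] * (2 * u)
    )
    ids = [f"s{i:03d}" for i in range(n_stimuli)]
    return from_leaves(ids, leaves)
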