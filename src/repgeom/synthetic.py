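"""Synthetic data emulating the study's structure.

The pipeline's natural inputs — model feature matrices, multi-subject
brain RDMs, ground-truth non-negative mixtures — are generated here so
every stage can be exercised and calibrated without external recordings.

Feature generation uses a category-component model: each of the ten
hierarchical categories contributes a shared random direction scaled by a
per-category cluster tightness, every stimulus adds an idiosyncratic
exemplar direction, and i.i.d. Gaussian feature noise sits on top. With
all tightnesses zero the representation has no categorical structure
(expected categoricality ~ 0); raising one category's tightness pulls its
members together in the representational space.

Subject ensembles apply independent symmetric Gaussian cell noise to a
shared true RDM, the simplest model of inter-subject RDM variability,
clipped to the metric's valid range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rdm import RDM, FeatureMatrix
from .noise_ceiling import SubjectEnsemble
from .recombination import ComponentSet, WeightVector, mixture_rdm
from .stimuli import CATEGORY_NAMES, StimulusSet, default_stimulus_set


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-shaped generation parameters.

    Defaults mirror the study's composition: 96 stimuli, half animate
    (24 faces and 24 bodies, each half human), 48 inanimates split
    natural/artificial, four subjects.
    """

    n_stimuli: int = 96
    n_features: int = 100
    tightness: dict = field(default_factory=dict)  # category -> cluster strength
    feature_noise_sd: float = 1.0
    n_subjects: int = 4
    subject_noise_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.tightness) - set(CATEGORY_NAMES)
        if unknown:
            raise ValueError(f"unknown categories in tightness: {sorted(unknown)}")
        if any(v < 0 for v in self.tightness.values()):
            raise ValueError("tightness values must be >= 0")
        if self.feature_noise_sd < 0 or self.subject_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")

    def stimulus_set(self) -> StimulusSet:
        return default_stimulus_set(self.n_stimuli)


def generate_model_features(spec: SyntheticSpec, model_name: str = "synthetic") -> FeatureMatrix:
    """Category-structured features: per-category shared components scaled by
    tightness, plus exemplar identity and i.i.d. feature noise. Deterministic
    given ``spec.seed``."""
    if spec.n_features < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(spec.seed)
    stim = spec.stimulus_set()
    n, f = spec.n_stimuli, spec.n_features
    X = np.zeros((n, f))
    for name in CATEGORY_NAMES:
        direction = rng.standard_normal(f)
        g = float(spec.tightness.get(name, 0.0))
        if g > 0:
            X[stim.members(name)] += g * direction
    X += rng.standard_normal((n, f))  # exemplar identity
    X += spec.feature_noise_sd * rng.standard_normal((n, f))
    return FeatureMatrix(stim.ids, X, model_name)


def generate_subject_ensemble(
    true_rdm: RDM,
    n_subjects: int = 4,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> SubjectEnsemble:
    """Subject RDMs = true RDM + independent symmetric zero-diagonal Gaussian
    cell noise, clipped to the metric's valid range."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = true_rdm.n_stimuli
    hi = 2.0 if true_rdm.metric == "correlation" else 4.0
    rdms = []
    for _ in range(n_subjects):
        noise = rng.standard_normal((n, n)) * noise_sd
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        d = true_rdm.values + noise
        d = np.clip(d, 0.0, hi)
        np.fill_diagonal(d, 0.0)
        rdms.append(RDM(true_rdm.stimulus_ids, d, true_rdm.metric))
    return SubjectEnsemble(tuple(rdms))


def generate_mixture(
    components: ComponentSet,
    true_weights: WeightVector | np.ndarray,
    cell_noise_sd: float = 0.0,
    seed: int | None = None,
) -> RDM:
    """Ground-truth reference RDM = sum_k w_k RDM_k + optional symmetric
    cell noise; the oracle for weight-recovery tests."""
    w = true_weights.w if isinstance(true_weights, WeightVector) else np.asarray(true_weights, float)
    if np.any(w < 0):
        raise ValueError("true weights must be non-negative")
    ref = mixture_rdm(components, w)
    if cell_noise_sd == 0.0:
        return ref
    rng = np.random.default_rng(seed)
    n = ref.n_stimuli
    noise = rng.standard_normal((n, n)) * cell_noise_sd
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    d = ref.values + noise
    np.fill_diagonal(d, 0.0)
    return RDM(ref.stimulus_ids, d, ref.metric)


def generate_component_models(
    n_components: int,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> ComponentSet:
    """Several independent synthetic models over the same stimulus set, as a
    component set for reweighting experiments."""
    base = seed if seed is not None else spec.seed
    ss = np.random.SeedSequence(base)
    items = []
    for k, child in enumerate(ss.spawn(n_components)):
        sub = SyntheticSpec(
            n_stimuli=spec.n_stimuli,
            n_features=spec.n_features,
            tightness=spec.tightness,
            feature_noise_sd=spec.feature_noise_sd,
            n_subjects=spec.n_subjects,
            subject_noise_sd=spec.subject_noise_sd,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        items.append((f"model_{k}", generate_model_features(sub, f"model_{k}")))
    return ComponentSet.from_items(items)
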