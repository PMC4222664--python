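"""Shared fixtures and independent oracles."""

from itertools import combinations

import numpy as np
import pytest

import repgeom as rg


def tau_a_brute(x, y) -> float:
    """O(m^2) pair-enumeration oracle for Kendall tau-a: concordant minus
    discordant over all m(m-1)/2 pairs, ties counting as neither."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = x.size
    s = 0.0
    for a, b in combinations(range(m), 2):
        s += np.sign(x[a] - x[b]) * np.sign(y[a] - y[b])
    return s / (m * (m - 1) / 2)


def random_rdm(rng: np.random.Generator, n: int, ids=None) -> rg.RDM:
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    ids = ids or tuple(f"s{i}" for i in range(n))
    return rg.RDM(ids, a)


def spawn_seeds(*entropy, n: int) -> list[int]:
    """Reproducible derived seeds below 2**31."""
    ss = np.random.SeedSequence(list(entropy))
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stimuli16():
    return rg.default_stimulus_set(16)


@pytest.fixture
def stimuli48():
    return rg.default_stimulus_set(48)


@pytest.fixture
def features16():
    spec = rg.SyntheticSpec(n_stimuli=16, n_features=30,
                            tightness={"animate": 1.0}, seed=101)
    return rg.generate_model_features(spec)
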