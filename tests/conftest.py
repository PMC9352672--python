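"""Shared fixtures: constructed feature clusters and a small trained map."""

from __future__ import annotations

import numpy as np
import pytest

from motifscope import behaviour_map as bm


def make_cluster_features(n_clusters: int = 3, n_per: int = 60,
                          dim: int = 746, spread: float = 1.0,
                          noise: float = 0.01,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated non-negative feature clusters shaped like real ones.

    Each vector is two unit-sum halves (234 frequency bins + 512 time bins)
    so the KL machinery of the behaviour map applies. Cluster centres are
    random profiles concentrated on disjoint-ish supports; renditions vary
    along two smooth latent directions (amplitude ``spread``) plus a small
    exchangeable noise floor, mimicking how real renditions vary along a
    low-dimensional articulation manifold rather than i.i.d. per bin.
    """
    rng = np.random.default_rng(seed)
    nf = 234
    X, y = [], []
    for c in range(n_clusters):
        centre = rng.gamma(2.0, 1.0, dim) + 1e-3
        support = rng.permutation(dim)[: dim // 3]
        centre[support] *= 20
        u, v_dir = rng.normal(0, 1, (2, dim))
        for _ in range(n_per):
            a, b = rng.normal(0, spread, 2)
            v = centre * np.exp(a * u * 0.1 + b * v_dir * 0.1
                                + rng.normal(0, noise, dim))
            v[:nf] /= v[:nf].sum()
            v[nf:] /= v[nf:].sum()
            X.append(v)
            y.append(c)
    return np.asarray(X), np.asarray(y)


@pytest.fixture(scope="session")
def cluster_data():
    return make_cluster_features(n_clusters=3, n_per=60, seed=0)


@pytest.fixture(scope="session")
def small_model(cluster_data):
    X, _ = cluster_data
    return bm.train_embedding(X, perplexity=10, seed=0)


@pytest.fixture(scope="session")
def small_map(small_model):
    return bm.build_behaviour_map(small_model, kernel_bandwidth="auto",
                                  min_peak_distance="auto")
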