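"""Comparison models: hard-assignment directional clustering and
multisubject Euclidean archetypal analysis.

Directional clustering keeps the directional model's generator C and
polarity-invariant squared-cosine distance but constrains each mixing
column to a single nonzero entry (l0 instead of l1), turning the S update
into a k-means-style assignment of samples to centroids ``Xf @ c_k``.

Euclidean archetypal analysis uses the classic least-squares loss
``sum_views ||X - X C S||_F^2`` with the raw (Frobenius-scaled) data as
both the target and the archetype dictionary — no sphere projection, no
hemisphere flipping — so it explicitly models the scale of the data.
Both baselines run through the same l1-invariant projected-gradient
machinery as the directional model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MultiViewData
from .model import (
    DAAModel,
    FitConfig,
    fit_daa,
    fit_with_restarts,
)

__all__ = [
    "HardAssignment",
    "assign_hard",
    "fit_directional_clustering",
    "euclidean_sse",
    "fit_euclidean_aa",
]


@dataclass
class HardAssignment:
    """Cluster labels for one view plus the equivalent one-hot S."""

    labels: np.ndarray  # length N, archetype index per sample
    S: np.ndarray       # K x N one-hot mixing matrix


def assign_hard(X: np.ndarray, Xf: np.ndarray, C: np.ndarray) -> HardAssignment:
    """Assign each sample to the centroid maximizing the squared cosine.

    ``k*(n) = argmax_k (x_n^T Xf c_k / ||Xf c_k||)^2``; antipodal samples
    map to the same centroid.  Ties resolve to the smallest index.
    Degenerate centroids (norm < 1e-12) raise an error naming k.
    """
    A = Xf @ C
    norms = np.linalg.norm(A, axis=0)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        raise ValueError(f"degenerate centroid(s) k={bad.tolist()} with near-zero norm")
    scores = ((X.T @ A) / norms) ** 2
    labels = np.argmax(scores, axis=1)
    S = np.zeros((C.shape[1], X.shape[1]))
    S[labels, np.arange(X.shape[1])] = 1.0
    return HardAssignment(labels=labels, S=S)


def fit_directional_clustering(
    data: MultiViewData, config: FitConfig,
    rng: np.random.Generator | None = None,
) -> DAAModel:
    """One directional-clustering fit (Watson loss, one-hot S per view)."""
    cfg = _with_model(config, "dir_clustering")
    return fit_daa(data, cfg, rng=rng)


def euclidean_sse(
    X_views, Xt_views, C: np.ndarray, S_views,
) -> float:
    """Least-squares reconstruction error summed over views:
    ``sum_m,b ||X - Xt C S||_F^2``.  Accepts single matrices or sequences."""
    if isinstance(X_views, np.ndarray):
        X_views, Xt_views, S_views = [X_views], [Xt_views], [S_views]
    total = 0.0
    for X, Xt, S in zip(X_views, Xt_views, S_views):
        R = X - Xt @ C @ S
        total += float(np.sum(R * R))
    return total


def fit_euclidean_aa(
    data: MultiViewData, config: FitConfig,
    rng: np.random.Generator | None = None,
) -> DAAModel:
    """One Euclidean archetypal-analysis fit (least-squares loss)."""
    cfg = _with_model(config, "euclidean_aa")
    return fit_daa(data, cfg, rng=rng)


def _with_model(config: FitConfig, model: str) -> FitConfig:
    if config.model == model:
        return config
    import dataclasses

    return dataclasses.replace(config, model=model)


def fit_baseline_with_restarts(data: MultiViewData, config: FitConfig, model: str):
    """Best-of-restarts protocol for either baseline (thin wrapper)."""
    return fit_with_restarts(data, _with_model(config, model))
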