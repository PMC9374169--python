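"""Model comparison and consistency metrics.

Includes soft-assignment normalized mutual information (NMI) between
mixing matrices, the cyclic run-to-run consistency protocol, archetype
recovery scoring against ground truth, a deterministic loss-curve knee
criterion, occupation-based archetype ordering, and circular trajectory
coordinates for visualizing mixing matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import DAAModel

__all__ = [
    "nmi",
    "consistency_protocol",
    "archetype_recovery",
    "knee_of_loss_curve",
    "order_archetypes",
    "trajectory_coordinates",
    "EvaluationReport",
]

log = logging.getLogger(__name__)

_SIMPLEX_ATOL = 1e-6


def _check_simplex(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix")
    if np.any(S < -_SIMPLEX_ATOL):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(S.sum(axis=0), 1.0, atol=_SIMPLEX_ATOL):
        raise ValueError(f"{name} columns must sum to 1")
    return S


def _soft_mi(P: np.ndarray) -> float:
    """Mutual information of a joint distribution matrix (natural log;
    0 log 0 treated as 0).  The NMI normalization cancels the log base."""
    pk = P.sum(axis=1, keepdims=True)
    pk_ = P.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = P * np.log(P / (pk * pk_))
    return float(np.sum(terms[P > 0]))


def nmi(S_r: np.ndarray, S_rp: np.ndarray) -> float:
    """Soft-assignment normalized mutual information between two
    column-stochastic mixing matrices over the same samples.

    The joint distribution is ``p(k, k') = (1/N) sum_n s^r_{kn} s^{r'}_{k'n}``
    and ``NMI = 2 MI(S_r, S_r') / (MI(S_r, S_r) + MI(S_r', S_r'))``.
    The value lies in [0, 1], equals 1 for identical inputs, and is
    invariant to row permutations of either input.
    """
    S_r = _check_simplex(S_r, "S_r")
    S_rp = _check_simplex(S_rp, "S_r'")
    if S_r.shape != S_rp.shape:
        raise ValueError(f"shape mismatch: {S_r.shape} vs {S_rp.shape}")
    N = S_r.shape[1]
    mi_rr = _soft_mi(S_r @ S_r.T / N)
    mi_pp = _soft_mi(S_rp @ S_rp.T / N)
    denom = mi_rr + mi_pp
    if denom == 0.0:
        # both marginals carry no information (e.g. K = 1): identical
        # degenerate assignments
        return 1.0
    return 2.0 * _soft_mi(S_r @ S_rp.T / N) / denom


def consistency_protocol(models: list[DAAModel]) -> dict:
    """Cyclic run-to-run consistency: NMI for adjacent pairs 1-2, 2-3, ...,
    R-1 only (avoiding all-pairs dependence), averaged over the views
    present in each model.  Returns per-pair means and the overall mean."""
    if len(models) < 2:
        raise ValueError("need at least 2 models for the consistency protocol")
    R = len(models)
    pair_values = []
    for i in range(R):
        a, b = models[i], models[(i + 1) % R]
        per_view = [nmi(a.S[k], b.S[k]) for k in sorted(a.S)]
        pair_values.append(float(np.mean(per_view)))
    return {
        "pairs": [(i + 1, (i + 1) % R + 1) for i in range(R)],
        "pair_nmi": pair_values,
        "mean_nmi": float(np.mean(pair_values)),
    }


def archetype_recovery(
    A_fit: np.ndarray, A_true: np.ndarray
) -> tuple[float, list[tuple[int, int]]]:
    """Mean matched absolute cosine between fitted and true archetypes.

    Solves the optimal one-to-one assignment maximizing the summed
    |cosine|; the absolute value makes the score polarity-invariant.
    Requires at least as many fitted as true archetypes.
    """
    A_fit = np.asarray(A_fit, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_fit.shape[0] != A_true.shape[0]:
        raise ValueError("archetype dimension mismatch")
    if A_fit.shape[1] < A_true.shape[1]:
        raise ValueError("need K_fit >= K_true")

    def unit(M):
        n = np.linalg.norm(M, axis=0)
        n = np.where(n == 0, 1.0, n)
        return M / n

    cos = np.abs(unit(A_fit).T @ unit(A_true))  # K_fit x K_true
    rows, cols = linear_sum_assignment(-cos)
    matching = list(zip(rows.tolist(), cols.tolist()))
    score = float(cos[rows, cols].mean())
    return score, matching


def knee_of_loss_curve(losses: dict[int, float]) -> int:
    """Deterministic elbow criterion on a loss-vs-K curve.

    For interior K, the drop ratio is
    ``(L(K-1) - L(K)) / (L(K) - L(K+1) + eps)`` with
    ``eps = 1e-12 * |L(K_min)|``; the knee is the interior K maximizing it,
    ties resolving to the smallest K.  Requires losses at >= 4 consecutive
    K values.  Non-monotone curves (restart noise) are allowed but logged.
    """
    ks = sorted(losses)
    if len(ks) < 4:
        raise ValueError("need losses at >= 4 K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    L = np.array([float(losses[k]) for k in ks])
    if np.any(np.diff(L) > 0):
        log.warning("loss curve is not monotone decreasing (restart noise?)")
    eps = 1e-12 * abs(L[0])
    drops = -np.diff(L)  # drops[i] = L(k_i) - L(k_{i+1})
    ratios = drops[:-1] / (drops[1:] + eps)
    best = int(np.argmax(ratios))  # first max -> smallest K on ties
    return ks[1 + best]


def order_archetypes(model: DAAModel) -> DAAModel:
    """Permute archetypes by descending total occupation of S.

    The occupation of archetype k is its summed mixing weight over all
    views and samples; C columns, S rows and archetype columns are permuted
    consistently, leaving the loss unchanged.  Ties keep the original
    order (stable sort).
    """
    import dataclasses

    K = model.n_archetypes
    occupation = np.zeros(K)
    for S in model.S.values():
        occupation += S.sum(axis=1)
    order = np.argsort(-occupation, kind="stable")
    if isinstance(model.C, dict):
        C = {k: v[:, order] for k, v in model.C.items()}
    else:
        C = model.C[:, order]
    S = {k: v[order, :] for k, v in model.S.items()}
    arche = {k: v[:, order] for k, v in model.archetypes.items()}
    return dataclasses.replace(model, C=C, S=S, archetypes=arche)


def occupation_percentages(model: DAAModel) -> np.ndarray:
    """Per-archetype share of the total mixing weight, in percent."""
    occ = np.zeros(model.n_archetypes)
    for S in model.S.values():
        occ += S.sum(axis=1)
    return 100.0 * occ / occ.sum()


def smooth_simplex_rows(S: np.ndarray, window: int) -> np.ndarray:
    """Centered rectangular (moving-average) smoothing of each row, with
    truncated windows at the edges.  Because every row is averaged over the
    same sample positions, column sums are preserved; columns are
    renormalized anyway to absorb rounding."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return S.copy()
    N = S.shape[1]
    kernel = np.ones(window)
    counts = np.convolve(np.ones(N), kernel, mode="same")
    sm = np.vstack([np.convolve(row, kernel, mode="same") / counts for row in S])
    return sm / sm.sum(axis=0)


def trajectory_coordinates(S: np.ndarray, window: int = 1) -> np.ndarray:
    """2 x N trajectory of a mixing matrix in the plane.

    Archetype k is anchored at ``(cos 2*pi*k/K, sin 2*pi*k/K)`` on the unit
    circle; each (optionally row-smoothed) mixing column maps to the convex
    combination of the anchors, so uniform mixing sits at the origin and
    one-hot columns sit on their anchor.
    """
    S = _check_simplex(S, "S")
    K = S.shape[0]
    sm = smooth_simplex_rows(S, window)
    angles = 2.0 * np.pi * np.arange(K) / K
    U = np.vstack([np.cos(angles), np.sin(angles)])  # 2 x K
    return U @ sm


@dataclass
class EvaluationReport:
    """Sweep results: per-K losses with SEM over outer runs, consistency
    NMI, knee per model, and recovery scores when ground truth is known."""

    losses: dict = field(default_factory=dict)       # model -> {K: [outer losses]}
    mean_loss: dict = field(default_factory=dict)    # model -> {K: mean}
    sem_loss: dict = field(default_factory=dict)     # model -> {K: sem}
    nmi: dict = field(default_factory=dict)          # model -> {K: mean cyclic NMI}
    knee: dict = field(default_factory=dict)         # model -> K*
    recovery: dict = field(default_factory=dict)     # model -> {K: score}

    def to_dict(self) -> dict:
        return {
            "losses": self.losses,
            "mean_loss": self.mean_loss,
            "sem_loss": self.sem_loss,
            "nmi": self.nmi,
            "knee": self.knee,
            "recovery": self.recovery,
        }
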