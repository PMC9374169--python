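"""Directional archetypal analysis: Watson loss, gradients and the
multiview alternating projected-gradient fit.

The model approximates each view's data matrix X (channels x samples) by
``X_hat = X_tilde_f @ C @ S`` where ``X_tilde_f`` is the hemisphere-flipped
unit-norm data, ``C`` (samples x K, column-stochastic) is the archetype
generator shared across all views, and ``S`` (K x samples,
column-stochastic, one per view) mixes the view-specific archetypes
``A = X_tilde_f @ C`` back into samples.

The loss is the negative sum of squared cosines between each raw sample and
its reconstruction,

    L_W = - sum_n ( x_n^T x_hat_n / ||x_hat_n|| )^2 ,

summed over views.  Squaring the cosine makes the loss invariant to the
polarity of both the data and the reconstruction (axial symmetry, as for
the Watson distribution on the projective hypersphere), and because x_n
carries its raw norm, each sample is weighted by its squared amplitude
kappa_n — high-amplitude (high-SNR) samples dominate.

Optimization alternates projected-gradient updates of C and S in
l1-normalization-invariant variables, with multiplicative step-size
adaptation (shrink by 1/2 on a worse loss, grow by 1.1 on an improvement)
and acceptance only on a strict decrease, which makes every loss trace
non-increasing by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import MultiViewData, ViewKey

__all__ = [
    "FitConfig",
    "DAAModel",
    "reconstruct",
    "watson_loss",
    "gradients",
    "fit_daa",
    "fit_with_restarts",
]

log = logging.getLogger(__name__)

SHRINK = 0.5
GROW = 1.1
EPS_Q = 1e-12


@dataclass
class FitConfig:
    """Settings for one model fit / restart protocol.

    ``n_archetypes`` is K.  ``n_restarts`` random initializations are run
    per fit keeping the lowest loss; ``n_outer`` such best-of fits are kept
    for consistency analysis.  ``sharing_mode`` controls how conditions are
    tied together: ``per_condition_S`` (one shared C, one S per view
    including condition), ``concat_conditions`` (conditions concatenated in
    time so C spans all of them), or ``no_correspondence`` (fully
    independent model per view).
    """

    n_archetypes: int
    model: str = "daa"  # daa | dir_clustering | euclidean_aa
    sharing_mode: str = "per_condition_S"
    n_restarts: int = 100
    n_outer: int = 5
    max_iter: int = 10_000
    rel_tol: float = 1e-8
    seed: int | None = None
    init_step: float = 1.0
    max_halvings: int = 20

    def __post_init__(self) -> None:
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.model not in {"daa", "dir_clustering", "euclidean_aa"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.sharing_mode not in {
            "per_condition_S", "concat_conditions", "no_correspondence",
        }:
            raise ValueError(f"unknown sharing_mode {self.sharing_mode!r}")


@dataclass
class DAAModel:
    """A fitted model: generator, per-view mixing matrices and loss trace."""

    model_type: str
    C: "np.ndarray | dict[ViewKey, np.ndarray]"
    S: dict[ViewKey, np.ndarray]
    archetypes: dict[ViewKey, np.ndarray]
    loss_trace: np.ndarray
    config: FitConfig
    seed: int | None = None
    condition_slices: dict | None = field(default=None)

    @property
    def loss(self) -> float:
        return float(self.loss_trace[-1])

    @property
    def n_archetypes(self) -> int:
        return self.config.n_archetypes


# ---------------------------------------------------------------------------
# Loss and gradients (reference, full-matrix form)


def reconstruct(Xf: np.ndarray, C: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Reconstruction ``X_hat = Xf @ C @ S``; columns are convex
    combinations of the archetypes ``Xf @ C``."""
    D, N = Xf.shape
    if C.shape[0] != N or S.shape[0] != C.shape[1] or S.shape[1] != N:
        raise ValueError(
            f"shape mismatch: Xf {Xf.shape}, C {C.shape}, S {S.shape}"
        )
    return Xf @ C @ S


def watson_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Watson-inspired loss  -sum_n (x_n^T x_hat_n / ||x_hat_n||)^2.

    Near-zero reconstruction norms are guarded by a small epsilon so the
    value is always finite.
    """
    z = np.einsum("dn,dn->n", X, X_hat)
    q = np.einsum("dn,dn->n", X_hat, X_hat)
    return float(-np.sum(z * z / (q + EPS_Q)))


def gradients(
    X: np.ndarray, Xf: np.ndarray, C: np.ndarray, S: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the minimized loss -sum z_n^2/q_n w.r.t. C and S.

    Uses the matrices T = X Dq^{-1/2} - X_hat Dq^{-3/2} Dz and
    V = Dz Dq^{-1/2}: the gradient of sum z^2/q w.r.t. X_hat is 2 T V, so
    the minimized (negated) loss has gradients -2 Xf^T T V S^T (for C) and
    -2 C^T Xf^T T V (for S).  Signs are fixed by the finite-difference
    oracle in the test suite.
    """
    X_hat = Xf @ C @ S
    z = np.einsum("dn,dn->n", X, X_hat)
    q = np.einsum("dn,dn->n", X_hat, X_hat) + EPS_Q
    TV = X * (z / q) - X_hat * (z * z / (q * q))
    grad_C = -2.0 * Xf.T @ (TV @ S.T)
    grad_S = -2.0 * (Xf @ C).T @ TV
    return grad_C, grad_S


# ---------------------------------------------------------------------------
# Problems: Watson and least-squares share one optimizer.
#
# A problem holds per-view matrices and knows how to evaluate per-sample
# loss terms and gradients from a per-view cache (A = dictionary @ C,
# A^T A and X^T A), which is recomputed once per C update.


class WatsonProblem:
    """Per-view loss terms and gradients for the directional model."""

    def __init__(self, data: MultiViewData):
        self.keys: list[ViewKey] = data.keys
        self.X = [data.views[k] for k in self.keys]
        self.dictionary = [data.x_tilde_flipped[k] for k in self.keys]
        self.N = data.n_samples

    def make_cache(self, C: np.ndarray) -> list[tuple[np.ndarray, ...]]:
        cache = []
        for X, Xf in zip(self.X, self.dictionary):
            A = Xf @ C
            cache.append((A, A.T @ A, X.T @ A))
        return cache

    @staticmethod
    def _zq(S, AtA, XtA):
        z = np.einsum("nk,kn->n", XtA, S)
        AS = AtA @ S
        q = np.einsum("kn,kn->n", S, AS) + EPS_Q
        return z, q, AS

    def loss_terms(self, v: int, S: np.ndarray, cache) -> np.ndarray:
        _, AtA, XtA = cache[v]
        z, q, _ = self._zq(S, AtA, XtA)
        return -(z * z) / q

    def grad_S(self, v: int, S: np.ndarray, cache) -> np.ndarray:
        _, AtA, XtA = cache[v]
        z, q, AS = self._zq(S, AtA, XtA)
        return -2.0 * (XtA.T * (z / q) - AS * (z * z / (q * q)))

    def grad_C(self, C: np.ndarray, S_list: Sequence[np.ndarray]) -> np.ndarray:
        G = None
        for X, Xf, S in zip(self.X, self.dictionary, S_list):
            g, _ = gradients(X, Xf, C, S)
            G = g if G is None else G + g
        return G

    def hard_scores(self, v: int, cache) -> np.ndarray:
        """(N x K) squared normalized inner products for hard assignment."""
        A, AtA, XtA = cache[v]
        norms = np.sqrt(np.diag(AtA))
        if np.any(norms < 1e-12):
            bad = np.flatnonzero(norms < 1e-12).tolist()
            raise ValueError(f"degenerate centroid(s) with near-zero norm: {bad}")
        return (XtA / norms) ** 2


class LeastSquaresProblem:
    """Euclidean archetypal analysis: dictionary is the raw (scaled) X,
    loss is the squared Frobenius residual per view."""

    def __init__(self, data: MultiViewData):
        self.keys: list[ViewKey] = data.keys
        self.X = [data.views[k] for k in self.keys]
        self.dictionary = self.X
        self.N = data.n_samples
        self._xn2 = [np.einsum("dn,dn->n", X, X) for X in self.X]

    def make_cache(self, C: np.ndarray) -> list[tuple[np.ndarray, ...]]:
        cache = []
        for X in self.X:
            A = X @ C
            cache.append((A, A.T @ A, X.T @ A))
        return cache

    def loss_terms(self, v: int, S: np.ndarray, cache) -> np.ndarray:
        _, AtA, XtA = cache[v]
        z = np.einsum("nk,kn->n", XtA, S)
        AS = AtA @ S
        q = np.einsum("kn,kn->n", S, AS)
        return self._xn2[v] - 2.0 * z + q

    def grad_S(self, v: int, S: np.ndarray, cache) -> np.ndarray:
        _, AtA, XtA = cache[v]
        return 2.0 * (AtA @ S - XtA.T)

    def grad_C(self, C: np.ndarray, S_list: Sequence[np.ndarray]) -> np.ndarray:
        G = None
        for X, S in zip(self.X, S_list):
            R = (X @ C) @ S - X
            g = 2.0 * X.T @ (R @ S.T)
            G = g if G is None else G + g
        return G


def _total_loss(problem, S_list, cache) -> float:
    return float(sum(problem.loss_terms(v, S, cache).sum()
                     for v, S in enumerate(S_list)))


# ---------------------------------------------------------------------------
# Simplex machinery


def _recast_gradient(G: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Gradient through the l1-normalization-invariant reparameterization
    w_tilde = w / sum(w): for columns already on the simplex this is the
    plain gradient minus its W-weighted column mean (quotient rule)."""
    return G - np.sum(G * W, axis=0, keepdims=True)


def _project_columns(M: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Clip to the nonnegative orthant and renormalize columns to sum 1.
    Columns that collapse to all zeros fall back to their previous value."""
    M = np.maximum(M, 0.0)
    s = M.sum(axis=0)
    dead = s <= 0.0
    if dead.any():
        M[:, dead] = fallback[:, dead]
        s = M.sum(axis=0)
    return M / s


def _init_simplex(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Rate-1 exponential draws, columns normalized to the simplex."""
    M = rng.exponential(scale=1.0, size=shape)
    return M / M.sum(axis=0)


# ---------------------------------------------------------------------------
# Updates


def _update_C(problem, C, S_list, mu_C, loss, cache, cfg: FitConfig):
    """One projected-gradient C update with step-halving line search.

    Accepts only a strict decrease of the total loss (growing the step by
    1.1); otherwise halves the step up to ``max_halvings`` times and keeps
    the old C.
    """
    G = _recast_gradient(problem.grad_C(C, S_list), C)
    if not np.any(G):
        return C, mu_C * GROW, loss, cache
    for _ in range(cfg.max_halvings):
        cand = _project_columns(C - mu_C * G, fallback=C)
        cand_cache = problem.make_cache(cand)
        new_loss = _total_loss(problem, S_list, cand_cache)
        if new_loss < loss:
            return cand, mu_C * GROW, new_loss, cand_cache
        mu_C *= SHRINK
    log.debug("C update fully rejected after %d halvings", cfg.max_halvings)
    return C, mu_C, loss, cache


def _update_S_view(problem, v, S, mu, cache):
    """One per-sample projected-gradient sweep over the columns of one
    view's S.  Each column is accepted only if its own loss term strictly
    decreases; per-sample step sizes adapt independently."""
    terms = problem.loss_terms(v, S, cache)
    G = _recast_gradient(problem.grad_S(v, S, cache), S)
    cand = _project_columns(S - mu * G, fallback=S)
    new_terms = problem.loss_terms(v, cand, cache)
    accept = new_terms < terms
    S = S.copy()
    S[:, accept] = cand[:, accept]
    mu = np.where(accept, mu * GROW, mu * SHRINK)
    return S, mu, np.where(accept, new_terms, terms)


def _assign_hard_view(problem: WatsonProblem, v, cache) -> np.ndarray:
    """l0-constrained S: one-hot assignment by maximal squared cosine."""
    scores = problem.hard_scores(v, cache)
    labels = np.argmax(scores, axis=1)
    K = scores.shape[1]
    S = np.zeros((K, scores.shape[0]))
    S[labels, np.arange(scores.shape[0])] = 1.0
    return S


# ---------------------------------------------------------------------------
# Fitting

_PATIENCE = 3  # consecutive below-tolerance iterations before stopping


def _fit_single(problem, cfg: FitConfig, rng: np.random.Generator):
    K = cfg.n_archetypes
    N = problem.N
    if K > N:
        raise ValueError(f"n_archetypes={K} exceeds the number of samples N={N}")
    C = _init_simplex(rng, (problem.dictionary[0].shape[1], K))
    hard = cfg.model == "dir_clustering"
    cache = problem.make_cache(C)
    if hard:
        S_list = [_assign_hard_view(problem, v, cache)
                  for v in range(len(problem.keys))]
    else:
        # one exponential draw shared by all views: updates are per-view
        # anyway, and identical views then follow identical paths
        S0 = _init_simplex(rng, (K, N))
        S_list = [S0.copy() for _ in problem.keys]
    mu_C = cfg.init_step
    mu_S = [np.full(N, cfg.init_step) for _ in problem.keys]

    loss = _total_loss(problem, S_list, cache)
    trace = [loss]

    # S first, then alternate C/S per iteration
    if not hard:
        for v in range(len(S_list)):
            S_list[v], mu_S[v], _ = _update_S_view(problem, v, S_list[v], mu_S[v], cache)
        loss = _total_loss(problem, S_list, cache)
        trace.append(loss)

    calm = 0
    for _ in range(cfg.max_iter):
        C, mu_C, loss, cache = _update_C(problem, C, S_list, mu_C, loss, cache, cfg)
        if hard:
            cand_S = [_assign_hard_view(problem, v, cache)
                      for v in range(len(problem.keys))]
            new_loss = _total_loss(problem, cand_S, cache)
            # reassignment minimizes each sample's term given C; accept
            # unless floating-point ties make it fractionally worse
            if new_loss <= loss:
                S_list, loss = cand_S, new_loss
            C, cache, S_list, loss = _revive_empty_clusters(
                problem, C, cache, S_list, loss, rng)
        else:
            for v in range(len(S_list)):
                S_list[v], mu_S[v], _ = _update_S_view(
                    problem, v, S_list[v], mu_S[v], cache)
            loss = _total_loss(problem, S_list, cache)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss encountered: {loss}")
        if log.isEnabledFor(logging.DEBUG):
            log.debug("iter %d: loss=%.10g mu_C=%.3g mu_S_mean=%.3g",
                      len(trace), loss, mu_C,
                      float(np.mean([m.mean() for m in mu_S])))
        prev = trace[-1]
        trace.append(loss)
        converged = abs(prev - loss) <= cfg.rel_tol * abs(prev)
        if converged:
            calm += 1
            if calm >= _PATIENCE:
                break
        else:
            calm = 0
    return C, S_list, np.asarray(trace)


def _revive_empty_clusters(problem, C, cache, S_list, loss, rng):
    """Redraw generator columns of archetypes with zero total occupation
    (exponential init); keep the redraw only if the reassigned loss
    improves, so the trace stays non-increasing."""
    occupation = np.zeros(C.shape[1])
    for S in S_list:
        occupation += S.sum(axis=1)
    empty = np.flatnonzero(occupation == 0)
    if empty.size == 0:
        return C, cache, S_list, loss
    log.debug("reinitializing empty cluster(s) %s", empty.tolist())
    cand = C.copy()
    for k in empty:
        col = rng.exponential(size=C.shape[0])
        cand[:, k] = col / col.sum()
    cand_cache = problem.make_cache(cand)
    cand_S = [_assign_hard_view(problem, v, cand_cache)
              for v in range(len(problem.keys))]
    cand_loss = _total_loss(problem, cand_S, cand_cache)
    if cand_loss < loss:
        return cand, cand_cache, cand_S, cand_loss
    return C, cache, S_list, loss


def _make_problem(data: MultiViewData, model: str):
    if model == "euclidean_aa":
        return LeastSquaresProblem(data)
    return WatsonProblem(data)


def _finalize(problem, data, cfg, C, S_list, trace, seed, slices=None) -> DAAModel:
    arche = {k: problem.dictionary[v] @ C for v, k in enumerate(problem.keys)}
    S = {k: S_list[v] for v, k in enumerate(problem.keys)}
    return DAAModel(model_type=cfg.model, C=C, S=S, archetypes=arche,
                    loss_trace=trace, config=cfg, seed=seed,
                    condition_slices=slices)


def fit_daa(data: MultiViewData, config: FitConfig,
            rng: np.random.Generator | None = None) -> DAAModel:
    """One model fit from a single random initialization (any of the three
    model types), with a shared generator C across all views in ``data``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    problem = _make_problem(data, config.model)
    C, S_list, trace = _fit_single(problem, config, rng)
    return _finalize(problem, data, config, C, S_list, trace, config.seed)


def _concat_conditions(data: MultiViewData):
    """Concatenate condition views in time per (modality, subject); the
    generator C then spans all conditions' samples.  Returns the merged
    data and the per-condition sample slices."""
    groups: dict[tuple[str, str], list[ViewKey]] = {}
    for k in data.keys:
        groups.setdefault((k.modality, k.subject), []).append(k)
    conditions = sorted({k.condition for k in data.keys})
    N = data.n_samples
    slices = {c: slice(i * N, (i + 1) * N) for i, c in enumerate(conditions)}
    merged = MultiViewData(views={})
    for (m, b), keys in sorted(groups.items()):
        keys = sorted(keys, key=lambda k: conditions.index(k.condition))
        mk = ViewKey(m, b)
        merged.views[mk] = np.concatenate([data.views[k] for k in keys], axis=1)
        merged.x_tilde[mk] = np.concatenate([data.x_tilde[k] for k in keys], axis=1)
        merged.x_tilde_flipped[mk] = np.concatenate(
            [data.x_tilde_flipped[k] for k in keys], axis=1)
        merged.kappa[mk] = np.concatenate([data.kappa[k] for k in keys])
        merged.frob_scale[mk] = 1.0
    return merged, slices


def fit_with_restarts(data: MultiViewData, config: FitConfig
                      ) -> tuple[DAAModel, list[DAAModel]]:
    """Best-of-``n_restarts`` fit, repeated ``n_outer`` times.

    Returns the overall best model and the list of per-outer-run best
    models (for the cyclic NMI consistency protocol).  The seed stream is
    spawned hierarchically so that increasing ``n_restarts`` extends, not
    perturbs, the stream.
    """
    cfg = config
    if cfg.sharing_mode == "concat_conditions":
        work, slices = _concat_conditions(data)
    else:
        work, slices = data, None

    master = np.random.SeedSequence(cfg.seed)
    outer_seeds = master.spawn(cfg.n_outer)
    outer_models: list[DAAModel] = []
    for outer_ss in outer_seeds:
        restart_seeds = outer_ss.spawn(cfg.n_restarts)
        best: DAAModel | None = None
        for r_ss in restart_seeds:
            rng = np.random.default_rng(r_ss)
            if cfg.sharing_mode == "no_correspondence":
                model = _fit_no_correspondence(work, cfg, rng)
            else:
                problem = _make_problem(work, cfg.model)
                C, S_list, trace = _fit_single(problem, cfg, rng)
                model = _finalize(problem, work, cfg, C, S_list, trace,
                                  cfg.seed, slices)
            if best is None or model.loss < best.loss:
                best = model
        outer_models.append(best)
    overall = min(outer_models, key=lambda m: m.loss)
    return overall, outer_models


def _fit_no_correspondence(data: MultiViewData, cfg: FitConfig,
                           rng: np.random.Generator) -> DAAModel:
    """Independent (C, S) per view; losses summed into one trace."""
    C_per_view: dict[ViewKey, np.ndarray] = {}
    S: dict[ViewKey, np.ndarray] = {}
    arche: dict[ViewKey, np.ndarray] = {}
    traces = []
    for k in data.keys:
        sub = MultiViewData(
            views={k: data.views[k]},
            x_tilde={k: data.x_tilde[k]},
            x_tilde_flipped={k: data.x_tilde_flipped[k]},
            kappa={k: data.kappa[k]},
            frob_scale={k: data.frob_scale[k]},
        )
        problem = _make_problem(sub, cfg.model)
        C, S_list, trace = _fit_single(problem, cfg, rng)
        C_per_view[k] = C
        S[k] = S_list[0]
        arche[k] = problem.dictionary[0] @ C
        traces.append(trace)
    L = max(len(t) for t in traces)
    total = np.zeros(L)
    for t in traces:  # pad each converged trace with its final value
        total += np.concatenate([t, np.full(L - len(t), t[-1])])
    return DAAModel(model_type=cfg.model, C=C_per_view, S=S, archetypes=arche,
                    loss_trace=total, config=cfg, seed=cfg.seed)
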