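"""Reproducible experiment protocols: model-order (knee) sweeps on the
synthetic families, the multiview timing-consistency experiment, and the
full evaluation sweep backing the command-line interface.

Problem sizes default to desk scale (n = 1000 samples, 20 restarts,
5 replicate seeds), with the optimizer capped at 500 alternating
iterations at a 1e-7 relative tolerance — ample for these
three-dimensional problems, whose loss curves flatten within a few
hundred iterations.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from .datamodel import MultiViewData, ViewKey
from .evaluation import (
    EvaluationReport,
    archetype_recovery,
    consistency_protocol,
    knee_of_loss_curve,
    nmi,
)
from .model import FitConfig, fit_with_restarts
from .synthetic import SyntheticSpec, as_multiview, simulate

__all__ = [
    "replicate_seeds",
    "knee_experiment",
    "multiview_timing_experiment",
    "run_sweep",
]

DESK_MAX_ITER = 500
DESK_REL_TOL = 1e-7


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit dataset seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _fit_best(data: MultiViewData, model: str, K: int, n_restarts: int,
              seed: int, n_outer: int = 1, max_iter: int = DESK_MAX_ITER,
              rel_tol: float = DESK_REL_TOL):
    cfg = FitConfig(n_archetypes=K, model=model, n_restarts=n_restarts,
                    n_outer=n_outer, max_iter=max_iter, rel_tol=rel_tol,
                    seed=seed)
    return fit_with_restarts(data, cfg)


def knee_experiment(
    family: str,
    model: str,
    k_range: range,
    n_samples: int = 1000,
    noise_sd: float = 0.05,
    alpha: float = 1.0,
    n_restarts: int = 20,
    n_seeds: int = 5,
    master_seed: int = 0,
    max_iter: int = DESK_MAX_ITER,
    rel_tol: float = DESK_REL_TOL,
) -> dict:
    """Best-of-restarts loss curve over K for replicate synthetic datasets,
    with the drop-ratio knee per replicate and the majority knee.

    Ties in the majority vote resolve to the smallest K.
    """
    seeds = replicate_seeds(master_seed, n_seeds)
    curves: list[dict[int, float]] = []
    knees: list[int] = []
    for s in seeds:
        spec = SyntheticSpec(family=family, n_samples=n_samples,
                             alpha=alpha, noise_sd=noise_sd, seed=s)
        X, _ = simulate(spec)
        data = as_multiview(X, modality=family)
        losses = {}
        for K in k_range:
            best, _ = _fit_best(data, model, K, n_restarts, seed=s,
                                max_iter=max_iter, rel_tol=rel_tol)
            losses[K] = best.loss
        curves.append(losses)
        knees.append(knee_of_loss_curve(losses))
    counts = Counter(knees)
    top = max(counts.values())
    majority = min(k for k, c in counts.items() if c == top)
    return {"seeds": seeds, "curves": curves, "knees": knees,
            "majority_knee": majority}


def multiview_timing_experiment(
    n_samples: int = 200,
    k_true: int = 4,
    n_modalities: int = 2,
    n_subjects: int = 3,
    noise_sd: float = 0.05,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = DESK_MAX_ITER,
) -> dict:
    """Fit the shared-generator model to multiview ERP-like data and
    measure cross-modality agreement of the per-view mixing matrices.

    Because all views share response timing, the fitted S of modality 1 and
    modality 2 for the same subject should agree far better than a
    time-scrambled baseline computed from the same fits.
    """
    spec = SyntheticSpec(family="multiview_erp", n_samples=n_samples,
                         k_true=k_true, n_modalities=n_modalities,
                         n_subjects=n_subjects, noise_sd=noise_sd, seed=seed)
    views, gt = simulate(spec)
    data = MultiViewData.from_raw(views)
    best, _ = _fit_best(data, "daa", k_true, n_restarts, seed=seed,
                        max_iter=max_iter)
    rng = np.random.default_rng(seed)
    cross, scrambled = [], []
    for b in range(n_subjects):
        k1 = ViewKey("mod1", f"sub{b+1}")
        k2 = ViewKey("mod2", f"sub{b+1}")
        S1, S2 = best.S[k1], best.S[k2]
        cross.append(nmi(S1, S2))
        perm = rng.permutation(S2.shape[1])
        scrambled.append(nmi(S1, S2[:, perm]))
    return {
        "model": best,
        "ground_truth": gt,
        "cross_modality_nmi": float(np.mean(cross)),
        "scrambled_baseline_nmi": float(np.mean(scrambled)),
    }


def run_sweep(
    data: MultiViewData,
    k_range: range,
    models: tuple[str, ...] = ("daa", "dir_clustering", "euclidean_aa"),
    n_restarts: int = 20,
    n_outer: int = 3,
    seed: int = 0,
    max_iter: int = DESK_MAX_ITER,
    rel_tol: float = DESK_REL_TOL,
    sharing_mode: str = "per_condition_S",
    A_true: np.ndarray | None = None,
) -> EvaluationReport:
    """K-by-model evaluation sweep: per-K best losses with SEM over outer
    runs, cyclic-NMI consistency, knee per model, and archetype recovery
    when the true archetypes are supplied."""
    report = EvaluationReport()
    for model in models:
        report.losses[model] = {}
        report.mean_loss[model] = {}
        report.sem_loss[model] = {}
        report.nmi[model] = {}
        report.recovery[model] = {}
        for K in k_range:
            cfg = FitConfig(n_archetypes=K, model=model, n_restarts=n_restarts,
                            n_outer=n_outer, max_iter=max_iter,
                            rel_tol=rel_tol, seed=seed,
                            sharing_mode=sharing_mode)
            best, outer = fit_with_restarts(data, cfg)
            outer_losses = [m.loss for m in outer]
            report.losses[model][K] = outer_losses
            report.mean_loss[model][K] = float(np.mean(outer_losses))
            report.sem_loss[model][K] = float(
                np.std(outer_losses, ddof=1) / np.sqrt(len(outer_losses))
            ) if len(outer_losses) > 1 else 0.0
            if len(outer) >= 2:
                report.nmi[model][K] = consistency_protocol(outer)["mean_nmi"]
            if A_true is not None and K >= A_true.shape[1] \
                    and not isinstance(best.C, dict):
                A_fit = next(iter(best.archetypes.values()))
                score, _ = archetype_recovery(A_fit, A_true)
                report.recovery[model][K] = score
        best_per_k = {K: min(report.losses[model][K]) for K in k_range}
        if len(best_per_k) >= 4:
            report.knee[model] = knee_of_loss_curve(best_per_k)
    return report
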