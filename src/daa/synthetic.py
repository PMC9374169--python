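"""Synthetic ground-truth generators for recovery and model-order studies.

Four three-dimensional families probe the geometry the directional model
does (and does not) handle:

* ``octant`` — sphere-projected convex combinations of the coordinate axes
  e1, e2, e3; data occupy one octant of S^2.
* ``antipodal`` — octant samples with independent random sign flips, so the
  data occupy two opposing octants (polarity-invariant archetypes).
* ``simplex`` — the same convex combinations left on the flat triangle
  (no sphere projection); norms vary with position.
* ``with_origin`` — archetypes e1, e2 and the origin; samples near the
  degenerate archetype have vanishing norm, the documented failure mode of
  sphere-projecting models.

A fifth, ``multiview_erp``, emulates the structure of multi-modality
event-related-potential data: several views (modality x subject) share the
timing of archetype activation (a common sparse generator and mixing
trajectory) while each view has its own topographic archetype maps,
amplitude envelope with a quiet pre-stimulus segment, and random per-sample
polarity flips.

Samples are drawn as Dirichlet(alpha) convex weights over the true
archetypes plus optional isotropic Gaussian noise; spherical families are
then projected back to the unit sphere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import MultiViewData, ViewKey, write_dataset

__all__ = [
    "SyntheticSpec",
    "simulate_octant",
    "simulate_antipodal",
    "simulate_simplex",
    "simulate_with_origin",
    "simulate_multiview_erp",
    "simulate",
    "write_synthetic_dataset",
]

FAMILIES = ("octant", "antipodal", "simplex", "with_origin", "multiview_erp")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic draw.

    ``alpha`` is the symmetric Dirichlet concentration of the convex mixing
    weights; ``noise_sd`` the standard deviation of the additive isotropic
    Gaussian perturbation (applied before sphere projection for the
    spherical families).
    """

    family: str = "octant"
    n_samples: int = 1000
    alpha: float = 1.0
    noise_sd: float = 0.05
    seed: int | None = None
    # multiview_erp only:
    n_modalities: int = 2
    n_subjects: int = 3
    n_conditions: int = 1
    n_channels: tuple[int, ...] = (8, 12)
    k_true: int = 4
    windows: tuple[tuple[int, int], ...] | None = None
    prestim_fraction: float = 0.2
    prestim_amplitude: float = 0.15
    subject_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


_CORNERS = np.eye(3)


def _dirichlet_weights(rng, n, k, alpha):
    return rng.dirichlet(np.full(k, alpha), size=n)  # n x k


def _octant_draw(rng: np.random.Generator, spec: SyntheticSpec):
    W = _dirichlet_weights(rng, spec.n_samples, 3, spec.alpha)
    X = _CORNERS @ W.T
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng.standard_normal(X.shape)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise RuntimeError("degenerate zero-norm sample in octant draw")
    return X / norms, W


def simulate_octant(spec: SyntheticSpec):
    """One-octant spherical data.  Returns ``(X, ground_truth)`` with X of
    shape 3 x n and ground truth holding the true archetypes and weights."""
    rng = np.random.default_rng(spec.seed)
    X, W = _octant_draw(rng, spec)
    gt = {"family": "octant", "archetypes": _CORNERS.copy(), "weights": W}
    return X, gt


def simulate_antipodal(spec: SyntheticSpec):
    """Two opposing octants: octant samples times independent Rademacher
    signs.  The sign stream is separate from the octant stream, so
    multiplying each sample by its stored sign reproduces the octant draw
    for the same seed exactly."""
    rng = np.random.default_rng(spec.seed)
    X, W = _octant_draw(rng, spec)
    sign_rng = np.random.default_rng(np.random.SeedSequence([0x5167, spec.seed or 0]))
    signs = sign_rng.choice([-1.0, 1.0], size=spec.n_samples)
    gt = {"family": "antipodal", "archetypes": _CORNERS.copy(), "weights": W,
          "signs": signs}
    return X * signs, gt


def simulate_simplex(spec: SyntheticSpec):
    """Flat-simplex data: convex combinations of the corners without sphere
    projection; noise-free samples have coordinates summing to 1."""
    rng = np.random.default_rng(spec.seed)
    W = _dirichlet_weights(rng, spec.n_samples, 3, spec.alpha)
    X = _CORNERS @ W.T
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng.standard_normal(X.shape)
    gt = {"family": "simplex", "archetypes": _CORNERS.copy(), "weights": W}
    return X, gt


def simulate_with_origin(spec: SyntheticSpec):
    """Archetypes e1, e2 and the origin; no projection.  Samples approach
    zero norm as the weight on the degenerate archetype approaches 1."""
    rng = np.random.default_rng(spec.seed)
    A = np.column_stack([_CORNERS[:, 0], _CORNERS[:, 1], np.zeros(3)])
    W = _dirichlet_weights(rng, spec.n_samples, 3, spec.alpha)
    X = A @ W.T
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng.standard_normal(X.shape)
    gt = {"family": "with_origin", "archetypes": A, "weights": W,
          "degenerate_archetype": 2}
    return X, gt


def _default_windows(n_samples: int, k: int, prestim: int):
    """Evenly spaced contiguous non-overlapping generator windows in the
    post-stimulus segment."""
    span = n_samples - prestim
    width = max(2, span // (2 * k))
    starts = prestim + np.linspace(0, span - width, k).astype(int)
    return tuple((int(s), int(s + width)) for s in starts)


def simulate_multiview_erp(spec: SyntheticSpec):
    """Multi-view data with shared response timing.

    All views share a sparse generator ``C_true`` (each archetype generated
    by a contiguous post-stimulus window) and a smooth simplex trajectory
    ``S_true``; per-view topographic maps are unit-norm random vectors with
    per-subject perturbations.  An amplitude envelope keeps the
    pre-stimulus segment low, and each sample's polarity is flipped at
    random per view.  Returns ``(raw_views, ground_truth)`` where
    ``raw_views`` maps :class:`ViewKey` to a channels x samples matrix.
    """
    rng = np.random.default_rng(spec.seed)
    N, K = spec.n_samples, spec.k_true
    prestim = int(round(spec.prestim_fraction * N))
    windows = spec.windows or _default_windows(N, K, prestim)
    if len(windows) != K:
        raise ValueError(f"need {K} generator windows, got {len(windows)}")
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping generator windows {(a0, a1)} and {(b0, b1)}")

    # shared sparse generator: uniform over each window
    C_true = np.zeros((N, K))
    for k, (lo, hi) in enumerate(windows):
        C_true[lo:hi, k] = 1.0 / (hi - lo)

    # shared mixing trajectory: Gaussian bumps at window centers on a
    # small uniform floor, columns normalized to the simplex
    t = np.arange(N)
    centers = np.array([(lo + hi) / 2 for lo, hi in windows])
    width = max(4.0, (N - prestim) / (3.0 * K))
    R = np.exp(-0.5 * ((t[None, :] - centers[:, None]) / width) ** 2)
    R += 0.02
    R[:, :prestim] = 1.0 / K  # no structure before the stimulus
    S_true = R / R.sum(axis=0)

    envelope = np.full(N, 1.0)
    envelope[:prestim] = spec.prestim_amplitude

    if len(spec.n_channels) != spec.n_modalities:
        raise ValueError("n_channels must list one channel count per modality")

    base_maps = []
    for D in spec.n_channels:
        G = rng.standard_normal((D, K))
        base_maps.append(G / np.linalg.norm(G, axis=0))

    views: dict[ViewKey, np.ndarray] = {}
    maps: dict[str, np.ndarray] = {}
    flips: dict[str, np.ndarray] = {}
    conditions = [f"c{c+1}" for c in range(spec.n_conditions)] \
        if spec.n_conditions > 1 else [None]
    for m in range(spec.n_modalities):
        for b in range(spec.n_subjects):
            A = base_maps[m] + spec.subject_sd * rng.standard_normal(base_maps[m].shape)
            A /= np.linalg.norm(A, axis=0)
            for c in conditions:
                key = ViewKey(f"mod{m+1}", f"sub{b+1}", c)
                signs = rng.choice([-1.0, 1.0], size=N)
                X = (A @ S_true) * envelope * signs
                if spec.noise_sd > 0:
                    X = X + spec.noise_sd * rng.standard_normal(X.shape)
                views[key] = X
                maps[key.label()] = A
                flips[key.label()] = signs
    gt = {"family": "multiview_erp", "C_true": C_true, "S_true": S_true,
          "windows": tuple(windows), "envelope": envelope, "maps": maps,
          "signs": flips, "prestim": prestim}
    return views, gt


def simulate(spec: SyntheticSpec):
    """Dispatch on ``spec.family``."""
    fn = {
        "octant": simulate_octant,
        "antipodal": simulate_antipodal,
        "simplex": simulate_simplex,
        "with_origin": simulate_with_origin,
        "multiview_erp": simulate_multiview_erp,
    }[spec.family]
    return fn(spec)


def as_multiview(X_or_views, modality: str = "sim", subject: str = "s1") -> MultiViewData:
    """Wrap a single matrix (or a view dict) as preprocessed MultiViewData."""
    if isinstance(X_or_views, dict):
        return MultiViewData.from_raw(X_or_views)
    return MultiViewData.from_raw({ViewKey(modality, subject): X_or_views})


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_synthetic_dataset(out_dir: str | Path, spec: SyntheticSpec) -> Path:
    """Generate one dataset and write manifest + matrices + a ground-truth
    JSON sidecar.  Deterministic given the spec (including seed)."""
    out_dir = Path(out_dir)
    result, gt = simulate(spec)
    if isinstance(result, dict):
        views = result
    else:
        views = {ViewKey(spec.family, "s1"): result}
    meta = {"family": spec.family, "seed": spec.seed, "n_samples": spec.n_samples,
            "alpha": spec.alpha, "noise_sd": spec.noise_sd}
    manifest_path = write_dataset(out_dir, views, metadata=meta)
    sidecar = dict(_jsonify(gt))
    sidecar["spec"] = _jsonify(dataclasses.asdict(spec))
    with open(out_dir / "ground_truth.json", "w") as f:
        json.dump(sidecar, f, sort_keys=True)
    return manifest_path
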