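"""Multiview data container and deterministic preprocessing transforms.

Multichannel time series (EEG/MEG topographic samples) are held as one
matrix per *view*, where a view is a (modality, subject[, condition])
combination.  Three transforms prepare a view for directional modeling:

1. Frobenius scaling equalizes the influence of each view on a shared loss.
2. Sphere normalization projects every sample (column) to the unit
   hypersphere, storing its squared norm as a per-sample precision ``kappa``.
3. Hemisphere flipping resolves the antipodal (polarity) ambiguity by
   negating samples whose projection onto the dominant principal direction
   is negative, so archetypes are built from a single closed half-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ViewKey",
    "MultiViewData",
    "frobenius_scale",
    "normalize_to_sphere",
    "hemisphere_flip",
    "principal_direction",
    "load_dataset",
    "write_dataset",
]


@dataclass(frozen=True, order=True)
class ViewKey:
    """Identifies one view: a modality/subject pair, optionally a condition."""

    modality: str
    subject: str
    condition: str | None = None

    def label(self) -> str:
        parts = [self.modality, self.subject]
        if self.condition is not None:
            parts.append(self.condition)
        return "|".join(parts)

    @classmethod
    def from_label(cls, label: str) -> "ViewKey":
        parts = label.split("|")
        if len(parts) == 2:
            return cls(parts[0], parts[1])
        if len(parts) == 3:
            return cls(parts[0], parts[1], parts[2])
        raise ValueError(f"cannot parse view label {label!r}")


def frobenius_scale(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a view matrix to unit Frobenius norm.

    Returns ``(X / ||X||_F, ||X||_F)``.  An all-zero matrix is an error.
    """
    X = np.asarray(X, dtype=float)
    scale = float(np.linalg.norm(X))
    if scale == 0.0:
        raise ValueError("cannot Frobenius-scale an all-zero view matrix")
    return X / scale, scale


def normalize_to_sphere(
    X: np.ndarray, view: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project every column of ``X`` to the unit sphere.

    Returns ``(X_tilde, kappa)`` with ``X_tilde[:, n] = x_n / ||x_n||`` and
    ``kappa[n] = ||x_n||^2``, so that ``X = X_tilde @ diag(sqrt(kappa))``.
    Columns with zero norm cannot be projected and raise a ``ValueError``
    naming the view and the offending sample index.
    """
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=0)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        where = f" in view {view}" if view else ""
        raise ValueError(
            f"zero-norm column(s) at sample index {zero.tolist()}{where}: "
            "cannot project to the sphere"
        )
    return X / norms, norms**2


def principal_direction(X_tilde: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of ``X_tilde @ X_tilde.T`` with a fixed sign.

    The sign is chosen so that the largest-magnitude entry of the vector is
    positive, making downstream flipping deterministic.
    """
    M = X_tilde @ X_tilde.T
    w, V = np.linalg.eigh(M)
    u = V[:, -1]
    if u[int(np.argmax(np.abs(u)))] < 0:
        u = -u
    return u


def hemisphere_flip(X_tilde: np.ndarray) -> np.ndarray:
    """Negate columns whose projection on the principal direction is negative.

    Samples exactly orthogonal to the principal direction are left as-is.
    The flipped cloud lies in the closed half-space ``{x : u.T x >= 0}``.
    """
    u = principal_direction(X_tilde)
    proj = u @ X_tilde
    signs = np.where(proj < 0, -1.0, 1.0)
    return X_tilde * signs


@dataclass
class MultiViewData:
    """Per-view raw matrices plus the derived directional representations.

    ``views`` holds the Frobenius-scaled raw matrices X (channels x samples);
    ``x_tilde`` the unit-column-norm projections; ``x_tilde_flipped`` the
    hemisphere-consistent versions used to construct archetypes; ``kappa``
    the per-sample precisions (squared norms of the scaled X columns); and
    ``frob_scale`` the per-view Frobenius norms of the original input.
    """

    views: dict[ViewKey, np.ndarray]
    x_tilde: dict[ViewKey, np.ndarray] = field(default_factory=dict)
    x_tilde_flipped: dict[ViewKey, np.ndarray] = field(default_factory=dict)
    kappa: dict[ViewKey, np.ndarray] = field(default_factory=dict)
    frob_scale: dict[ViewKey, float] = field(default_factory=dict)

    @classmethod
    def from_raw(cls, raw_views: Mapping[ViewKey, np.ndarray]) -> "MultiViewData":
        """Apply Frobenius scaling, sphere normalization and hemisphere
        flipping to each raw view, in that order."""
        if not raw_views:
            raise ValueError("at least one view is required")
        n_samples = {k: np.asarray(v).shape[1] for k, v in raw_views.items()}
        if len(set(n_samples.values())) > 1:
            bad = ", ".join(f"{k.label()}: N={n}" for k, n in sorted(n_samples.items()))
            raise ValueError(f"views disagree on the number of samples ({bad})")
        data = cls(views={})
        for key in sorted(raw_views):
            X_scaled, scale = frobenius_scale(raw_views[key])
            X_tilde, kappa = normalize_to_sphere(X_scaled, view=key.label())
            data.views[key] = X_scaled
            data.x_tilde[key] = X_tilde
            data.x_tilde_flipped[key] = hemisphere_flip(X_tilde)
            data.kappa[key] = kappa
            data.frob_scale[key] = scale
        return data

    @property
    def n_samples(self) -> int:
        return next(iter(self.views.values())).shape[1]

    @property
    def keys(self) -> list[ViewKey]:
        return sorted(self.views)

    def n_channels(self, key: ViewKey) -> int:
        return self.views[key].shape[0]


# ---------------------------------------------------------------------------
# Manifest I/O
#
# A dataset on disk is a small YAML manifest listing one entry per view plus
# the matrix files themselves, either delimited text (rows = channels,
# columns = samples) or an HDF5 file with a dataset named "X".


def _read_matrix(path: Path, delimiter: str | None) -> np.ndarray:
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            return np.asarray(f["X"][()], dtype=float)
    try:
        M = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric or malformed content in {path}: {exc}") from exc
    return M


def load_dataset(manifest_path: str | Path) -> MultiViewData:
    """Load a manifest and return fully preprocessed :class:`MultiViewData`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as f:
        manifest = yaml.safe_load(f)
    entries = manifest.get("entries")
    if not entries:
        raise ValueError(f"manifest {manifest_path} lists no entries")
    raw: dict[ViewKey, np.ndarray] = {}
    for e in entries:
        key = ViewKey(str(e["modality"]), str(e["subject"]),
                      str(e["condition"]) if e.get("condition") is not None else None)
        path = manifest_path.parent / e["path"]
        if not path.exists():
            raise FileNotFoundError(f"matrix file {path} referenced by manifest is missing")
        raw[key] = _read_matrix(path, e.get("delimiter"))
    return MultiViewData.from_raw(raw)


def write_dataset(
    out_dir: str | Path,
    raw_views: Mapping[ViewKey, np.ndarray],
    metadata: Mapping | None = None,
) -> Path:
    """Write raw view matrices as TSV files plus a YAML manifest.

    Returns the manifest path.  Files are written with full float precision
    so a round trip through :func:`load_dataset` is exact, and regeneration
    with the same inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for key in sorted(raw_views):
        fname = key.label().replace("|", "_") + ".tsv"
        np.savetxt(out_dir / fname, np.asarray(raw_views[key], dtype=float),
                   delimiter="\t", fmt="%.17g")
        entry = {"modality": key.modality, "subject": key.subject,
                 "path": fname, "delimiter": "\t"}
        if key.condition is not None:
            entry["condition"] = key.condition
        entries.append(entry)
    manifest = dict(metadata or {})
    manifest["entries"] = entries
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)
    return manifest_path
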