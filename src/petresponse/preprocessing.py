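"""Class rebalancing (SMOTE) and dimensionality reduction (PCA).

SMOTE synthesizes minority samples on the segment between a minority sample
and one of its k nearest minority-class neighbors; by default 6 synthetic
samples are generated for each of the 2 rarest classes.  PCA retains the
top principal components of the (optionally standardized) centered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError


def class_order(y) -> list:
    """Canonical class enumeration order: first appearance in ``y``."""
    return list(dict.fromkeys(y))


@dataclass
class SmoteConfig:
    n_synthetic_per_class: int = 6
    n_classes_to_oversample: int = 2
    k_neighbors: int = 5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_synthetic_per_class < 0:
            raise ConfigurationError("n_synthetic_per_class must be >= 0")
        if self.n_classes_to_oversample < 0:
            raise ConfigurationError("n_classes_to_oversample must be >= 0")
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")


def smote(
    X: np.ndarray,
    y: np.ndarray,
    config: SmoteConfig | None = None,
    singleton_policy: str = "error",
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the rarest classes with synthetic interpolated samples.

    The ``config.n_classes_to_oversample`` rarest classes (ties broken by
    class enumeration order) each receive ``n_synthetic_per_class``
    synthetic samples.  Each synthetic sample is
    ``x_i + g * (x_j - x_i)`` with ``x_j`` one of the ``k`` nearest
    minority-class neighbors of ``x_i`` (Euclidean) and ``g ~ U[0, 1]``;
    ``k`` is clamped to the minority size minus one, with a warning.

    Original rows are returned unchanged, in order, followed by the
    synthetic rows.  Interpolation needs at least two samples of a class;
    ``singleton_policy`` decides what happens below that: ``"error"``
    (default) raises with advice to lower k or skip, ``"skip"`` leaves the
    class untouched with a warning, ``"duplicate"`` copies the lone sample
    verbatim.  The leave-one-out driver uses ``"skip"``: a fold may hold
    only one sample of the rarest class, and a 7-fold point mass would
    visibly distort any PCA fit downstream.
    """
    if singleton_policy not in ("error", "skip", "duplicate"):
        raise ConfigurationError(f"unknown singleton_policy {singleton_policy!r}")
    config = config or SmoteConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.shape[0] != y.shape[0]:
        raise DataError("X and y row counts differ")
    if config.n_synthetic_per_class == 0 or config.n_classes_to_oversample == 0:
        return X.copy(), y.copy()

    order = class_order(y)
    counts = {c: int((y == c).sum()) for c in order}
    rarest = sorted(order, key=lambda c: (counts[c], order.index(c)))
    targets = rarest[: config.n_classes_to_oversample]

    rng = np.random.default_rng(config.rng_seed)
    new_rows, new_labels = [], []
    for cls in targets:
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            if singleton_policy == "error":
                raise DataError(
                    f"class {cls!r} has {idx.size} sample(s); SMOTE needs >= 2 "
                    "(lower k_neighbors or skip this class)"
                )
            if singleton_policy == "skip":
                warnings.warn(f"class {cls!r} has {idx.size} sample(s); left untouched")
                continue
            for _ in range(config.n_synthetic_per_class):
                new_rows.append(X[idx[0]].copy())
                new_labels.append(cls)
            continue
        k = min(config.k_neighbors, idx.size - 1)
        if k < config.k_neighbors:
            warnings.warn(
                f"class {cls!r}: k_neighbors clamped from {config.k_neighbors} to {k}"
            )
        Xc = X[idx]
        d2 = ((Xc[:, None, :] - Xc[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        neighbor_lists = np.argsort(d2, axis=1, kind="stable")[:, :k]
        for _ in range(config.n_synthetic_per_class):
            i = int(rng.integers(idx.size))
            j = int(neighbor_lists[i, int(rng.integers(k))])
            g = float(rng.uniform())
            new_rows.append(Xc[i] + g * (Xc[j] - Xc[i]))
            new_labels.append(cls)

    X_out = np.vstack([X, np.array(new_rows)]) if new_rows else X.copy()
    y_out = np.concatenate([y, np.array(new_labels, dtype=object)]) if new_labels else y.copy()
    return X_out, y_out


@dataclass
class PcaModel:
    """Fitted principal-component model (orthonormal rows of ``components``)."""

    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray  # per retained component
    mean: np.ndarray
    scale: np.ndarray | None = None  # feature SDs when standardized

    def to_dict(self) -> dict:
        return {
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "mean": self.mean.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(
            components=np.asarray(d["components"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            mean=np.asarray(d["mean"], dtype=float),
            scale=None if d.get("scale") is None else np.asarray(d["scale"], dtype=float),
        )


def pca_fit(X: np.ndarray, n_components: int = 2, standardize: bool = False) -> PcaModel:
    """Fit PCA by SVD of the centered (optionally z-scored) data matrix.

    Explained-variance fractions are reported relative to the total
    variance; signs are fixed so each component's largest-magnitude entry
    is positive (determinism).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("pca_fit requires a 2-D matrix with >= 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if standardize:
        scale = Xc.std(axis=0)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        raise ConfigurationError(
            f"requested {n_components} components but data rank is {rank}"
        )
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    components = vt[:n_components].copy()
    for row in components:  # deterministic sign convention
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaModel(
        components=components,
        explained_variance_ratio=var[:n_components] / total if total > 0 else var[:n_components],
        mean=mean,
        scale=scale,
    )


def pca_transform(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` onto the retained components."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.mean.shape[0]:
        raise DataError(
            f"feature dimension {X.shape[-1]} does not match fitted model "
            f"({model.mean.shape[0]})"
        )
    Xc = X - model.mean
    if model.scale is not None:
        Xc = Xc / model.scale
    return Xc @ model.components.T
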