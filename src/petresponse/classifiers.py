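"""The six classifier families and their hyperparameter grids.

Families: kNN (baseline), one- and two-hidden-layer MLPs, LVQ (learning
vector quantization, LVQ1 update rule), RBF network (Gaussian units at
every training point, ridge-stabilized linear output solve) and PNN
(Parzen-window kernel-density classifier).

Grids::

    kNN   k in 1..15                          (15 configurations)
    MLP1  hidden size even in [6, 28]         (12)
    MLP2  first layer even in [6, 28],
          second = half the first             (12)
    LVQ   codebook size even in [6, 28]       (12)
    RBF   spread = 2**e, e integer in [-1,15] (17)
    PNN   spread = 2**e, e integer in [-1,15] (17)

Features are z-scored inside ``train`` (statistics from the training fold
only) for every family: the kernel/distance-based families require it, and
it is applied uniformly for simplicity.  Determinism: identical spec, seed
and data produce identical models and predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.neural_network import MLPClassifier

from .errors import ConfigurationError, DataError
from .preprocessing import class_order

FAMILIES = ("kNN", "MLP1", "MLP2", "LVQ", "RBF", "PNN")

EVEN_6_28 = tuple(range(6, 29, 2))
SPREAD_EXPONENTS = tuple(range(-1, 16))


@dataclass
class ClassifierSpec:
    family: str
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown classifier family {self.family!r}")


def grid(family: str) -> list[ClassifierSpec]:
    """The frozen hyperparameter grid of one family."""
    if family == "kNN":
        return [ClassifierSpec("kNN", {"k": k}) for k in range(1, 16)]
    if family == "MLP1":
        return [ClassifierSpec("MLP1", {"hidden": n}) for n in EVEN_6_28]
    if family == "MLP2":
        return [ClassifierSpec("MLP2", {"hidden": n, "hidden2": n // 2}) for n in EVEN_6_28]
    if family == "LVQ":
        return [ClassifierSpec("LVQ", {"codebook_size": n}) for n in EVEN_6_28]
    if family in ("RBF", "PNN"):
        return [ClassifierSpec(family, {"spread": 2.0**e}) for e in SPREAD_EXPONENTS]
    raise ConfigurationError(f"unknown classifier family {family!r}")


# --------------------------------------------------------------------------
# trained model
# --------------------------------------------------------------------------


@dataclass
class TrainedModel:
    family: str
    classes: list
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    state: dict

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.scaler_mean.shape[0]:
            raise DataError(
                f"feature dimension {X.shape[1]} does not match training "
                f"dimension {self.scaler_mean.shape[0]}"
            )
        return (X - self.scaler_mean) / self.scaler_std


def _check_training_data(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise DataError("training data must be a non-empty matrix with matching labels")
    if not np.isfinite(X).all():
        raise DataError("training features must be finite")
    return X, y


def train(spec: ClassifierSpec, X, y) -> TrainedModel:
    """Fit one classifier; see the module docstring for family contracts."""
    X, y = _check_training_data(X, y)
    classes = class_order(y)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Xs = (X - mean) / std
    state: dict = {}
    p = spec.params

    if spec.family == "kNN":
        state = {"X": Xs, "y": y, "k": int(p.get("k", 1))}
        if not 1 <= state["k"] <= X.shape[0]:
            raise ConfigurationError(f"k={state['k']} invalid for {X.shape[0]} training samples")

    elif spec.family in ("MLP1", "MLP2"):
        hidden = int(p.get("hidden", 6))
        layers = (hidden,) if spec.family == "MLP1" else (hidden, int(p.get("hidden2", hidden // 2)))
        net = MLPClassifier(
            hidden_layer_sizes=layers,
            activation="logistic",
            solver="adam",
            alpha=float(p.get("alpha", 1e-4)),
            max_iter=int(p.get("max_iter", 400)),
            tol=float(p.get("tol", 1e-5)),
            random_state=spec.rng_seed,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-convergence on tiny folds is fine
            net.fit(Xs, y.astype(str))
        state = {"net": net}

    elif spec.family == "LVQ":
        state = _train_lvq(Xs, y, classes, spec)

    elif spec.family == "RBF":
        spread = float(p.get("spread", 1.0))
        if spread <= 0:
            raise ConfigurationError("RBF spread must be positive")
        phi = _rbf_design(Xs, Xs, spread)
        targets = np.array([[1.0 if label == c else 0.0 for c in classes] for label in y])
        lam = float(p.get("ridge", 1e-8))
        a = phi.T @ phi + lam * np.eye(phi.shape[1])
        weights = np.linalg.solve(a, phi.T @ targets)
        state = {"centers": Xs, "spread": spread, "weights": weights}

    elif spec.family == "PNN":
        spread = float(p.get("spread", 1.0))
        if spread <= 0:
            raise ConfigurationError("PNN spread must be positive")
        state = {"X": Xs, "y": y, "spread": spread}

    return TrainedModel(
        family=spec.family, classes=classes, scaler_mean=mean, scaler_std=std, state=state
    )


def _train_lvq(Xs: np.ndarray, y: np.ndarray, classes: list, spec: ClassifierSpec) -> dict:
    """LVQ1: frequency-proportional codebook at class means + jitter,
    winner-attract/repel updates with a linearly decaying learning rate."""
    p = spec.params
    size = int(p.get("codebook_size", 8))
    if size < len(classes):
        raise ConfigurationError(
            f"codebook_size={size} smaller than the number of classes ({len(classes)})"
        )
    lr0 = float(p.get("learning_rate", 0.3))
    epochs = int(p.get("epochs", 50))
    rng = np.random.default_rng(spec.rng_seed)

    counts = np.array([(y == c).sum() for c in classes], dtype=float)
    if (counts == 0).any():
        raise DataError("LVQ requires at least one sample of every class")
    alloc = np.maximum(1, np.floor(size * counts / counts.sum()).astype(int))
    while alloc.sum() > size:
        alloc[int(np.argmax(alloc))] -= 1
    while alloc.sum() < size:
        alloc[int(np.argmax(counts / alloc))] += 1

    protos, proto_labels = [], []
    for c, n_protos in zip(classes, alloc):
        class_mean = Xs[y == c].mean(axis=0)
        for _ in range(n_protos):
            protos.append(class_mean + 0.05 * rng.standard_normal(Xs.shape[1]))
            proto_labels.append(c)
    codebook = np.array(protos)
    proto_labels = np.array(proto_labels, dtype=object)

    n = Xs.shape[0]
    total_steps = max(1, epochs * n)
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            lr = lr0 * (1.0 - step / total_steps)
            step += 1
            if lr <= 0:
                break
            d2 = ((codebook - Xs[i]) ** 2).sum(axis=1)
            w = int(np.argmin(d2))
            direction = 1.0 if proto_labels[w] == y[i] else -1.0
            codebook[w] += direction * lr * (Xs[i] - codebook[w])
    return {"codebook": codebook, "proto_labels": proto_labels}


def _rbf_design(X: np.ndarray, centers: np.ndarray, spread: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / spread**2)


def _vote(scores: np.ndarray, classes: list) -> list:
    """Argmax per row with ties broken by class enumeration order."""
    return [classes[int(np.argmax(row))] for row in scores]


def predict(model: TrainedModel, X) -> np.ndarray:
    """Predict one label per row of ``X``."""
    Xs = model._scale(X)
    s = model.state
    classes = model.classes

    if model.family == "kNN":
        d2 = ((Xs[:, None, :] - s["X"][None, :, :]) ** 2).sum(axis=2)
        # stable sort: distance ties broken by smallest training index
        nearest = np.argsort(d2, axis=1, kind="stable")[:, : s["k"]]
        out = []
        for row in nearest:
            votes = np.array([(s["y"][row] == c).sum() for c in classes])
            out.append(classes[int(np.argmax(votes))])
        return np.array(out, dtype=object)

    if model.family in ("MLP1", "MLP2"):
        return np.array(s["net"].predict(Xs), dtype=object)

    if model.family == "LVQ":
        d2 = ((Xs[:, None, :] - s["codebook"][None, :, :]) ** 2).sum(axis=2)
        return np.array([s["proto_labels"][int(np.argmin(row))] for row in d2], dtype=object)

    if model.family == "RBF":
        phi = _rbf_design(Xs, s["centers"], s["spread"])
        return np.array(_vote(phi @ s["weights"], classes), dtype=object)

    if model.family == "PNN":
        # class score = sum of Gaussian kernels / N (density x prior), in
        # log space so tiny spreads do not underflow
        d2 = ((Xs[:, None, :] - s["X"][None, :, :]) ** 2).sum(axis=2)
        log_k = -d2 / (2.0 * s["spread"] ** 2)
        scores = np.column_stack(
            [
                logsumexp(log_k[:, s["y"] == c], axis=1)
                if (s["y"] == c).any()
                else np.full(Xs.shape[0], -np.inf)
                for c in classes
            ]
        )
        return np.array(_vote(scores, classes), dtype=object)

    raise ConfigurationError(f"unknown classifier family {model.family!r}")
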