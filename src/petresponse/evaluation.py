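"""Leave-one-out evaluation and rank-based classifier comparison.

The comparison machinery operates on an accuracy table (classifiers x
classes).  Within each class, classifiers are ranked (rank 1 = best, ties
averaged); the Friedman chi-square is computed from mean ranks over N
classes and converted to its Iman–Davenport F-ratio form, compared against
the F distribution with ``(k-1, (k-1)(N-1))`` degrees of freedom.  The
post-hoc comparison against a baseline uses the Bonferroni–Dunn critical
difference ``CD = q_alpha * sqrt(k(k+1) / (6N))`` with ``q_alpha`` the
normal quantile at ``1 - alpha / (2(k-1))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import ClassifierSpec, grid, predict, train
from .errors import ConfigurationError, DataError
from .preprocessing import PcaModel, SmoteConfig, class_order, pca_fit, pca_transform, smote

VARIANTS = ("original", "smote", "pca", "smote+pca")


@dataclass
class AccuracyTable:
    """Per-class accuracies (rows: classifiers, columns: classes)."""

    values: np.ndarray
    classifiers: list[str]
    classes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k, n = self.values.shape
        if k != len(self.classifiers) or n != len(self.classes):
            raise DataError("accuracy table shape does not match its labels")
        if len(set(self.classifiers)) != k or len(set(self.classes)) != n:
            raise DataError("accuracy table labels must be unique")
        if ((self.values < 0) | (self.values > 1)).any():
            raise DataError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.classifiers, columns=self.classes)


@dataclass
class ComparisonResult:
    rank_table: np.ndarray  # classifiers x classes, tie-averaged ranks
    avg_ranks: np.ndarray  # per classifier
    chi2_friedman: float
    t1: float  # Iman–Davenport F-ratio
    degenerate: bool  # chi2 hit its upper bound N(k-1)
    df: tuple[int, int]
    f_critical: float
    alpha: float
    cd: float
    baseline: str
    significant_vs_baseline: dict[str, bool]
    classifiers: list[str] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classifiers": self.classifiers,
            "classes": self.classes,
            "rank_table": self.rank_table.tolist(),
            "avg_ranks": self.avg_ranks.tolist(),
            "chi2_friedman": self.chi2_friedman,
            "t1": None if self.degenerate else self.t1,
            "degenerate": self.degenerate,
            "df": list(self.df),
            "f_critical": self.f_critical,
            "alpha": self.alpha,
            "cd": self.cd,
            "baseline": self.baseline,
            "significant_vs_baseline": self.significant_vs_baseline,
        }


# --------------------------------------------------------------------------
# rank statistics
# --------------------------------------------------------------------------


def rank_with_ties(scores, higher_is_better: bool = True) -> np.ndarray:
    """Rank scores (best = 1); tied scores share the average spanned rank."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise DataError("cannot rank an empty score list")
    return stats.rankdata(-scores if higher_is_better else scores, method="average")


def friedman_T1(rank_table: np.ndarray) -> tuple[float, float, bool]:
    """Friedman chi-square and its Iman–Davenport F-ratio (T1).

    ``rank_table`` holds one row per problem (class) and one column per
    method (classifier); each row's ranks must sum to ``k(k+1)/2``.
    Returns ``(chi2, t1, degenerate)``; when the chi-square attains its
    upper bound ``N(k-1)`` the F-ratio denominator vanishes and T1 is
    reported as ``+inf`` with ``degenerate=True``.
    """
    r = np.asarray(rank_table, dtype=float)
    if r.ndim != 2 or r.shape[0] < 1 or r.shape[1] < 2:
        raise DataError("rank table must be N problems x k>=2 methods")
    n, k = r.shape
    expected = k * (k + 1) / 2.0
    if not np.allclose(r.sum(axis=1), expected):
        raise DataError(f"each row of the rank table must sum to k(k+1)/2 = {expected}")
    mean_ranks = r.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * (float((mean_ranks**2).sum()) - k * (k + 1) ** 2 / 4.0)
    denom = n * (k - 1) - chi2
    if abs(denom) < 1e-12:
        return chi2, float("inf"), True
    t1 = (n - 1) * chi2 / denom
    return chi2, t1, False


def f_critical(alpha: float = 0.05, df1: int = 5, df2: int = 15) -> float:
    """Upper-alpha quantile of the F distribution."""
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ConfigurationError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def bonferroni_dunn_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Critical difference for k-1 comparisons against a control at level alpha."""
    if k < 2 or n < 1:
        raise ConfigurationError("need k >= 2 methods and n >= 1 problems")
    q = float(stats.norm.ppf(1.0 - alpha / (2.0 * (k - 1))))
    return q * np.sqrt(k * (k + 1) / (6.0 * n))


def compare(
    table: AccuracyTable,
    baseline: str = "kNN",
    alpha: float = 0.05,
    cd_override: float | None = None,
) -> ComparisonResult:
    """Full rank-based comparison of an accuracy table against a baseline."""
    if baseline not in table.classifiers:
        raise ConfigurationError(f"baseline {baseline!r} not among classifiers {table.classifiers}")
    k = len(table.classifiers)
    n = len(table.classes)
    # rank within each class (column of the values matrix = per-class scores)
    rank_table = np.column_stack(
        [rank_with_ties(table.values[:, j]) for j in range(n)]
    )  # classifiers x classes
    avg_ranks = rank_table.mean(axis=1)
    chi2, t1, degenerate = friedman_T1(rank_table.T)
    df = (k - 1, (k - 1) * (n - 1))
    fc = f_critical(alpha, *df)
    cd = cd_override if cd_override is not None else bonferroni_dunn_cd(k, n, alpha)
    base_rank = avg_ranks[table.classifiers.index(baseline)]
    significant = {
        name: bool(base_rank - avg_ranks[i] > cd)
        for i, name in enumerate(table.classifiers)
    }
    return ComparisonResult(
        rank_table=rank_table,
        avg_ranks=avg_ranks,
        chi2_friedman=chi2,
        t1=t1,
        degenerate=degenerate,
        df=df,
        f_critical=fc,
        alpha=alpha,
        cd=float(cd),
        baseline=baseline,
        significant_vs_baseline=significant,
        classifiers=list(table.classifiers),
        classes=list(table.classes),
    )


def load_benchmark_accuracies() -> dict[str, AccuracyTable]:
    """The bundled benchmark accuracy tables (one per experiment variant)."""
    payload = json.loads(
        resources.files("petresponse").joinpath("data/benchmark_accuracies.json").read_text()
    )
    return {
        name: AccuracyTable(
            values=np.asarray(matrix, dtype=float),
            classifiers=list(payload["classifiers"]),
            classes=list(payload["classes"]),
        )
        for name, matrix in payload["experiments"].items()
    }


# --------------------------------------------------------------------------
# leave-one-out evaluation
# --------------------------------------------------------------------------


def _apply_variant_fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    variant: str,
    seed: int,
    smote_config: SmoteConfig | None,
    pca_components: int,
    pca_standardize: bool,
) -> tuple[np.ndarray, np.ndarray, PcaModel | None]:
    """Fit the variant's preprocessing on a training fold (SMOTE before PCA)."""
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; choose one of {VARIANTS}")
    model = None
    if variant in ("smote", "smote+pca"):
        cfg = smote_config or SmoteConfig()
        cfg = SmoteConfig(
            n_synthetic_per_class=cfg.n_synthetic_per_class,
            n_classes_to_oversample=cfg.n_classes_to_oversample,
            k_neighbors=cfg.k_neighbors,
            rng_seed=seed,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # k clamping on tiny folds is expected
            X_train, y_train = smote(X_train, y_train, cfg, singleton_policy="skip")
    if variant in ("pca", "smote+pca"):
        model = pca_fit(X_train, n_components=pca_components, standardize=pca_standardize)
        X_train = pca_transform(model, X_train)
    return X_train, y_train, model


def loo_predictions(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    variant: str = "original",
    seed: int = 0,
    smote_config: SmoteConfig | None = None,
    pca_components: int = 2,
    pca_standardize: bool = True,
) -> np.ndarray:
    """Predicted label for every sample under leave-one-out.

    For each fold the variant's preprocessing (SMOTE and/or PCA) is fit on
    the remaining samples only; the held-out sample is transformed with the
    fold's fitted PCA and predicted by the fold's trained model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = X.shape[0]
    if n < 2:
        raise DataError("leave-one-out requires >= 2 samples")
    preds = np.empty(n, dtype=object)
    for i in range(n):
        keep = np.arange(n) != i
        X_tr, y_tr, pca_model = _apply_variant_fit(
            X[keep], y[keep], variant, seed + i, smote_config, pca_components, pca_standardize
        )
        fold_spec = ClassifierSpec(spec.family, dict(spec.params), rng_seed=spec.rng_seed)
        model = train(fold_spec, X_tr, y_tr)
        X_te = X[i : i + 1]
        if pca_model is not None:
            X_te = pca_transform(pca_model, X_te)
        preds[i] = predict(model, X_te)[0]
    return preds


def per_class_accuracy(y_true, y_pred, classes: list | None = None) -> dict:
    """Per-class recall: correct fraction among held-out samples of a class."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    classes = classes if classes is not None else class_order(y_true)
    out = {}
    for c in classes:
        mask = y_true == c
        if not mask.any():
            raise DataError(f"class {c!r} has no held-out sample")
        out[c] = float((y_pred[mask] == c).mean())
    return out


def loo_per_class_accuracy(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    variant: str = "original",
    classes: list | None = None,
    **kwargs,
) -> dict:
    """Leave-one-out per-class accuracies of one classifier configuration."""
    preds = loo_predictions(spec, X, y, variant=variant, **kwargs)
    return per_class_accuracy(y, preds, classes)


def select_best_configuration(
    per_config_accuracies: list[dict],
) -> int:
    """Index of the configuration with the best (lowest) mean rank.

    ``per_config_accuracies`` maps, per configuration, class -> accuracy;
    all entries must cover the same classes.  Within each class the
    configurations are ranked with ties averaged; ties on the mean rank are
    broken by grid order.
    """
    if not per_config_accuracies:
        raise DataError("select_best_configuration requires at least one configuration")
    classes = list(per_config_accuracies[0])
    for acc in per_config_accuracies:
        if list(acc) != classes:
            raise DataError("all configurations must be evaluated on the same classes")
    ranks = np.column_stack(
        [rank_with_ties([acc[c] for acc in per_config_accuracies]) for c in classes]
    )
    mean_ranks = ranks.mean(axis=1)
    return int(np.argmin(mean_ranks))  # argmin keeps the first (grid order) on ties


def run_experiment(
    X: np.ndarray,
    y: np.ndarray,
    variant: str = "smote+pca",
    families: tuple[str, ...] = ("kNN", "MLP1", "MLP2", "LVQ", "RBF", "PNN"),
    seed: int = 0,
    baseline: str = "kNN",
    alpha: float = 0.05,
    cd_override: float | None = None,
    grids: dict[str, list[ClassifierSpec]] | None = None,
    **loo_kwargs,
) -> tuple[AccuracyTable, ComparisonResult, dict]:
    """Grid-search every family under LOO, then compare the winners.

    Returns the winners' accuracy table, the rank-based comparison, and a
    provenance record (chosen configuration and seed per family).
    """
    classes = class_order(y)
    rows = []
    provenance: dict = {"variant": variant, "seed": seed, "chosen": {}}
    for family in families:
        specs = (grids or {}).get(family) or grid(family)
        accs = []
        for s in specs:
            s = ClassifierSpec(s.family, dict(s.params), rng_seed=seed)
            accs.append(
                loo_per_class_accuracy(s, X, y, variant=variant, classes=classes,
                                       seed=seed, **loo_kwargs)
            )
        best = select_best_configuration(accs)
        rows.append([accs[best][c] for c in classes])
        provenance["chosen"][family] = {
            "params": specs[best].params,
            "per_class_accuracy": accs[best],
        }
    table = AccuracyTable(values=np.array(rows), classifiers=list(families), classes=classes)
    result = compare(table, baseline=baseline, alpha=alpha, cd_override=cd_override)
    return table, result, provenance
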