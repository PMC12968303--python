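"""Pairwise binary classification with bootstrap uncertainty.

For one disease-vs-control comparison: stratified train/test split at a
fixed seed, training-set-only feature screening (univariate + VIP), five
classifier families tuned by small-grid 5-fold cross-validation, and a
test-set metric panel (AUC, accuracy, sensitivity, specificity, F1, PPV,
NPV) with 95% percentile bootstrap confidence intervals over 1000
test-set resamples.

The point estimates come from the single declared split; the bootstrap
qualifies their stability, it does not redefine them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.metrics import roc_curve
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .matrix import AbundanceMatrix
from .screen import FeatureScreener, single_marker_auc

__all__ = [
    "ALGORITHMS",
    "METRICS",
    "SplitSpec",
    "ModelPanel",
    "ModelReport",
    "PairwiseConfig",
    "stratified_split",
    "train_models",
    "evaluate",
    "bootstrap_ci",
    "run_pairwise",
]

ALGORITHMS = (
    "logistic_regression",
    "svc",
    "knn",
    "random_forest",
    "gradient_boosting",
)

METRICS = ("auc", "accuracy", "sensitivity", "specificity", "f1", "ppv", "npv")


@dataclass(frozen=True)
class SplitSpec:
    """A stratified train/test partition (indices into the sample axis)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 42
    test_fraction: float = 0.25


def stratified_split(labels, test_fraction: float = 0.25, seed: int = 42) -> SplitSpec:
    """Deterministic stratified split preserving class proportions.

    Every class keeps its global proportion within one sample in each
    partition; classes with fewer than 2 samples are rejected.
    """
    labels = np.asarray(labels)
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    vals, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    if any(int(round(c * (1 - test_fraction))) < 1 or int(round(c * test_fraction)) < 1
           for c in counts):
        raise ValueError("test_fraction leaves an empty class in one partition")
    idx = np.arange(labels.size)
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    return SplitSpec(np.sort(train), np.sort(test), seed, test_fraction)


def _default_grids(seed: int) -> dict[str, tuple[BaseEstimator, dict]]:
    scaler = StandardScaler()
    return {
        "logistic_regression": (
            Pipeline([("scale", clone(scaler)), ("clf", LogisticRegression(max_iter=5000))]),
            {"clf__C": [0.01, 0.1, 1.0, 10.0]},
        ),
        "svc": (
            Pipeline([
                ("scale", clone(scaler)),
                ("clf", SVC(kernel="rbf", probability=True, random_state=seed)),
            ]),
            {"clf__C": [0.1, 1.0, 10.0]},
        ),
        "knn": (
            Pipeline([("scale", clone(scaler)), ("clf", KNeighborsClassifier())]),
            {"clf__n_neighbors": [3, 5, 7, 9]},
        ),
        "random_forest": (
            RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1),
            {"max_depth": [None, 4]},
        ),
        "gradient_boosting": (
            XGBClassifier(
                n_estimators=100,
                random_state=seed,
                eval_metric="logloss",
                tree_method="hist",
                n_jobs=1,
            ),
            {"max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
        ),
    }


class ModelPanel(BaseEstimator):
    """The five classifier families behind one fit/predict surface.

    Each family is tuned by seeded 5-fold stratified cross-validation over
    a small hyperparameter grid, on the training data only.  After
    ``fit``: ``models_`` maps family name to the refit best estimator and
    ``best_params_`` to the chosen hyperparameters.
    """

    def __init__(self, families=None, seed: int = 42, cv: int = 5, grids=None):
        self.families = families
        self.seed = seed
        self.cv = cv
        self.grids = grids

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training labels are single-class")
        grids = self.grids or _default_grids(self.seed)
        families = self.families or ALGORITHMS
        folds = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.seed)
        self.models_ = {}
        self.best_params_ = {}
        for name in families:
            est, grid = grids[name]
            gs = GridSearchCV(est, grid, cv=folds, scoring="roc_auc", n_jobs=1)
            gs.fit(X, y)
            self.models_[name] = gs.best_estimator_
            self.best_params_[name] = gs.best_params_
        self.classes_ = np.unique(y)
        return self

    def predict_proba_panel(self, X) -> dict[str, np.ndarray]:
        """Positive-class score from every fitted family."""
        X = np.asarray(X, dtype=float)
        return {
            name: model.predict_proba(X)[:, 1] for name, model in self.models_.items()
        }


def train_models(X, y, config: dict | None = None, seed: int = 42) -> ModelPanel:
    """Thin wrapper: fit a :class:`ModelPanel` on the training split."""
    cfg = config or {}
    panel = ModelPanel(
        families=cfg.get("families"),
        seed=seed,
        cv=cfg.get("cv", 5),
        grids=cfg.get("grids"),
    )
    return panel.fit(X, y)


def _metrics_from_scores(scores, y01, threshold: float = 0.5) -> dict[str, float]:
    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray(y01, dtype=int)
    pos, neg = scores[y01 == 1], scores[y01 == 0]
    auc = single_marker_auc(pos, neg) if pos.size and neg.size else np.nan
    yhat = (scores >= threshold).astype(int)
    tp = int(np.sum((yhat == 1) & (y01 == 1)))
    fn = int(np.sum((yhat == 0) & (y01 == 1)))
    tn = int(np.sum((yhat == 0) & (y01 == 0)))
    fp = int(np.sum((yhat == 1) & (y01 == 0)))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    ppv = tp / (tp + fp) if (tp + fp) else np.nan
    npv = tn / (tn + fn) if (tn + fn) else np.nan
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
        else np.nan
    )
    acc = (tp + tn) / y01.size
    return {
        "auc": auc,
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
        "ppv": ppv,
        "npv": npv,
    }


def evaluate(model, X, y01, threshold: float = 0.5) -> dict[str, float]:
    """Test-set metric panel from a fitted probabilistic classifier.

    AUC is the rank statistic on the positive-class scores (ties
    half-weighted); the remaining metrics come from the confusion matrix at
    the given probability threshold.  Undefined ratios (e.g. PPV with no
    positive call) are reported as NaN, never as 0.
    """
    scores = model.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return _metrics_from_scores(scores, y01, threshold)


def bootstrap_ci(
    scores,
    labels,
    metric,
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """95% percentile bootstrap interval of one test-set metric.

    Test rows are resampled with replacement; resamples collapsing to a
    single class are redrawn (count logged via warning).  An error is
    raised when the metric is undefined in more than half the resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if isinstance(metric, str):
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        fn = lambda s, l: _metrics_from_scores(s, l, threshold)[metric]  # noqa: E731
    else:
        fn = metric
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    skipped = 0
    for b in range(n_boot):
        idx = rng.integers(0, labels.size, labels.size)
        while np.unique(labels[idx]).size < 2:
            skipped += 1
            idx = rng.integers(0, labels.size, labels.size)
        vals[b] = fn(scores[idx], labels[idx])
    if skipped:
        warnings.warn(f"redrew {skipped} single-class bootstrap resamples")
    finite = vals[np.isfinite(vals)]
    if finite.size < 0.5 * n_boot:
        raise ValueError("metric undefined in more than half the resamples")
    return float(np.percentile(finite, 2.5)), float(np.percentile(finite, 97.5))


def _bootstrap_panel(scores, labels01, n_boot, seed, threshold=0.5):
    """All seven metrics over the same n_boot resamples."""
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01, dtype=int)
    rng = np.random.default_rng(seed)
    out = {m: np.empty(n_boot) for m in METRICS}
    skipped = 0
    for b in range(n_boot):
        n = labels01.size
        idx = rng.integers(0, n, n)
        while np.unique(labels01[idx]).size < 2:
            skipped += 1
            idx = rng.integers(0, n, n)
        vals = _metrics_from_scores(scores[idx], labels01[idx], threshold)
        for m in METRICS:
            out[m][b] = vals[m]
    if skipped:
        warnings.warn(f"redrew {skipped} single-class bootstrap resamples")
    return out


@dataclass(frozen=True)
class PairwiseConfig:
    """Conditions for one pairwise comparison run."""

    seed: int = 42
    test_fraction: float = 0.25
    alpha: float = 0.05
    vip_min: float = 1.0
    n_ortho: int = 1
    n_boot: int = 1000
    threshold: float = 0.5
    log_transform: bool = True
    families: tuple = ALGORITHMS


@dataclass
class ModelReport:
    """Per-algorithm metric panel with bootstrap CIs for one comparison."""

    pair: tuple[str, str]
    seed: int
    n_boot: int
    selected_features: list[str]
    screening: pd.DataFrame
    results: dict[str, dict]
    n_train: int
    n_test: int
    roc: dict[str, pd.DataFrame] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for algo, res in self.results.items():
            row = {"algorithm": algo, "train_auc": res["train_auc"]}
            for m in METRICS:
                row[m] = res["test"][m]
                row[f"{m}_lo"], row[f"{m}_hi"] = res["ci"][m]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "pair": list(self.pair),
            "seed": self.seed,
            "n_boot": self.n_boot,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "selected_features": self.selected_features,
            "results": {
                algo: {
                    "train_auc": res["train_auc"],
                    "test": res["test"],
                    "ci": {m: list(res["ci"][m]) for m in METRICS},
                    "best_params": {k: repr(v) for k, v in res["best_params"].items()},
                }
                for algo, res in self.results.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)

    @property
    def best_test_auc(self) -> float:
        return max(res["test"]["auc"] for res in self.results.values())


def run_pairwise(
    m: AbundanceMatrix,
    pair: tuple[str, str],
    config: PairwiseConfig | None = None,
) -> ModelReport:
    """Full leakage-free comparison of one disease/control pair.

    Order of operations: subset the matrix to the pair, stratified split,
    half-minimum imputation with training-split minima, optional log
    transform, screening (Mann-Whitney + BH + VIP) on the training split,
    model tuning on the selected features, evaluation on the untouched
    test split, bootstrap CIs.  Fewer than 2 passing features falls back
    to all features with a warning.
    """
    cfg = config or PairwiseConfig()
    case, control = pair
    have = set(m.groups.unique())
    if case not in have or control not in have:
        raise ValueError(f"pair {pair!r} not found among groups {sorted(have)}")
    keep = m.groups.isin([case, control])
    sub = m.subset(samples=list(m.groups.index[keep]))
    X = sub.data.copy()
    y = sub.groups.astype(str)

    split = stratified_split(y.to_numpy(), cfg.test_fraction, cfg.seed)
    train_rows = X.index[split.train_idx]
    test_rows = X.index[split.test_idx]

    # impute from training-split minima only; drop features never seen in train
    train_min = X.loc[train_rows].min(axis=0)
    dead = train_min.isna()
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} feature(s) with no training observations"
        )
        X = X.loc[:, ~dead]
        train_min = train_min[~dead]
    X = X.fillna(0.5 * train_min)

    if cfg.log_transform:
        # floor from the training split only: the test fold must not shape
        # any part of the transform
        xtr = X.loc[train_rows]
        floor = float(xtr[xtr > 0].min().min())
        X = np.log(X.clip(lower=floor / 2.0))

    Xtr, ytr = X.loc[train_rows], y.loc[train_rows]
    Xte, yte = X.loc[test_rows], y.loc[test_rows]

    screener = FeatureScreener(
        alpha=cfg.alpha, vip_min=cfg.vip_min, n_ortho=cfg.n_ortho, positive_class=case
    ).fit(Xtr, ytr)
    selected = screener.selected_features_
    if len(selected) < 2:
        warnings.warn(
            f"only {len(selected)} feature(s) passed the screen; using all features"
        )
        selected = list(X.columns)

    ytr01 = (ytr == case).astype(int).to_numpy()
    yte01 = (yte == case).astype(int).to_numpy()
    panel = train_models(
        Xtr[selected].to_numpy(), ytr01, {"families": cfg.families}, seed=cfg.seed
    )

    results = {}
    roc = {}
    train_scores = panel.predict_proba_panel(Xtr[selected].to_numpy())
    test_scores = panel.predict_proba_panel(Xte[selected].to_numpy())
    for algo in panel.models_:
        s_tr, s_te = train_scores[algo], test_scores[algo]
        train_auc = single_marker_auc(s_tr[ytr01 == 1], s_tr[ytr01 == 0])
        test_metrics = _metrics_from_scores(s_te, yte01, cfg.threshold)
        draws = _bootstrap_panel(s_te, yte01, cfg.n_boot, cfg.seed, cfg.threshold)
        ci = {}
        for met in METRICS:
            finite = draws[met][np.isfinite(draws[met])]
            if finite.size < 0.5 * cfg.n_boot:
                ci[met] = (np.nan, np.nan)
            else:
                ci[met] = (
                    float(np.percentile(finite, 2.5)),
                    float(np.percentile(finite, 97.5)),
                )
        fpr, tpr, _ = roc_curve(yte01, s_te)
        roc[algo] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        results[algo] = {
            "train_auc": train_auc,
            "test": test_metrics,
            "ci": ci,
            "best_params": panel.best_params_[algo],
        }

    return ModelReport(
        pair=pair,
        seed=cfg.seed,
        n_boot=cfg.n_boot,
        selected_features=list(selected),
        screening=screener.records_,
        results=results,
        n_train=len(train_rows),
        n_test=len(test_rows),
        roc=roc,
    )
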