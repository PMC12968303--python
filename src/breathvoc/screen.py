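"""Univariate + multivariate feature screening on the training split.

Per feature: Mann-Whitney U with Benjamini-Hochberg FDR control, fold
change as the ratio of group medians (disease over control), the
single-marker AUC (the concordance probability U / (n1*n2), ties
half-weighted), and the OPLS-DA VIP.  A feature passes the screen when
its BH-adjusted q-value is below alpha AND its VIP exceeds vip_min.

The screen must only ever see the training split; :class:`FeatureScreener`
packages the rule as a scikit-learn feature selector so pipelines enforce
that by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from statsmodels.stats.multitest import multipletests

from .oplsda import OPLSDA

__all__ = [
    "mann_whitney",
    "adjust_fdr",
    "fold_change",
    "single_marker_auc",
    "screen_features",
    "FeatureScreener",
]

#: Largest pooled size for which the exact (enumeration) null is used.
EXACT_MAX_N = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = #{x_i > y_j} + 0.5 * #ties``.  The exact
    permutation null is used when ``n1 + n2 <= 12`` and the pooled data are
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def fold_change(x, y) -> float:
    """Ratio of group medians, median(x) / median(y) (x = disease group)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    my = np.median(y)
    if my <= 0:
        raise ValueError("denominator group median must be positive")
    return float(np.median(x) / my)


def single_marker_auc(x, y) -> float:
    """Concordance probability P(x > y) with ties half-weighted.

    Equals the rank-based AUC of the feature as a single diagnostic marker
    for membership in the x group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    r = rankdata(np.concatenate([x, y]))
    u = r[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def screen_features(
    X: pd.DataFrame,
    labels,
    vips,
    case: str,
    control: str,
    alpha: float = 0.05,
    vip_min: float = 1.0,
) -> pd.DataFrame:
    """Full screening table for one pairwise comparison.

    ``X`` is a complete (imputed) training matrix; ``vips`` a per-feature
    series aligned to its columns.  ``passes = (q < alpha) & (vip >
    vip_min)``; records are sorted by q then feature id.
    """
    labels = pd.Series(labels, index=X.index) if not isinstance(labels, pd.Series) else labels
    if not labels.index.equals(X.index):
        raise ValueError("labels must be aligned to the matrix rows")
    vips = pd.Series(vips, index=X.columns) if not isinstance(vips, pd.Series) else vips
    if not vips.index.equals(X.columns):
        raise ValueError("vips must be aligned to the matrix columns")
    xi = labels == case
    yi = labels == control
    if not xi.any() or not yi.any():
        raise ValueError(f"groups {case!r} / {control!r} not both present")

    rows = []
    for f in X.columns:
        xv = X.loc[xi, f].dropna().to_numpy()
        yv = X.loc[yi, f].dropna().to_numpy()
        u, p = mann_whitney(xv, yv)
        rows.append(
            {
                "feature_id": f,
                "u_stat": u,
                "p": p,
                "fold_change": fold_change(xv, yv),
                "vip": float(vips[f]),
                "auc_single": single_marker_auc(xv, yv),
            }
        )
    rec = pd.DataFrame(rows)
    rec["q"] = adjust_fdr(rec["p"].to_numpy())
    rec["passes"] = (rec["q"] < alpha) & (rec["vip"] > vip_min)
    rec = rec[
        ["feature_id", "u_stat", "p", "q", "fold_change", "vip", "auc_single", "passes"]
    ]
    return rec.sort_values(["q", "feature_id"], kind="mergesort").reset_index(drop=True)


class FeatureScreener(SelectorMixin, BaseEstimator):
    """Scikit-learn selector implementing the q < alpha AND VIP > vip_min rule.

    Parameters
    ----------
    alpha, vip_min : screening thresholds.
    n_ortho : orthogonal components of the internal OPLS-DA VIP model.
    positive_class : label treated as the disease group (fold-change and
        AUC orientation); defaults to the lexicographically larger label.

    After ``fit``, ``records_`` holds the full screening table and
    ``selected_features_`` the passing feature ids.
    """

    def __init__(self, alpha: float = 0.05, vip_min: float = 1.0, n_ortho: int = 1,
                 positive_class=None):
        self.alpha = alpha
        self.vip_min = vip_min
        self.n_ortho = n_ortho
        self.positive_class = positive_class

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            frame = pd.DataFrame(np.asarray(X, dtype=float))
            frame.columns = [f"x{j}" for j in range(frame.shape[1])]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        y = pd.Series(np.asarray(y), index=frame.index)
        classes = sorted(map(str, y.unique()))
        if len(classes) != 2:
            raise ValueError("screening requires exactly two groups")
        pos = self.positive_class if self.positive_class is not None else classes[1]
        neg = [c for c in classes if c != str(pos)]
        if len(neg) != 1:
            raise ValueError(f"positive_class {pos!r} not found among groups {classes}")
        model = OPLSDA(n_ortho=self.n_ortho).fit(frame.to_numpy(), y.to_numpy())
        vips = pd.Series(model.vip_, index=frame.columns)
        self.opls_ = model
        self.records_ = screen_features(
            frame, y.astype(str), vips, str(pos), neg[0],
            alpha=self.alpha, vip_min=self.vip_min,
        )
        passing = set(self.records_.loc[self.records_["passes"], "feature_id"])
        self.support_ = np.array([f in passing for f in frame.columns])
        self.selected_features_ = [f for f in frame.columns if f in passing]
        return self

    def _get_support_mask(self):
        return self.support_
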