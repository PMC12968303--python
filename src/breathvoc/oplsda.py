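"""Orthogonal PLS discriminant analysis (O-PLS) and VIP scoring.

O-PLS splits X-variation into a single class-predictive component and
``n_ortho`` components orthogonal to the class label, via the NIPALS-style
deflation of Trygg & Wold: for each orthogonal component the y-orthogonal
part of the current weight vector is extracted and its scores removed from
X; the predictive component is then fit on the deflated matrix.  The fit
is deterministic (no randomness).

VIP is computed on the predictive component only: with one predictive
component and a unit-norm weight vector w this reduces to
``VIP_j = sqrt(p) * |w_j|``, which automatically satisfies
``mean(VIP^2) = 1``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["autoscale", "OPLSDA", "fit_opls", "vip_scores"]


def autoscale(X):
    """Center each column to mean 0 and scale to unit (population) SD.

    Returns ``(X_scaled, center, spread)``.  Zero-variance columns are an
    error naming the offending feature.
    """
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    spread = X.std(axis=0)
    zero = np.flatnonzero(spread == 0)
    if zero.size:
        raise ValueError(f"zero-variance feature(s) at column index {zero.tolist()}")
    return (X - center) / spread, center, spread


class OPLSDA(BaseEstimator, TransformerMixin):
    """O-PLS discriminant analysis with one predictive component.

    Parameters
    ----------
    n_ortho : int, default 1
        Number of y-orthogonal components removed before the predictive fit.
        With ``n_ortho=0`` the model coincides with one-component PLS-DA.
    scale : bool, default True
        Autoscale columns (unit variance) before fitting.

    Attributes (after fit)
    ----------------------
    weights_, loadings_, scores_ : predictive component (w, p, t)
    ortho_weights_, ortho_loadings_, ortho_scores_ : orthogonal components
    y_loading_ : scalar regression of centered y on the predictive scores
    vip_ : per-feature variable importance in projection
    x_mean_, x_std_ : scaling parameters
    classes_ : the two class labels, ``classes_[1]`` coded +1
    """

    def __init__(self, n_ortho: int = 1, scale: bool = True):
        self.n_ortho = n_ortho
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("OPLS-DA requires exactly two classes in y")
        if X.shape[0] <= self.n_ortho + 1:
            raise ValueError("need more samples than n_ortho + 1")
        self.classes_ = classes
        yv = np.where(y == classes[1], 1.0, 0.0)
        self._y_mean = yv.mean()
        yc = yv - self._y_mean

        if self.scale:
            Xw, self.x_mean_, self.x_std_ = autoscale(X)
        else:
            self.x_mean_ = X.mean(axis=0)
            self.x_std_ = np.ones(X.shape[1])
            Xw = X - self.x_mean_

        def _w_of(M):
            w = M.T @ yc
            nrm = np.linalg.norm(w)
            if nrm == 0:
                raise ValueError("y carries no covariance with X")
            return w / nrm

        w_o, p_o, t_o = [], [], []
        Xd = Xw
        for _ in range(self.n_ortho):
            w = _w_of(Xd)
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            wo = p - (w @ p) * w
            nrm = np.linalg.norm(wo)
            if nrm < 1e-12:
                break  # nothing orthogonal left to remove
            wo = wo / nrm
            to = Xd @ wo
            po = Xd.T @ to / (to @ to)
            Xd = Xd - np.outer(to, po)
            w_o.append(wo)
            p_o.append(po)
            t_o.append(to)

        w = _w_of(Xd)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        self.weights_ = w
        self.scores_ = t
        self.loadings_ = p
        self.y_loading_ = float(yc @ t / (t @ t))
        self.ortho_weights_ = np.array(w_o)
        self.ortho_loadings_ = np.array(p_o)
        self.ortho_scores_ = np.array(t_o).T if t_o else np.empty((X.shape[0], 0))
        n_feat = X.shape[1]
        self.vip_ = np.sqrt(n_feat) * np.abs(w)  # ||w|| = 1
        return self

    def _deflate(self, Xw):
        for wo, po in zip(self.ortho_weights_, self.ortho_loadings_):
            to = Xw @ wo
            Xw = Xw - np.outer(to, po)
        return Xw

    def transform(self, X):
        """Predictive scores of new samples (orthogonal variation removed)."""
        check_is_fitted(self, "weights_")
        Xw = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        return (self._deflate(Xw) @ self.weights_)[:, None]

    def decision_function(self, X):
        return self.transform(X).ravel() * self.y_loading_ + self._y_mean - 0.5

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def fit_opls(X, y, n_ortho: int = 1, scale: bool = True) -> OPLSDA:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_ortho=n_ortho, scale=scale).fit(X, y)


def vip_scores(model: OPLSDA) -> np.ndarray:
    """Per-feature VIP of a fitted model (predictive component only)."""
    check_is_fitted(model, "vip_")
    return model.vip_
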