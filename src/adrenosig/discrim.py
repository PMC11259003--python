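"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

The model splits the predictor variation into a single y-predictive
component and ``n_ortho`` components orthogonal to the class response
(orthogonal signal correction). With ``n_ortho=0`` it reduces exactly to a
one-component NIPALS PLS fit, which the test suite exploits as an oracle.

Variable importance in projection (VIP) scores satisfy sum(VIP^2) = p, so
the mean squared VIP is 1 and VIP > 1.5 marks strongly contributing
variables. Predictive ability is assessed by stratified-k-fold Q2Y
(1 - PRESS/TSS) and by a label-permutation test on Q2Y; under repeated
SMOTE resampling the per-variable VIPs are aggregated by their medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortMatrix
from .resample import SmoteParams, resample_stream

VIP_CUTOFF = 1.5


class OPLSDA(BaseEstimator):
    """Two-class OPLS-DA estimator with one predictive component.

    Parameters
    ----------
    n_ortho : int
        Number of orthogonal (y-uncorrelated) components removed before the
        predictive fit.

    Attributes (after ``fit``)
    --------------------------
    w_, t_, p_ : predictive weights, scores, loadings
    W_ortho_, T_ortho_, P_ortho_ : orthogonal component sets (p x a, n x a)
    c_ : y-loading of the predictive score
    r2y_ : fraction of class variance explained on the training data
    vip_ : variable importance in projection (sum of squares = n_features)
    """

    def __init__(self, n_ortho: int = 1):
        self.n_ortho = n_ortho

    # -- fitting -------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "OPLSDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one label per row")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("OPLS-DA requires exactly two classes")
        if self.n_ortho >= min(X.shape) or self.n_ortho < 0:
            raise ValueError("n_ortho must be in [0, rank(X))")
        self.classes_ = classes
        # +1 for the minority (second-sorted == rarer? keep: minority = less frequent)
        counts = [(y == c).sum() for c in classes]
        self.positive_class_ = classes[int(np.argmin(counts))]
        yc = np.where(y == self.positive_class_, 1.0, -1.0)

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = yc.mean()
        Xd = X - self.x_mean_
        u = yc - self.y_mean_

        n, p = Xd.shape
        W_o, T_o, P_o = [], [], []
        for _ in range(self.n_ortho):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("response carries no covariance with X")
            w /= nw
            t = Xd @ w
            p_load = Xd.T @ t / (t @ t)
            w_o = p_load - (w @ p_load) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12:
                break  # no orthogonal variation left
            w_o /= n_o
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)

        w = Xd.T @ u
        w /= np.linalg.norm(w)
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        c = (u @ t) / (t @ t)
        # orient so the positive class has positive mean score
        if t[yc > 0].mean() < 0:
            w, t, p_load, c = -w, -t, -p_load, -c

        self.w_ = w
        self.t_ = t
        self.p_ = p_load
        self.c_ = c
        self.W_ortho_ = np.column_stack(W_o) if W_o else np.empty((p, 0))
        self.T_ortho_ = np.column_stack(T_o) if T_o else np.empty((n, 0))
        self.P_ortho_ = np.column_stack(P_o) if P_o else np.empty((p, 0))

        ss_y = u @ u
        resid = u - t * c
        self.r2y_ = 1.0 - (resid @ resid) / ss_y
        self._u = u
        self.vip_ = self._compute_vip()
        return self

    def _compute_vip(self) -> np.ndarray:
        """VIP_j = sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a).

        The sum runs over the predictive component and the orthogonal
        components, each weighted by the share of class variance its score
        explains; orthogonal scores explain ~0 of y by construction, so the
        predictive component dominates.
        """
        u = self._u
        ss_y = u @ u
        weights = [self.w_]
        scores = [self.t_]
        for a in range(self.T_ortho_.shape[1]):
            weights.append(self.W_ortho_[:, a])
            scores.append(self.T_ortho_[:, a])
        ssy = np.array([(u @ t) ** 2 / (t @ t) / ss_y for t in scores])
        wnorm = np.column_stack([w / np.linalg.norm(w) for w in weights])
        p = len(self.w_)
        return np.sqrt(p * (wnorm**2 @ ssy) / ssy.sum())

    # -- prediction ----------------------------------------------------------
    def _orthogonal_correct(self, X: np.ndarray) -> np.ndarray:
        Xd = np.asarray(X, dtype=float) - self.x_mean_
        for a in range(self.W_ortho_.shape[1]):
            t_o = Xd @ self.W_ortho_[:, a]
            Xd = Xd - np.outer(t_o, self.P_ortho_[:, a])
        return Xd

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive score of new samples after orthogonal correction."""
        return self._orthogonal_correct(X) @ self.w_

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction on the centered +/-1 scale."""
        return self.transform(X) * self.c_ + self.y_mean_

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        neg = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(d >= 0, self.positive_class_, neg)


def fit_oplsda(X: np.ndarray, y: np.ndarray, n_ortho: int = 1) -> OPLSDA:
    """Functional wrapper: fit an :class:`OPLSDA` model."""
    return OPLSDA(n_ortho=n_ortho).fit(X, y)


def vip(model: OPLSDA) -> np.ndarray:
    """VIP scores of a fitted model (sum of squares equals n_features)."""
    if not hasattr(model, "vip_"):
        raise ValueError("model is not fitted")
    return model.vip_


def q2y(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 1,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """Cross-validated predictive ability, 1 - PRESS/TSS.

    Stratified k-fold so every training fold keeps both classes; requires
    the minority class to have at least ``n_folds`` members.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class ({counts.min()}) smaller than n_folds={n_folds}; "
            "reduce n_folds"
        )
    positive = classes[int(np.argmin(counts))]
    ynum = np.where(y == positive, 1.0, -1.0)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    press = 0.0
    for train, test in cv.split(X, y):
        model = OPLSDA(n_ortho=n_ortho).fit(X[train], y[train])
        pred = model.decision_function(X[test])
        sign = 1.0 if model.positive_class_ == positive else -1.0
        press += np.sum((ynum[test] - sign * pred) ** 2)
    tss = np.sum((ynum - ynum.mean()) ** 2)
    return 1.0 - press / tss


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    n_ortho: int = 1,
    n_folds: int = 7,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Label-permutation test on Q2Y.

    Returns ``(p_perm, null_q2y, observed_q2y)`` with
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = q2y(X, y, n_ortho=n_ortho, n_folds=n_folds, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    y = np.asarray(y)
    for i in range(n_perm):
        null[i] = q2y(X, rng.permutation(y), n_ortho=n_ortho, n_folds=n_folds, seed=seed)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return p, null, observed


@dataclass
class OplsSummary:
    r2y: float
    q2y: float
    p_perm: float | None


def repeated_vip(
    cohort: CohortMatrix,
    params: SmoteParams | None = None,
    n_resamples: int = 1000,
    n_ortho: int = 1,
    vip_cutoff: float = VIP_CUTOFF,
) -> pd.DataFrame:
    """Median VIP per metabolite over SMOTE resamples, ranked.

    Fails if fewer than half of the resample fits succeed.
    """
    if params is None:
        params = SmoteParams()
    if "scale" not in cohort.state:
        raise ValueError("cohort must be fully processed (log + Pareto scaled)")
    X = cohort.abundances.to_numpy(dtype=float)
    y = cohort.group_indicator()
    vips = []
    n_fail = 0
    for res in resample_stream(X, y, params, n_resamples):
        try:
            model = OPLSDA(n_ortho=n_ortho).fit(res.X, res.y)
            vips.append(model.vip_)
        except (ValueError, np.linalg.LinAlgError):
            n_fail += 1
    if len(vips) < n_resamples / 2:
        raise RuntimeError(f"only {len(vips)}/{n_resamples} OPLS-DA fits succeeded")
    med = np.median(np.array(vips), axis=0)
    table = pd.DataFrame(
        {"vip_median": med, "selected": med > vip_cutoff},
        index=cohort.abundances.columns,
    )
    table["rank"] = table["vip_median"].rank(ascending=False, method="first").astype(int)
    table.attrs["n_failed_fits"] = n_fail
    return table.sort_values("vip_median", ascending=False)
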