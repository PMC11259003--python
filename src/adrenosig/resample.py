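"""Synthetic Minority Over-sampling Technique (SMOTE), from scratch.

For every minority-class sample, ``replications`` synthetic samples are
generated as convex combinations ``x + u * (x_nb - x)`` with ``u ~ U(0, 1)``
and ``x_nb`` drawn uniformly from the sample's ``k`` nearest minority
neighbors (Euclidean distance in the processed feature space). With the
discovery-cohort defaults (k = 3, replications = 3) a 188/12 cohort becomes
188 majority / 48 minority.

Categorical covariates (e.g. sex) are never interpolated: a synthetic
sample copies them from its seed instance, so binary covariates remain in
{0, 1} for the downstream logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


@dataclass
class SmoteParams:
    """k nearest neighbors and synthetic replications per minority sample."""

    k: int = 3
    replications: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.replications < 0:
            raise ValueError("replications must be >= 0")


@dataclass
class SmoteResult:
    """Augmented data plus per-synthetic-row provenance."""

    X: np.ndarray
    y: np.ndarray
    covariates: np.ndarray | None
    #: (seed row index into X_in, neighbor row index into X_in, u) per synthetic row
    provenance: list[tuple[int, int, float]] = field(default_factory=list)


class SmoteOversampler:
    """Estimator-style wrapper around :func:`smote`.

    Follows the resampler convention (``fit_resample``) with
    ``get_params``/``set_params`` so it composes with sklearn-style tooling.
    """

    def __init__(self, k: int = 3, replications: int = 3, seed: int = 0):
        self.k = k
        self.replications = replications
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "replications": self.replications, "seed": self.seed}

    def set_params(self, **params) -> "SmoteOversampler":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit_resample(
        self, X: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        params = SmoteParams(self.k, self.replications, self.seed)
        result = smote(X, y, params, covariates=covariates)
        self.provenance_ = result.provenance
        self.covariates_resampled_ = result.covariates
        return result.X, result.y


def _minority_label(y: np.ndarray) -> tuple[np.ndarray, int | float]:
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) != 2:
        raise ValueError(f"expected exactly two classes, found {len(labels)}")
    order = np.argsort(counts, kind="stable")
    return labels, labels[order[0]]


def smote(
    X: np.ndarray,
    y: np.ndarray,
    params: SmoteParams,
    covariates: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SmoteResult:
    """Oversample the minority class of a two-class dataset.

    Parameters
    ----------
    X
        Feature matrix (n_samples, n_features); must be fully observed.
    y
        Binary class vector; the rarer label is oversampled.
    covariates
        Optional per-sample array copied (not interpolated) onto synthetic
        samples from their seed instance.
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if np.isnan(X).any():
        raise ValueError("SMOTE requires a fully imputed feature matrix")
    _, minority = _minority_label(y)
    idx_min = np.flatnonzero(y == minority)
    n_min = len(idx_min)
    if n_min <= params.k:
        raise ValueError(f"minority size {n_min} must exceed k={params.k}")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    Xm = X[idx_min]
    # all-pairs distances within the minority class; ties broken by index
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    if np.isfinite(d2).any() and np.nanmax(np.where(np.isfinite(d2), d2, 0)) == 0:
        warnings.warn("all minority samples identical; synthetic samples duplicate them")
    neighbors = np.argsort(d2, axis=1, kind="stable")[:, : params.k]

    synth_rows = []
    synth_cov = []
    provenance: list[tuple[int, int, float]] = []
    for local_i, i in enumerate(idx_min):
        for _ in range(params.replications):
            nb_local = neighbors[local_i, rng.integers(params.k)]
            u = rng.uniform()
            row = Xm[local_i] + u * (Xm[nb_local] - Xm[local_i])
            synth_rows.append(row)
            provenance.append((int(i), int(idx_min[nb_local]), float(u)))
            if covariates is not None:
                synth_cov.append(np.asarray(covariates)[i])

    if synth_rows:
        X_out = np.vstack([X, np.array(synth_rows)])
        y_out = np.concatenate([y, np.full(len(synth_rows), minority, dtype=y.dtype)])
        cov_out = (
            None
            if covariates is None
            else np.concatenate([np.asarray(covariates), np.array(synth_cov)])
        )
    else:
        X_out, y_out = X.copy(), y.copy()
        cov_out = None if covariates is None else np.asarray(covariates).copy()
    return SmoteResult(X=X_out, y=y_out, covariates=cov_out, provenance=provenance)


def resample_stream(
    X: np.ndarray,
    y: np.ndarray,
    params: SmoteParams,
    n_resamples: int,
    covariates: np.ndarray | None = None,
) -> Iterator[SmoteResult]:
    """Yield `n_resamples` independent SMOTE datasets.

    Each resample is seeded deterministically from ``(params.seed, index)``
    so streams are reproducible and order-independent.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    for i in range(n_resamples):
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, i)))
        yield smote(X, y, params, covariates=covariates, rng=rng)
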