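"""Repeated logistic association testing under class imbalance.

Each metabolite is tested with the model

    P(y = insufficient) = 1 / (1 + exp(-(b0 + b1*m + b2*g)))

where ``m`` is the (processed) metabolite measurement and ``g`` is sex
(female = 0, male = 1). To absorb the randomness of minority oversampling,
the model is refitted on many independent SMOTE resamples and the per-
metabolite p-values (and effect estimates) are aggregated by their medians,
followed by Benjamini-Hochberg FDR correction across metabolites.

The maximum-likelihood fits run as a single batched Newton/IRLS solve
across all metabolites, which keeps 1000 resamples x hundreds of
metabolites tractable. Quasi-separated fits (likely with ~12 cases) are
refitted with a small L2 ridge on the slopes and flagged, never silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortMatrix
from .resample import SmoteParams, resample_stream

_Z95 = stats.norm.ppf(0.975)
#: |beta| beyond this on a scaled covariate signals (quasi-)separation
_SEPARATION_BOUND = 30.0
_RIDGE = 1e-4


@dataclass
class LogisticFit:
    beta: np.ndarray  # (intercept, slope of m, [slope of g])
    se: np.ndarray
    p_beta1: float
    or_point: float
    or_ci_low: float
    or_ci_high: float
    converged: bool
    ridged: bool


def _batch_irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton/IRLS for B logistic models sharing the response.

    Parameters
    ----------
    X
        Stacked design matrices, shape (B, n, k).
    y
        Response, shape (n,).
    ridge
        L2 penalty applied to slopes (not the intercept).

    Returns (beta (B,k), se (B,k), converged (B,) bool).
    """
    B, n, k = X.shape
    beta = np.zeros((B, k))
    pen = np.full(k, ridge)
    pen[0] = 0.0  # never penalize the intercept
    pen_mat = np.diag(pen)
    converged = np.zeros(B, dtype=bool)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        Xa = X[active]
        ba = beta[active]
        eta = np.einsum("bnk,bk->bn", Xa, ba)
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = np.einsum("bnk,bn->bk", Xa, y[None, :] - mu) - ba * pen
        hess = np.einsum("bnk,bn,bnl->bkl", Xa, w, Xa) + pen_mat
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("bkl,bl->bk", np.linalg.pinv(hess), grad)
        ba = ba + step
        beta[active] = ba
        done = np.max(np.abs(step), axis=1) < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False
        if not active.any():
            break
    eta = np.einsum("bnk,bk->bn", X, beta)
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = np.einsum("bnk,bn,bnl->bkl", X, w, X) + pen_mat
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0, None))
    return beta, se, converged


def fit_logistic_batch(
    y: np.ndarray, M: np.ndarray, g: np.ndarray | None = None
) -> pd.DataFrame:
    """Fit `y ~ m_j (+ g)` for every column of `M` in one batched solve.

    Returns a DataFrame with beta1, se1, p, OR and 95% CI, plus convergence
    and ridge flags, one row per column of ``M``.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("y must contain both classes")
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, B = M.shape
    cols = [np.ones((B, n, 1)), np.transpose(M)[:, :, None]]
    if g is not None:
        cols.append(np.broadcast_to(np.asarray(g, float)[None, :, None], (B, n, 1)))
    X = np.concatenate(cols, axis=2)

    beta, se, converged = _batch_irls(X, y)
    # separation / non-convergence -> ridge refit, flagged
    bad = (~converged) | (np.abs(beta).max(axis=1) > _SEPARATION_BOUND) | ~np.isfinite(se).all(axis=1)
    ridged = np.zeros(B, dtype=bool)
    if bad.any():
        b2, s2, c2 = _batch_irls(X[bad], y, ridge=_RIDGE)
        beta[bad], se[bad] = b2, s2
        converged[bad] = c2
        ridged[bad] = True
    z = np.divide(beta[:, 1], se[:, 1], out=np.zeros(B), where=se[:, 1] > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "beta1": beta[:, 1],
            "se1": se[:, 1],
            "p": p,
            "or_point": np.exp(beta[:, 1]),
            "or_ci_low": np.exp(beta[:, 1] - _Z95 * se[:, 1]),
            "or_ci_high": np.exp(beta[:, 1] + _Z95 * se[:, 1]),
            "converged": converged,
            "ridged": ridged,
        }
    )


def fit_logistic(y, m, g=None) -> LogisticFit:
    """Single-metabolite logistic fit: Wald p and 95% CI for the slope."""
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    cols = [np.ones_like(m), m]
    if g is not None:
        cols.append(np.asarray(g, dtype=float))
    X = np.column_stack(cols)[None, :, :]
    beta, se, converged = _batch_irls(X, y)
    ridged = False
    if (not converged[0]) or np.abs(beta).max() > _SEPARATION_BOUND:
        beta, se, converged = _batch_irls(X, y, ridge=_RIDGE)
        ridged = True
    b, s = beta[0], se[0]
    z = b[1] / s[1] if s[1] > 0 else 0.0
    return LogisticFit(
        beta=b,
        se=s,
        p_beta1=float(2 * stats.norm.sf(abs(z))),
        or_point=float(np.exp(b[1])),
        or_ci_low=float(np.exp(b[1] - _Z95 * s[1])),
        or_ci_high=float(np.exp(b[1] + _Z95 * s[1])),
        converged=bool(converged[0]),
        ridged=ridged,
    )


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(raw_imputed: pd.DataFrame, labels: np.ndarray | pd.Series) -> pd.DataFrame:
    """Per-metabolite ratio of group medians: median(minority)/median(majority).

    Computed on the untransformed (imputed) matrix; direction is "down" when
    the ratio is below 1. A zero majority median yields NaN with a flag.
    """
    y = np.asarray(labels)
    num = raw_imputed.loc[y == 1].median(axis=0)
    den = raw_imputed.loc[y == 0].median(axis=0)
    fc = num / den.replace(0, np.nan)
    return pd.DataFrame(
        {
            "fold_change": fc,
            "direction": np.where(fc < 1, "down", "up"),
            "fc_undefined": den == 0,
        }
    )


def repeated_association(
    cohort: CohortMatrix,
    params: SmoteParams | None = None,
    n_resamples: int = 1000,
    fdr_alpha: float = 0.05,
    adjust_sex: bool = True,
) -> pd.DataFrame:
    """Median-aggregated SMOTE-logistic association table for every metabolite.

    For each of ``n_resamples`` independent SMOTE resamples, every metabolite
    is fitted with the logistic model (adjusted for sex); p-values, slopes
    and CI bounds are aggregated by their medians across converged fits, and
    BH-FDR is applied to the median p-values.
    """
    if params is None:
        params = SmoteParams()
    if "scale" not in cohort.state:
        raise ValueError("cohort must be fully processed (log + Pareto scaled)")
    X = cohort.abundances.to_numpy(dtype=float)
    y = cohort.group_indicator()
    sex = cohort.sample_meta["sex"].to_numpy(dtype=float) if adjust_sex else None

    mets = cohort.abundances.columns
    B = len(mets)
    p_all = np.empty((n_resamples, B))
    b_all = np.empty((n_resamples, B))
    lo_all = np.empty((n_resamples, B))
    hi_all = np.empty((n_resamples, B))
    ok_all = np.empty((n_resamples, B), dtype=bool)
    for r, res in enumerate(resample_stream(X, y, params, n_resamples, covariates=sex)):
        fits = fit_logistic_batch(res.y, res.X, res.covariates if adjust_sex else None)
        p_all[r] = fits["p"].to_numpy()
        b_all[r] = fits["beta1"].to_numpy()
        lo_all[r] = np.log(fits["or_ci_low"].to_numpy())
        hi_all[r] = np.log(fits["or_ci_high"].to_numpy())
        ok_all[r] = fits["converged"].to_numpy()

    with np.errstate(invalid="ignore"):
        masked = lambda a: np.where(ok_all, a, np.nan)  # noqa: E731
        p_med = np.nanmedian(masked(p_all), axis=0)
        b_med = np.nanmedian(masked(b_all), axis=0)
        lo_med = np.nanmedian(masked(lo_all), axis=0)
        hi_med = np.nanmedian(masked(hi_all), axis=0)
    n_conv = ok_all.sum(axis=0)

    table = pd.DataFrame(
        {
            "beta1": b_med,
            "or_point": np.exp(b_med),
            "or_ci_low": np.exp(lo_med),
            "or_ci_high": np.exp(hi_med),
            "p_median": p_med,
            "n_converged": n_conv,
        },
        index=mets,
    )
    # metabolites with no converged fit are excluded from the FDR family
    in_family = n_conv > 0
    q = np.full(B, np.nan)
    if in_family.any():
        q[in_family] = bh_fdr(p_med[in_family])
    table["q_fdr"] = q
    table["significant"] = table["q_fdr"] < fdr_alpha

    if cohort.untransformed is not None:
        fc = fold_change(cohort.untransformed, y)
        table = table.join(fc)
    if "sub_pathway" in cohort.metabolite_meta:
        table["sub_pathway"] = cohort.metabolite_meta["sub_pathway"]
    return table


def validate_linear(
    cohort2: CohortMatrix,
    outcome: str,
    discovery_hits: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Cross-cohort validation: OLS of a continuous cortisol outcome on each
    metabolite, adjusted for sex and age.

    Metabolites with unadjusted p < `alpha` are "potentially associated";
    the overlap report intersects them with the discovery hits by shared id.
    """
    meta = cohort2.sample_meta
    if outcome not in meta:
        raise ValueError(f"outcome column {outcome!r} not in sample metadata")
    yv = meta[outcome].to_numpy(dtype=float)
    sex = meta["sex"].to_numpy(dtype=float)
    age = meta["age"].to_numpy(dtype=float)
    n = len(yv)
    k = 4  # intercept + metabolite + sex + age
    if n <= k:
        raise ValueError(f"need more than {k} samples for the adjusted linear model")

    ab = cohort2.abundances
    rows = []
    for mid in ab.columns:
        x = np.column_stack([np.ones(n), ab[mid].to_numpy(dtype=float), sex, age])
        coef, *_ = np.linalg.lstsq(x, yv, rcond=None)
        resid = yv - x @ coef
        dof = n - k
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.pinv(x.T @ x)
        se = np.sqrt(max(cov[1, 1], 0))
        t = coef[1] / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), dof)
        rows.append((mid, coef[1], se, p))
    table = pd.DataFrame(rows, columns=["metabolite_id", "slope", "se", "p"]).set_index(
        "metabolite_id"
    )
    table["potentially_associated"] = table["p"] < alpha

    overlap: dict = {"outcome": outcome, "n_validation_hits": int(table["potentially_associated"].sum())}
    if discovery_hits is not None:
        shared = [m for m in discovery_hits if m in table.index]
        validated = [m for m in shared if table.loc[m, "p"] < alpha]
        overlap.update(
            n_discovery_hits=len(discovery_hits),
            n_shared_ids=len(shared),
            validated=validated,
            n_validated=len(validated),
        )
    return table, overlap
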