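"""Quality control and normalization of the abundance matrix.

The pipeline mirrors standard urine-metabolomics practice: keep metabolites
measured in over 70% of samples, drop xenobiotics and partially
characterized molecules, impute missing values with half the per-metabolite
observed minimum, normalize by sample osmolality then per-metabolite median,
natural-log transform and Pareto scale. The imputed, untransformed matrix is
retained on the cohort (``untransformed``) because fold changes are ratios
of group medians on that scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import CohortMatrix, QcReport

#: default: keep metabolites observed in strictly more than 70% of samples
DEFAULT_MIN_PRESENT = 0.70
#: peak plasma cortisol dichotomization cutoff, nmol/L
DEFAULT_CUTOFF = 350.0


def filter_missingness(
    m: CohortMatrix, min_present: float = DEFAULT_MIN_PRESENT
) -> tuple[CohortMatrix, QcReport]:
    """Keep metabolites whose non-missing fraction is strictly above `min_present`."""
    if not (0 < min_present <= 1):
        raise ValueError("min_present must be in (0, 1]")
    if m.abundances.size == 0:
        raise ValueError("empty abundance matrix")
    present = m.abundances.notna().mean(axis=0)
    keep = present > min_present
    report = QcReport(
        n_input=m.n_metabolites,
        n_kept_missingness=int(keep.sum()),
        n_final=int(keep.sum()),
        missing_fraction=1.0 - present,
    )
    out = m.with_transform("filter", m.abundances.loc[:, keep])
    return out, report


def drop_flagged(m: CohortMatrix, report: QcReport | None = None) -> tuple[CohortMatrix, QcReport]:
    """Drop xenobiotics and partially characterized metabolites.

    A metabolite carrying both flags is counted once, under xenobiotic.
    """
    meta = m.metabolite_meta
    xeno = meta.get("is_xenobiotic", pd.Series(False, index=meta.index)).astype(bool)
    partial = meta.get("is_partially_characterized", pd.Series(False, index=meta.index)).astype(bool)
    keep = ~(xeno | partial)
    if report is None:
        report = QcReport(n_input=m.n_metabolites, n_kept_missingness=m.n_metabolites)
    report.n_removed_xenobiotic = int(xeno.sum())
    report.n_removed_partial = int((partial & ~xeno).sum())
    report.n_final = int(keep.sum())
    report.validate()
    kept = m.abundances.loc[:, keep]
    # not a numbered transform: flag removal may happen alongside the filter
    out = CohortMatrix(
        abundances=kept,
        sample_meta=m.sample_meta,
        metabolite_meta=meta.loc[kept.columns],
        state=list(m.state),
        untransformed=None if m.untransformed is None else m.untransformed.loc[:, kept.columns],
    )
    return out, report


def impute_half_min(m: CohortMatrix) -> CohortMatrix:
    """Replace each missing entry with half the metabolite's observed minimum."""
    ab = m.abundances
    n_obs = ab.notna().sum(axis=0)
    if (n_obs == 0).any():
        bad = list(ab.columns[n_obs == 0])
        raise ValueError(f"cannot impute metabolites with no observed values: {bad}")
    fill = ab.min(axis=0, skipna=True) / 2.0
    imputed = ab.fillna(fill)
    return m.with_transform("impute", imputed, untransformed=imputed)


def normalize(m: CohortMatrix) -> CohortMatrix:
    """Divide each sample by its osmolality, then each metabolite by its median.

    After this step every metabolite has cohort median 1.
    """
    if "osmolality" not in m.sample_meta:
        raise ValueError("sample metadata lacks an 'osmolality' column")
    osmo = m.sample_meta["osmolality"].to_numpy(dtype=float)
    if np.any(~np.isfinite(osmo)) or np.any(osmo <= 0):
        raise ValueError("osmolality must be positive and finite for every sample")
    ab = m.abundances.div(osmo, axis=0)
    med = ab.median(axis=0)
    if (med == 0).any():
        bad = list(ab.columns[med == 0])
        raise ValueError(f"zero median after osmolality normalization: {bad}")
    ab = ab.div(med, axis=1)
    return m.with_transform("normalize", ab, untransformed=ab)


def log_pareto(m: CohortMatrix, drop_zero_variance: bool = True) -> CohortMatrix:
    """Natural-log transform then Pareto scale (center, divide by sqrt(SD)).

    Zero-variance columns cannot be Pareto scaled; they are dropped with a
    warning (configurable to raise instead).
    """
    vals = m.abundances.to_numpy(dtype=float)
    if np.any(~(vals > 0)):
        raise ValueError("log transform requires strictly positive abundances")
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        cols = list(m.abundances.columns[zero_var])
        if not drop_zero_variance:
            raise ValueError(f"zero-variance columns at Pareto scaling: {cols}")
        warnings.warn(f"dropping {len(cols)} zero-variance column(s) at Pareto scaling: {cols[:5]}")
    scaled = (logged - logged.mean(axis=0)) / np.sqrt(np.where(zero_var, 1.0, sd))
    out = pd.DataFrame(scaled, index=m.abundances.index, columns=m.abundances.columns)
    out = out.loc[:, ~zero_var]
    interim = m.with_transform("log", out)
    return interim.with_transform("scale", interim.abundances)


def iqr_check(m: CohortMatrix) -> QcReport:
    """Flag metabolites with non-positive interquartile range (type-7 quantiles)."""
    vals = m.abundances.to_numpy(dtype=float)
    q75, q25 = np.nanpercentile(vals, [75, 25], axis=0)
    iqr = pd.Series(q75 - q25, index=m.abundances.columns, name="iqr")
    return QcReport(
        n_input=m.n_metabolites,
        n_kept_missingness=m.n_metabolites,
        n_final=m.n_metabolites,
        iqr=iqr,
        flagged_zero_iqr=list(iqr.index[iqr <= 0]),
    )


def dichotomize(cortisol: pd.Series | np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> pd.Series:
    """Label samples insufficient (cortisol <= cutoff) vs sufficient (> cutoff).

    Missing cortisol yields a missing label, with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    s = pd.Series(cortisol, dtype=float)
    labels = pd.Series(
        np.where(s <= cutoff, "insufficient", "sufficient"), index=s.index, dtype=object
    )
    if s.isna().any():
        warnings.warn(f"{int(s.isna().sum())} sample(s) lack cortisol; left unlabeled")
        labels[s.isna()] = pd.NA
    return labels


def run_qc(
    m: CohortMatrix,
    min_present: float = DEFAULT_MIN_PRESENT,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[CohortMatrix, QcReport]:
    """Full preprocessing chain: filter, drop flags, impute, normalize, log+Pareto.

    If the cohort carries continuous cortisol but no group labels, labels are
    derived by thresholding at `cutoff`.
    """
    if "group" not in m.sample_meta and "cortisol" in m.sample_meta:
        m = CohortMatrix(
            abundances=m.abundances,
            sample_meta=m.sample_meta.assign(group=dichotomize(m.sample_meta["cortisol"], cutoff)),
            metabolite_meta=m.metabolite_meta,
            state=list(m.state),
            untransformed=m.untransformed,
        )
    filtered, report = filter_missingness(m, min_present)
    flagged, report = drop_flagged(filtered, report)
    imputed = impute_half_min(flagged)
    normed = normalize(imputed)
    processed = log_pareto(normed)
    final = iqr_check(processed)
    report.iqr = final.iqr
    report.flagged_zero_iqr = final.flagged_zero_iqr
    report.n_final = processed.n_metabolites
    return processed, report
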