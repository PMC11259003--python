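"""Core data container for a metabolomics cohort.

A :class:`CohortMatrix` bundles the sample-by-metabolite abundance matrix
with the per-sample metadata (group / cortisol / sex / age / osmolality),
the per-metabolite annotations (pathway labels, exclusion flags, optional
fingerprints) and an ordered record of the preprocessing transforms that
have been applied. The record enforces the legal transform order

    filter -> impute -> normalize -> log -> scale

and rejects re-application of a transform, so downstream stages can assert
the processing state they require.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: legal preprocessing steps, in order
TRANSFORM_ORDER = ("filter", "impute", "normalize", "log", "scale")

# metadata columns a cohort may carry; only those present are written/read
SAMPLE_META_COLUMNS = ("group", "cortisol", "sex", "age", "osmolality")
METABOLITE_META_COLUMNS = (
    "name",
    "super_pathway",
    "sub_pathway",
    "kegg_id",
    "hmdb_id",
    "smiles",
    "fingerprint",
    "is_xenobiotic",
    "is_partially_characterized",
)


class StateError(ValueError):
    """Raised when a preprocessing transform is applied out of order or twice."""


@dataclass
class CohortMatrix:
    """Sample x metabolite abundances plus metadata and processing state.

    Parameters
    ----------
    abundances
        DataFrame, samples in rows, metabolites in columns. Missing values
        are ``NaN``. Non-negative before the log transform.
    sample_meta
        DataFrame indexed like ``abundances`` rows.
    metabolite_meta
        DataFrame indexed like ``abundances`` columns.
    state
        Ordered list of applied transforms (subset of ``TRANSFORM_ORDER``).
    untransformed
        Snapshot of the imputed (and normalized) matrix before the log
        transform; fold changes are computed from this matrix.
    """

    abundances: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame
    state: list[str] = field(default_factory=list)
    untransformed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.abundances.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.abundances.columns.has_duplicates:
            raise ValueError("metabolite ids must be unique")
        if not self.abundances.index.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match abundance rows")
        if not self.abundances.columns.equals(self.metabolite_meta.index):
            raise ValueError("metabolite_meta index must match abundance columns")
        if "log" not in self.state:
            vals = self.abundances.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative abundances before log transform")

    # -- state bookkeeping -------------------------------------------------
    def check_transform(self, name: str) -> None:
        """Validate that transform `name` may legally be applied next."""
        if name not in TRANSFORM_ORDER:
            raise StateError(f"unknown transform {name!r}")
        if name in self.state:
            raise StateError(f"transform {name!r} already applied")
        pos = TRANSFORM_ORDER.index(name)
        for applied in self.state:
            if TRANSFORM_ORDER.index(applied) > pos:
                raise StateError(
                    f"transform {name!r} must precede {applied!r} (state={self.state})"
                )

    def with_transform(
        self,
        name: str,
        abundances: pd.DataFrame,
        metabolite_meta: pd.DataFrame | None = None,
        untransformed: pd.DataFrame | None = None,
    ) -> "CohortMatrix":
        """Return a new cohort with `name` appended to the state log."""
        self.check_transform(name)
        meta = self.metabolite_meta if metabolite_meta is None else metabolite_meta
        snap = self.untransformed if untransformed is None else untransformed
        if snap is not None:
            snap = snap.loc[:, snap.columns.intersection(abundances.columns)]
        return CohortMatrix(
            abundances=abundances,
            sample_meta=self.sample_meta,
            metabolite_meta=meta.loc[abundances.columns],
            state=self.state + [name],
            untransformed=snap,
        )

    # -- convenience accessors ---------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.abundances.shape[1]

    def group_indicator(self, minority_label: str = "insufficient") -> np.ndarray:
        """Binary outcome vector: 1 for the minority (insufficient) group."""
        if "group" not in self.sample_meta:
            raise KeyError("cohort has no 'group' column; dichotomize cortisol first")
        return (self.sample_meta["group"] == minority_label).to_numpy(dtype=int)

    # -- I/O -----------------------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
        """Write abundances / sample metadata / annotations / state as TSV+JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "abundances": outdir / f"{prefix}_abundances.tsv",
            "sample_meta": outdir / f"{prefix}_samples.tsv",
            "metabolite_meta": outdir / f"{prefix}_metabolites.tsv",
            "state": outdir / f"{prefix}_state.json",
        }
        self.abundances.to_csv(paths["abundances"], sep="\t", index_label="sample_id")
        self.sample_meta.to_csv(paths["sample_meta"], sep="\t", index_label="sample_id")
        self.metabolite_meta.to_csv(
            paths["metabolite_meta"], sep="\t", index_label="metabolite_id"
        )
        paths["state"].write_text(json.dumps({"state": self.state}) + "\n")
        if self.untransformed is not None:
            p = outdir / f"{prefix}_untransformed.tsv"
            self.untransformed.to_csv(p, sep="\t", index_label="sample_id")
            paths["untransformed"] = p
        return paths


#: missing-value markers accepted by the TSV readers
NA_VALUES = ["", "NA", "NaN", "nan", "N/A"]


def read_cohort(
    matrix_path: str | Path,
    sample_meta_path: str | Path,
    metabolite_meta_path: str | Path,
    na_values: list[str] | None = None,
) -> CohortMatrix:
    """Read a cohort from three TSV/CSV files (delimiter sniffed from suffix)."""
    na = NA_VALUES if na_values is None else na_values

    def _read(path: str | Path, index_col: str) -> pd.DataFrame:
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, na_values=na, keep_default_na=False)
        if index_col not in df.columns:
            raise ValueError(f"{path}: missing required column {index_col!r}")
        return df.set_index(index_col)

    abundances = _read(matrix_path, "sample_id").astype(float)
    sample_meta = _read(sample_meta_path, "sample_id")
    metabolite_meta = _read(metabolite_meta_path, "metabolite_id")
    for flag in ("is_xenobiotic", "is_partially_characterized"):
        if flag in metabolite_meta:
            metabolite_meta[flag] = metabolite_meta[flag].astype(bool)
    return CohortMatrix(
        abundances=abundances,
        sample_meta=sample_meta.loc[abundances.index],
        metabolite_meta=metabolite_meta.loc[abundances.columns],
    )


@dataclass
class QcReport:
    """Bookkeeping of the QC funnel plus per-metabolite diagnostics."""

    n_input: int = 0
    n_kept_missingness: int = 0
    n_removed_xenobiotic: int = 0
    n_removed_partial: int = 0
    n_final: int = 0
    missing_fraction: pd.Series | None = None
    iqr: pd.Series | None = None
    flagged_zero_iqr: list[str] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)

    def validate(self) -> None:
        expected = (
            self.n_kept_missingness
            - self.n_removed_xenobiotic
            - self.n_removed_partial
        )
        if self.n_final != expected:
            raise ValueError(
                f"inconsistent QC bookkeeping: n_final={self.n_final}, expected {expected}"
            )

    def to_json(self) -> str:
        d = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if not isinstance(v, pd.Series)
        }
        d.pop("missing_fraction", None)
        d.pop("iqr", None)
        return json.dumps(d, indent=2, default=str)

    def write(self, outdir: str | Path, prefix: str = "qc") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{prefix}_report.json").write_text(self.to_json() + "\n")
        per_met = pd.DataFrame(
            {
                "missing_fraction": self.missing_fraction,
                "iqr": self.iqr,
            }
        )
        per_met.to_csv(outdir / f"{prefix}_per_metabolite.tsv", sep="\t", index_label="metabolite_id")
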