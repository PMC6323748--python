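"""Readers, normalization and probe-to-gene aggregation for expression/CNV data.

All matrices are plain tab-separated text: first column ``gene_id``, remaining
columns sample identifiers, ``NA`` for missing, ``.`` decimal.  Tumor/normal
status comes from a required two-column sample sheet and is never inferred
from sample names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "read_clinical",
    "write_clinical",
    "quantile_normalize",
    "aggregate_probes",
    "log_median_center",
    "cnv_gene_level",
]

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression (or copy-number) matrix with sample classes.

    ``data`` is genes x samples with unique gene ids as the index;
    ``sample_class`` maps every sample id to "tumor" or "normal".
    """

    data: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dupes[:5]}")
        self.sample_class = self.sample_class.reindex(self.data.columns)
        if self.sample_class.isna().any():
            missing = self.sample_class.index[self.sample_class.isna()].tolist()
            raise ValueError(f"samples without a class label: {missing[:5]}")
        bad = set(self.sample_class.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"sample classes must be tumor/normal, got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def tumor(self) -> pd.DataFrame:
        return self.data.loc[:, self.sample_class == TUMOR]

    @property
    def normal(self) -> pd.DataFrame:
        return self.data.loc[:, self.sample_class == NORMAL]

    def with_data(self, data: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, sample_class=self.sample_class.reindex(data.columns))


@dataclass
class ClinicalTable:
    """Per-sample survival time (years), event indicator, grade and covariates."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        required = {"time_years", "event"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        t = self.table["time_years"]
        if (t.dropna() < 0).any():
            raise ValueError("survival times must be >= 0")
        ev = self.table["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        if "grade" in self.table.columns:
            g = self.table["grade"].dropna()
            if not g.isin([1, 2, 3]).all():
                raise ValueError("grade must be in {1, 2, 3} when present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# TSV dialect readers/writers


def read_sample_sheet(path) -> pd.Series:
    """Two-column TSV (sample_id, class) -> Series sample_id -> tumor/normal."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise ValueError(f"sample sheet {path}: missing column {col!r}")
    return df.set_index("sample_id")["class"]


def read_expression(path, sample_sheet) -> ExpressionMatrix:
    """Read a gene-by-sample TSV plus its sample sheet."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col="gene_id")
    classes = sample_sheet if isinstance(sample_sheet, pd.Series) else read_sample_sheet(sample_sheet)
    return ExpressionMatrix(data=df.astype(float), sample_class=classes)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def write_sample_sheet(sample_class: pd.Series, path) -> None:
    df = sample_class.rename("class").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col="sample_id")
    return ClinicalTable(table=df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Normalization and aggregation


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean-of-sorted-columns reference.

    After normalization all columns share the identical sorted value multiset.
    Ties within a column receive the mean of the reference values across the
    tied rank range (midrank convention).
    """
    values = matrix.data.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("quantile normalization undefined for fewer than 2 samples")
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires complete data (drop or impute NA first)")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # midrank ties: tied values share the mean reference over their range
        s = pd.Series(assigned).groupby(col, sort=False).transform("mean")
        out[:, j] = s.to_numpy()
    return matrix.with_data(pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns))


def aggregate_probes(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
    stat: Literal["mean", "median", "max"] = "mean",
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene; unmapped probes are dropped."""
    if stat not in ("mean", "median", "max"):
        raise ValueError(f"unknown aggregation statistic {stat!r}")
    if not probe_to_gene:
        warnings.warn("empty probe-to-gene mapping: result has no rows")
        empty = probe_matrix.data.iloc[:0].copy()
        empty.index.name = "gene_id"
        return probe_matrix.with_data(empty)
    genes = probe_matrix.data.index.map(lambda p: probe_to_gene.get(p))
    keep = genes.notna()
    df = probe_matrix.data.loc[keep]
    grouped = df.groupby(genes[keep].to_numpy(), sort=False).agg(stat)
    grouped.index.name = "gene_id"
    return probe_matrix.with_data(grouped)


def log_median_center(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    axis: Literal["gene", "sample"] = "gene",
) -> ExpressionMatrix:
    """log2(x + pseudocount) then subtract the per-gene (or per-sample) median."""
    values = matrix.data.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("log transform requires non-negative values")
    logged = np.log2(values + pseudocount)
    if axis == "gene":
        centered = logged - np.nanmedian(logged, axis=1, keepdims=True)
    elif axis == "sample":
        centered = logged - np.nanmedian(logged, axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown centering axis {axis!r}")
    return matrix.with_data(
        pd.DataFrame(centered, index=matrix.data.index, columns=matrix.data.columns)
    )


def cnv_gene_level(probe_cnv: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Gene-level copy number as the mean of the probes covering each gene."""
    return aggregate_probes(probe_cnv, probe_to_gene, stat="mean")
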