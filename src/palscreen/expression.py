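"""Expression and clinical data model, count normalization, case-to-normal ratios.

RNA-seq cohorts arrive as raw gene × sample count matrices and are
normalized with median-of-ratios size factors (the estimator DESeq2 uses):
each sample's factor is the median, over genes expressed in every sample, of
that sample's count divided by the gene's geometric mean across samples.

Case-to-normal ratios (CNR) divide a tumor sample's normalized expression by
the geometric mean over a control group of normal samples from the same
anatomical site; a pseudocount keeps the ratio finite for zero counts.
Label-based proteomic data instead arrive as gene-level log-ratios, and the
CNR of a tumor sample is its ratio to the average normal profile on the
linear scale of the input's log base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, NormalizationError

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "CNRMatrix",
    "median_of_ratios_normalize",
    "case_to_normal_ratios",
    "proteomic_ratios_to_cnr",
    "read_expression_table",
    "write_expression_table",
]

MODE_RNA = "rna_counts"
MODE_PROTEOMIC = "proteomic_log_ratio"


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with an explicit assay mode.

    ``rna_counts`` values are non-negative raw or normalized counts;
    ``proteomic_log_ratio`` values are signed gene-level log-ratios (NaN
    allowed for missing quantifications).
    """

    values: pd.DataFrame
    mode: str = MODE_RNA

    def __post_init__(self) -> None:
        if self.mode not in (MODE_RNA, MODE_PROTEOMIC):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates:
            raise FormatError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        if self.mode == MODE_RNA:
            arr = self.values.to_numpy()
            if np.isnan(arr).any() or (arr < 0).any():
                raise FormatError("rna_counts mode requires finite non-negative values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.mode)


_CLINICAL_COLS = ["cancer_type", "tissue", "os_time", "os_event", "pfs_time", "pfs_event"]


@dataclass
class ClinicalTable:
    """Per-sample annotations: cancer type, tumor/normal flag, survival endpoints.

    Indexed by sample id.  ``os_time``/``pfs_time`` are days (NaN when
    missing); events are 1 (occurred) / 0 (censored) / NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CLINICAL_COLS if c not in self.data.columns]
        if missing:
            raise FormatError(f"clinical table missing columns {missing}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in clinical table")
        bad_tissue = set(self.data["tissue"]) - {"tumor", "normal"}
        if bad_tissue:
            raise FormatError(f"tissue must be 'tumor' or 'normal', got {sorted(bad_tissue)}")
        for prefix in ("os", "pfs"):
            t, e = self.data[f"{prefix}_time"], self.data[f"{prefix}_event"]
            if (e.notna() & t.isna()).any():
                raise FormatError(f"{prefix}_event given without {prefix}_time")
            if (t.dropna() < 0).any():
                raise FormatError(f"negative {prefix}_time")
            if not set(e.dropna().unique()) <= {0, 1}:
                raise FormatError(f"{prefix}_event must be 0/1")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def cancer_types(self) -> list[str]:
        return sorted(self.data["cancer_type"].unique())

    def tumor_samples(self, cancer_type: str | None = None) -> pd.Index:
        mask = self.data["tissue"] == "tumor"
        if cancer_type is not None:
            mask &= self.data["cancer_type"] == cancer_type
        return self.data.index[mask]

    def normal_samples(self, cancer_type: str | None = None) -> pd.Index:
        mask = self.data["tissue"] == "normal"
        if cancer_type is not None:
            mask &= self.data["cancer_type"] == cancer_type
        return self.data.index[mask]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


@dataclass
class CNRMatrix:
    """Gene × tumor-sample case-to-normal ratios; entries strictly positive and finite."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr <= 0).any():
            raise ValueError("CNR entries must be strictly positive and finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def median_of_ratios_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios normalization of a raw count matrix.

    Reference genes are those with a nonzero count in every sample.  Each
    sample's size factor is the median over reference genes of
    ``count / geometric_mean_across_samples``; counts divide by their
    sample's factor.  Returns the normalized matrix and the factors.
    """
    if matrix.mode != MODE_RNA:
        raise ValueError("normalization applies to rna_counts matrices")
    counts = matrix.values
    if counts.shape[1] < 1 or counts.shape[0] < 1:
        raise NormalizationError("need at least one gene and one sample")
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError("no gene has nonzero counts in every sample")
    ref = counts.loc[usable]
    log_geo_mean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref).sub(log_geo_mean, axis=0)
    size_factors = np.exp(log_ratios.median(axis=0))
    size_factors.name = "size_factor"
    normalized = counts.div(size_factors, axis=1)
    return ExpressionMatrix(normalized, MODE_RNA), size_factors


def case_to_normal_ratios(
    tumor: ExpressionMatrix,
    controls: ExpressionMatrix,
    pseudocount: float = 1.0,
) -> CNRMatrix:
    """CNR of each tumor sample against the geometric mean of a control group.

    ``CNR_gene(sample) = (tumor + pc) / geomean_controls(control + pc)``,
    computed over the genes shared by both matrices.  Inputs should already
    be normalized.
    """
    if controls.values.shape[1] == 0:
        raise ValueError("control group is empty")
    common = tumor.genes.intersection(controls.genes)
    if len(common) == 0:
        raise ValueError("tumor and control matrices share no genes")
    t = tumor.values.loc[common] + pseudocount
    c = controls.values.loc[common] + pseudocount
    if (t.to_numpy() <= 0).any() or (c.to_numpy() <= 0).any():
        raise ValueError("values + pseudocount must be strictly positive")
    geo_mean = np.exp(np.log(c).mean(axis=1))
    return CNRMatrix(t.div(geo_mean, axis=0))


def proteomic_ratios_to_cnr(
    matrix: ExpressionMatrix,
    normal_samples,
    log_base: float = 2.0,
    min_normal_frac: float = 0.5,
) -> tuple[CNRMatrix, list[str]]:
    """Tumor / average-normal ratios from a gene-level log-ratio matrix.

    Per gene, subtract the mean log-ratio over normal samples and exponentiate
    in the input's log base, yielding the tumor-to-average-normal ratio on
    the linear scale.  Genes observed in fewer than ``min_normal_frac`` of
    the normals are dropped (returned as the second element); missing tumor
    values map to CNR 1 (no evidence of change).
    """
    if matrix.mode != MODE_PROTEOMIC:
        raise ValueError("expects a proteomic_log_ratio matrix")
    normal_samples = list(normal_samples)
    if not normal_samples:
        raise ValueError("normal sample set is empty")
    missing = [s for s in normal_samples if s not in matrix.samples]
    if missing:
        raise ValueError(f"normal samples not in matrix: {missing[:3]}")
    tumor_cols = [s for s in matrix.samples if s not in set(normal_samples)]
    normals = matrix.values[normal_samples]
    observed_frac = normals.notna().mean(axis=1)
    keep = observed_frac >= min_normal_frac
    dropped = list(matrix.genes[~keep])
    normal_mean = normals.loc[keep].mean(axis=1)
    log_cnr = matrix.values.loc[keep, tumor_cols].sub(normal_mean, axis=0)
    cnr = pd.DataFrame(
        np.power(float(log_base), log_cnr.fillna(0.0)),
        index=log_cnr.index,
        columns=log_cnr.columns,
    )
    return CNRMatrix(cnr), dropped


def read_expression_table(path, mode: str = MODE_RNA) -> ExpressionMatrix:
    """Read a TSV whose first column is the gene id and remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, mode)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
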