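"""Cancer-type-specific and tumor-vs-normal biomarker screening.

Every analyte — a gene's expression level or a pathway's activation level —
is scored in a two-group contrast with the Mann–Whitney AUC (fraction of
(target, rest) sample pairs in which the target sample scores higher, ties
counting one half) and a two-sided rank test p-value.  p-values are
Benjamini–Hochberg adjusted within each (cancer type × analyte category ×
contrast) stratum, and an analyte is called a significant potential
biomarker when its orientation-resolved AUC exceeds 0.7 and its adjusted
p-value (q) falls below 0.05.

Orientation: significance uses max(AUC, 1 − AUC) so both over- and
under-expressed markers qualify; the raw directional AUC is reported
alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StratumError
from .expression import ClinicalTable

__all__ = [
    "auc_two_group",
    "rank_test_p",
    "bh_adjust",
    "screen_analytes",
    "screen_cancer_types",
    "screen_tumor_vs_normal",
    "AUC_THRESHOLD",
    "Q_THRESHOLD",
]

AUC_THRESHOLD = 0.7
Q_THRESHOLD = 0.05

CONTRAST_TYPE = "cancer_type_one_vs_rest"
CONTRAST_TUMOR = "tumor_vs_normal"


def auc_two_group(values, is_target) -> float:
    """Directional Mann–Whitney AUC: P(target sample > rest sample), ties 0.5.

    Computed from midranks, which is algebraically identical to exhaustive
    pair counting.
    """
    values = np.asarray(values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    n1 = int(is_target.sum())
    n0 = int((~is_target).sum())
    if n1 == 0 or n0 == 0:
        raise StratumError("both groups must be nonempty for AUC")
    ranks = stats.rankdata(values)
    u = ranks[is_target].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def rank_test_p(values, is_target, paired: bool = False) -> float:
    """Two-sided rank test p-value for a two-group comparison.

    Unpaired: Wilcoxon rank-sum (Mann–Whitney U), exact for small tie-free
    samples, normal approximation with tie correction otherwise.  Paired:
    Wilcoxon signed-rank on matched vectors (``values`` is then the
    target-group vector and ``is_target`` the matched-control vector).
    Degenerate inputs (all values identical, or all paired differences zero)
    return p = 1: no evidence either way.
    """
    if paired:
        x = np.asarray(values, dtype=float)
        y = np.asarray(is_target, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired test requires equal-length matched vectors")
        if np.all(x == y):
            return 1.0
        return float(stats.wilcoxon(x, y, zero_method="wilcox").pvalue)
    values = np.asarray(values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    x, y = values[is_target], values[~is_target]
    if len(x) == 0 or len(y) == 0:
        raise StratumError("both groups must be nonempty for the rank-sum test")
    if np.all(values == values[0]):
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_analytes(
    analyte_matrix: pd.DataFrame,
    is_target,
    category: str,
    contrast: str,
    cancer_type: str = "",
    auc_threshold: float = AUC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    paired: bool = False,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Screen every row of an analyte × sample matrix in one two-group stratum.

    Returns a frame with columns ``analyte, category, contrast, cancer_type,
    auc_raw, auc_oriented, p, q, significant``; q is BH-adjusted across all
    analytes of this stratum.
    """
    is_target = np.asarray(is_target, dtype=bool)
    if len(is_target) != analyte_matrix.shape[1]:
        raise ValueError("is_target length must match the number of samples")
    n1, n0 = int(is_target.sum()), int((~is_target).sum())
    if n1 < min_group_size or n0 < min_group_size:
        raise StratumError(
            f"stratum ({contrast}, {cancer_type or 'all'}, {category}): "
            f"group sizes {n1}/{n0} below minimum {min_group_size}"
        )
    if analyte_matrix.shape[0] == 0:
        return pd.DataFrame(
            columns=[
                "analyte", "category", "contrast", "cancer_type",
                "auc_raw", "auc_oriented", "p", "q", "significant",
            ]
        )

    vals = analyte_matrix.to_numpy(dtype=float)
    # midrank AUC for all analytes at once
    ranks = stats.rankdata(vals, axis=1)
    u = ranks[:, is_target].sum(axis=1) - n1 * (n1 + 1) / 2
    auc_raw = u / (n1 * n0)

    pvals = np.empty(vals.shape[0])
    for i, row in enumerate(vals):
        if np.all(row == row[0]):
            pvals[i] = 1.0
            auc_raw[i] = 0.5
        elif paired:
            pvals[i] = rank_test_p(row[is_target], row[~is_target], paired=True)
        else:
            pvals[i] = float(
                stats.mannwhitneyu(row[is_target], row[~is_target], alternative="two-sided").pvalue
            )
    q = bh_adjust(pvals)
    auc_oriented = np.maximum(auc_raw, 1.0 - auc_raw)
    significant = (auc_oriented > auc_threshold) & (q < q_threshold)
    return pd.DataFrame(
        {
            "analyte": analyte_matrix.index,
            "category": category,
            "contrast": contrast,
            "cancer_type": cancer_type,
            "auc_raw": auc_raw,
            "auc_oriented": auc_oriented,
            "p": pvals,
            "q": q,
            "significant": significant,
        }
    ).reset_index(drop=True)


def screen_cancer_types(
    analyte_matrix: pd.DataFrame,
    clinical: ClinicalTable,
    category: str,
    cancer_types=None,
    **kwargs,
) -> pd.DataFrame:
    """One-vs-rest screen of every cancer type over the pooled tumor samples."""
    tumor = clinical.tumor_samples()
    cols = [s for s in analyte_matrix.columns if s in set(tumor)]
    sub = analyte_matrix[cols]
    labels = clinical.data.loc[cols, "cancer_type"]
    results = []
    for ct in cancer_types if cancer_types is not None else sorted(labels.unique()):
        results.append(
            screen_analytes(
                sub,
                (labels == ct).to_numpy(),
                category=category,
                contrast=CONTRAST_TYPE,
                cancer_type=ct,
                **kwargs,
            )
        )
    return pd.concat(results, ignore_index=True) if results else pd.DataFrame()


def screen_tumor_vs_normal(
    analyte_matrix: pd.DataFrame,
    clinical: ClinicalTable,
    category: str,
    cancer_types=None,
    **kwargs,
) -> pd.DataFrame:
    """Tumor vs matched-site normal screen, one stratum per cancer type."""
    results = []
    types = cancer_types if cancer_types is not None else clinical.cancer_types()
    for ct in types:
        samples = [
            s
            for s in analyte_matrix.columns
            if s in clinical.samples and clinical.data.loc[s, "cancer_type"] == ct
        ]
        if not samples:
            continue
        tissue = clinical.data.loc[samples, "tissue"]
        results.append(
            screen_analytes(
                analyte_matrix[samples],
                (tissue == "tumor").to_numpy(),
                category=category,
                contrast=CONTRAST_TUMOR,
                cancer_type=ct,
                **kwargs,
            )
        )
    return pd.concat(results, ignore_index=True) if results else pd.DataFrame()
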