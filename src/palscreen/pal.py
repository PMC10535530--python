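"""Pathway Activation Level (PAL) computation.

For a pathway *p* and one sample's per-gene case-to-normal ratios, the
activation level is the ARR-weighted mean of log ratios over the pathway
members measured by the assay:

    PAL_p = Σ_n log(CNR_n) · PG_p,n · ARR_p,n  /  Σ_n |ARR_p,n|

where PG_p,n is the membership indicator and ARR_p,n ∈ {−1, −0.5, 0, 0.5, 1}
is the member's activator/repressor role.  Both sums run over genes that are
in the pathway AND in the assay: members without expression data (including
metabolite and process nodes, which have none by construction) contribute to
neither numerator nor denominator.  Positive PAL means the pathway is
up-regulated in the case sample relative to the normal reference, negative
means down-regulated.

The log base (default 10) rescales PAL by a constant factor and therefore
never changes rank-based downstream statistics; it is recorded in the
matrix provenance so numeric outputs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedPALError
from .expression import CNRMatrix
from .pathways import Pathway

__all__ = ["PALMatrix", "compute_pal", "compute_pal_matrix", "write_pal_table"]


@dataclass
class PALMatrix:
    """Pathway × sample activation levels with provenance."""

    values: pd.DataFrame
    log_base: float = 10.0
    pathway_set_id: str = ""
    cnr_source_id: str = ""
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pathways(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def compute_pal(
    cnr_column: Mapping[str, float] | pd.Series,
    pathway: Pathway,
    log_base: float = 10.0,
) -> float:
    """Activation level of one pathway in one sample.

    ``cnr_column`` maps assay gene ids to strictly positive case-to-normal
    ratios.  Raises :class:`~palscreen.errors.UndefinedPALError` when no
    assay-covered member has a nonzero ARR (zero denominator).
    """
    if pathway.arr is None:
        raise ValueError(f"pathway {pathway.id!r} is not ARR-annotated")
    log_b = math.log(log_base)
    num = 0.0
    denom = 0.0
    for member in pathway.members:
        if member not in cnr_column:
            continue
        w = pathway.arr[member]
        num += math.log(cnr_column[member]) / log_b * w
        denom += abs(w)
    if denom == 0.0:
        raise UndefinedPALError(
            f"pathway {pathway.id!r}: no assay-covered member with nonzero ARR"
        )
    return num / denom


def compute_pal_matrix(
    cnr: CNRMatrix,
    pathways: Sequence[Pathway],
    log_base: float = 10.0,
    pathway_set_id: str = "",
) -> PALMatrix:
    """Vectorized PAL for every pathway over every sample of a CNR matrix.

    Pathways whose denominator is zero on this assay are excluded and listed
    in ``PALMatrix.excluded`` with a reason, mirroring the upstream
    uninformative-pathway filter.
    """
    gene_pos = {g: i for i, g in enumerate(cnr.genes)}
    log_cnr = np.log(cnr.values.to_numpy()) / math.log(log_base)

    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    excluded: list[tuple[str, str]] = []
    n_genes = len(gene_pos)
    for pw in pathways:
        if pw.arr is None:
            raise ValueError(f"pathway {pw.id!r} is not ARR-annotated")
        weights = np.zeros(n_genes)
        denom = 0.0
        for member in pw.members:
            idx = gene_pos.get(member)
            if idx is None:
                continue
            w = pw.arr[member]
            weights[idx] = w
            denom += abs(w)
        if denom == 0.0:
            excluded.append((pw.id, "no assay-covered member with nonzero ARR"))
            continue
        kept_ids.append(pw.id)
        rows.append(weights / denom)

    if rows:
        values = np.vstack(rows) @ log_cnr
    else:
        values = np.empty((0, len(cnr.samples)))
    frame = pd.DataFrame(values, index=pd.Index(kept_ids, name="pathway"), columns=cnr.samples)
    return PALMatrix(
        frame,
        log_base=log_base,
        pathway_set_id=pathway_set_id,
        excluded=excluded,
    )


def write_pal_table(pal: PALMatrix, path) -> None:
    """Export a PAL matrix as TSV with a provenance comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# log_base={pal.log_base} pathway_set={pal.pathway_set_id} "
            f"cnr_source={pal.cnr_source_id}\n"
        )
        pal.values.to_csv(fh, sep="\t", index_label="pathway")
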