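"""Gene-centric pathway construction and classical pathway ingestion.

A gene-centric pathway is the radius-1 neighborhood of a chosen central gene
in the interactome, with one extra inclusion step: whenever the neighborhood
contains a "process" node (a biochemical reaction or transport event), every
participant of that process joins the pathway as well.  Process expansion is
a single pass — participants that are themselves process nodes are added but
not expanded further — and the radius counts only non-process hops.

Classical pathways are curated gene sets read from GMT files, with
activator/repressor role (ARR) weights supplied by a sidecar table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import AnnotationStateError, FormatError
from .interactome import Interactome, NodeKind

__all__ = [
    "ALLOWED_ARR",
    "Pathway",
    "build_gene_centric_pathway",
    "expand_process_nodes",
    "build_all_gene_centric",
    "filter_uninformative",
    "read_classical_pathways",
    "write_pathways_table",
    "read_pathways_table",
]

#: The five admissible activator/repressor role values: full activator (+1),
#: full repressor (−1), probable activator/repressor (±0.5), unclear (0).
ALLOWED_ARR = frozenset({-1.0, -0.5, 0.0, 0.5, 1.0})


@dataclass(frozen=True)
class Pathway:
    """A pathway: member node ids with optional ARR weights.

    ``central_gene`` is set for gene-centric pathways and absent for
    classical (curated gene-set) pathways.  ``arr`` is ``None`` until the
    annotation stage runs; membership itself is the PG indicator (a gene is
    "in" the pathway iff it is in ``members``).
    """

    id: str
    members: tuple[str, ...]
    member_kind: Mapping[str, NodeKind] = field(default_factory=dict)
    central_gene: str | None = None
    arr: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"pathway {self.id!r}: duplicate members")
        if self.central_gene is not None and self.central_gene not in self.members:
            raise ValueError(f"pathway {self.id!r}: central gene not among members")
        if self.arr is not None:
            missing = [m for m in self.members if m not in self.arr]
            if missing:
                raise ValueError(f"pathway {self.id!r}: ARR missing for {missing[:3]}")
            bad = [v for v in self.arr.values() if v not in ALLOWED_ARR]
            if bad:
                raise FormatError(f"pathway {self.id!r}: ARR values {bad[:3]} outside {sorted(ALLOWED_ARR)}")
            if self.central_gene is not None and self.arr[self.central_gene] != 1.0:
                raise ValueError(f"pathway {self.id!r}: central gene ARR must be 1")

    @property
    def annotated(self) -> bool:
        return self.arr is not None

    @property
    def is_degenerate(self) -> bool:
        """True for a single-member pathway (isolated central gene)."""
        return len(self.members) == 1

    def with_arr(self, arr: Mapping[str, float]) -> "Pathway":
        return replace(self, arr=dict(arr))


def expand_process_nodes(graph: Interactome, members: set[str]) -> set[str]:
    """Add all participants of every process node already in *members*.

    Applied once, not recursively: a participant that is itself a process
    node joins the set but its own participants do not.
    """
    expanded = set(members)
    for m in members:
        if graph.node_kind(m) is NodeKind.PROCESS:
            expanded |= graph.direct_neighbors(m, "both")
    return expanded


def build_gene_centric_pathway(
    graph: Interactome,
    central_gene: str,
    direction: str = "both",
    radius: int = 1,
    pathway_id: str | None = None,
) -> Pathway:
    """Build the pathway centered at *central_gene* (members only, ARR unset).

    Members are every node within *radius* interactions of the central gene
    in the requested edge ``direction`` ("out", "in" or "both"), followed by
    one pass of process-node expansion.  Member order is lexicographic.
    """
    if graph.node_kind(central_gene) is not NodeKind.GENE_PRODUCT:
        raise TypeError(
            f"central node {central_gene!r} has kind "
            f"{graph.node_kind(central_gene).value}, expected gene_product"
        )
    if radius < 1:
        raise ValueError("radius must be a positive integer")
    members = {central_gene}
    frontier = {central_gene}
    for _ in range(radius):
        nxt: set[str] = set()
        for node in frontier:
            nxt |= graph.direct_neighbors(node, direction)
        frontier = nxt - members
        members |= nxt
        if not frontier:
            break
    members = expand_process_nodes(graph, members)
    return Pathway(
        id=pathway_id if pathway_id is not None else f"gcp_{central_gene}",
        members=tuple(sorted(members)),
        member_kind={m: graph.node_kind(m) for m in sorted(members)},
        central_gene=central_gene,
    )


def build_all_gene_centric(
    graph: Interactome, direction: str = "both", radius: int = 1
) -> list[Pathway]:
    """One gene-centric pathway per gene_product node, in sorted gene order."""
    return [
        build_gene_centric_pathway(graph, gene, direction=direction, radius=radius)
        for gene in sorted(graph.nodes(NodeKind.GENE_PRODUCT))
    ]


REASON_ALL_ZERO = "all-zero ARR"
REASON_NO_COVERAGE = "no expression coverage"


def filter_uninformative(
    pathways: Sequence[Pathway], assay_gene_universe: set[str]
) -> tuple[list[Pathway], list[tuple[Pathway, str]]]:
    """Drop pathways that cannot yield a defined activation level.

    A pathway is uninformative if every member's ARR is zero, or if no
    member with a nonzero ARR is present in the assay's gene universe (the
    activation-level denominator would be zero either way).  Returns
    ``(kept, excluded)`` where each exclusion carries a reason string.
    """
    kept: list[Pathway] = []
    excluded: list[tuple[Pathway, str]] = []
    for pw in pathways:
        if not pw.annotated:
            raise AnnotationStateError(f"pathway {pw.id!r} has no ARR annotation")
        nonzero = [m for m in pw.members if pw.arr[m] != 0.0]
        if not nonzero:
            excluded.append((pw, REASON_ALL_ZERO))
        elif not any(m in assay_gene_universe for m in nonzero):
            excluded.append((pw, REASON_NO_COVERAGE))
        else:
            kept.append(pw)
    return kept, excluded


def read_classical_pathways(gene_set_file, arr_sidecar_file) -> list[Pathway]:
    """Read curated pathways from a GMT file plus an ARR sidecar table.

    GMT lines are ``id <TAB> description <TAB> gene ...``; the sidecar is a
    TSV with columns ``pathway_id, gene, arr``.  Genes absent from the
    sidecar default to ARR 0; ARR values outside the five-value set raise
    :class:`~palscreen.errors.FormatError`.
    """
    arr_by_pathway: dict[str, dict[str, float]] = {}
    with open(arr_sidecar_file, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["pathway_id", "gene", "arr"]:
            raise FormatError(f"{arr_sidecar_file}: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            pwid, gene, arr_str = row
            try:
                val = float(arr_str)
            except ValueError:
                raise FormatError(f"{arr_sidecar_file}:{lineno}: non-numeric arr {arr_str!r}") from None
            if val not in ALLOWED_ARR:
                raise FormatError(
                    f"{arr_sidecar_file}:{lineno}: arr {val} outside {sorted(ALLOWED_ARR)}"
                )
            arr_by_pathway.setdefault(pwid, {})[gene] = val

    pathways: list[Pathway] = []
    with open(gene_set_file, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{gene_set_file}:{lineno}: GMT line needs id, description, ≥1 gene")
            pwid, _desc, *genes = parts
            genes = [g for g in genes if g]
            members = tuple(sorted(set(genes)))
            sidecar = arr_by_pathway.get(pwid, {})
            arr = {g: sidecar.get(g, 0.0) for g in members}
            pathways.append(
                Pathway(
                    id=pwid,
                    members=members,
                    member_kind={g: NodeKind.GENE_PRODUCT for g in members},
                    arr=arr,
                )
            )
    return pathways


_PW_HEADER = ["pathway_id", "central_gene", "member", "member_kind", "arr"]


def write_pathways_table(pathways: Iterable[Pathway], path) -> None:
    """Export pathways as a long-format TSV, one member per row."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PW_HEADER)
        for pw in pathways:
            for m in pw.members:
                kind = pw.member_kind.get(m, NodeKind.GENE_PRODUCT)
                arr = "" if pw.arr is None else repr(pw.arr[m])
                writer.writerow([pw.id, pw.central_gene or "", m, kind.value, arr])


def read_pathways_table(path) -> list[Pathway]:
    """Read pathways back from the long-format TSV written by :func:`write_pathways_table`."""
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _PW_HEADER:
            raise FormatError(f"{path}: bad header {header}")
        for row in reader:
            if not row or all(not c for c in row):
                continue
            pwid, central, member, kind, arr = row
            if pwid not in rows:
                rows[pwid] = {"central": central or None, "members": [], "kind": {}, "arr": {}}
                order.append(pwid)
            rec = rows[pwid]
            rec["members"].append(member)
            rec["kind"][member] = NodeKind(kind)
            if arr != "":
                rec["arr"][member] = float(arr)
    out: list[Pathway] = []
    for pwid in order:
        rec = rows[pwid]
        out.append(
            Pathway(
                id=pwid,
                members=tuple(rec["members"]),
                member_kind=rec["kind"],
                central_gene=rec["central"],
                arr=rec["arr"] if rec["arr"] else None,
            )
        )
    return out
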