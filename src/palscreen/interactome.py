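"""Signed, typed, directed interactome graph: data model, TSV I/O, merging.

The interactome is a directed graph whose nodes are gene products,
metabolites, or assistive "process" nodes (biochemical reactions and
transport events), and whose edges carry one of three interaction labels:
``activation``, ``inhibition``, or ``other``.  Parallel edges between the
same ordered pair of nodes are kept when (and only when) their interaction
labels differ — the source pathway databases can legitimately assert both an
activating and an inhibiting influence — while identical
(source, target, interaction) triples are collapsed to a single edge.
"""

from __future__ import annotations

import csv
import enum
from typing import Iterable, Iterator

import networkx as nx

from .errors import FormatError, NodeKindConflictError, NodeLookupError

__all__ = [
    "NodeKind",
    "Interaction",
    "Interactome",
    "parse_interactome_table",
    "write_interactome_table",
    "merge_pathway_collection",
]


class NodeKind(str, enum.Enum):
    GENE_PRODUCT = "gene_product"
    METABOLITE = "metabolite"
    PROCESS = "process"


class Interaction(str, enum.Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    OTHER = "other"


def _coerce_kind(value: "NodeKind | str") -> NodeKind:
    try:
        return NodeKind(value)
    except ValueError:
        raise FormatError(f"unknown node kind {value!r}") from None


def _coerce_interaction(value: "Interaction | str") -> Interaction:
    try:
        return Interaction(value)
    except ValueError:
        raise FormatError(f"unknown interaction label {value!r}") from None


class Interactome:
    """Directed multigraph over typed nodes with signed edges.

    Backed by a :class:`networkx.MultiDiGraph` whose edge keys are the
    interaction labels, so identical (source, target, interaction) triples
    deduplicate automatically while differently-labeled parallel edges
    coexist.  Node ids are case-sensitive opaque strings.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, kind: "NodeKind | str", label: str | None = None) -> None:
        kind = _coerce_kind(kind)
        if node_id in self._g:
            existing = self._g.nodes[node_id]["kind"]
            if existing != kind:
                raise NodeKindConflictError(
                    f"node {node_id!r} declared both {existing.value} and {kind.value}"
                )
            if label is not None:
                self._g.nodes[node_id]["label"] = label
        else:
            self._g.add_node(node_id, kind=kind, label=label if label is not None else node_id)

    def add_edge(self, source: str, target: str, interaction: "Interaction | str") -> None:
        interaction = _coerce_interaction(interaction)
        for nid in (source, target):
            if nid not in self._g:
                raise NodeLookupError(f"edge endpoint {nid!r} is not a declared node")
        # key == label: re-adding an identical triple is a no-op
        self._g.add_edge(source, target, key=interaction.value, interaction=interaction)

    # -- accessors -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self, kind: NodeKind | None = None) -> list[str]:
        if kind is None:
            return list(self._g.nodes)
        return [n for n, k in self._g.nodes(data="kind") if k == kind]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._g

    def node_kind(self, node_id: str) -> NodeKind:
        try:
            return self._g.nodes[node_id]["kind"]
        except KeyError:
            raise NodeLookupError(f"unknown node {node_id!r}") from None

    def node_label(self, node_id: str) -> str:
        try:
            return self._g.nodes[node_id]["label"]
        except KeyError:
            raise NodeLookupError(f"unknown node {node_id!r}") from None

    def edges(self) -> Iterator[tuple[str, str, Interaction]]:
        for u, v, k in self._g.edges(keys=True):
            yield u, v, Interaction(k)

    def edges_between(self, a: str, b: str) -> list[tuple[str, str, Interaction]]:
        """All edges connecting *a* and *b* in either direction."""
        pairs = ((a, b),) if a == b else ((a, b), (b, a))
        out: list[tuple[str, str, Interaction]] = []
        for u, v in pairs:
            if self._g.has_edge(u, v):
                for k in self._g[u][v]:
                    out.append((u, v, Interaction(k)))
        return out

    def direct_neighbors(self, node_id: str, direction: str = "both") -> set[str]:
        """Node ids one edge away from *node_id* in the requested direction.

        ``node_id`` itself appears in the result only if a self-loop exists.
        """
        if node_id not in self._g:
            raise NodeLookupError(f"unknown node {node_id!r}")
        if direction == "out":
            nbrs = set(self._g.successors(node_id))
        elif direction == "in":
            nbrs = set(self._g.predecessors(node_id))
        elif direction == "both":
            nbrs = set(self._g.successors(node_id)) | set(self._g.predecessors(node_id))
        else:
            raise ValueError(f"direction must be 'out', 'in' or 'both', got {direction!r}")
        if node_id in nbrs and not self._g.has_edge(node_id, node_id):
            nbrs.discard(node_id)
        return nbrs

    # -- equality ------------------------------------------------------

    def _node_table(self) -> dict[str, NodeKind]:
        return {n: k for n, k in self._g.nodes(data="kind")}

    def _edge_set(self) -> set[tuple[str, str, str]]:
        return {(u, v, k) for u, v, k in self._g.edges(keys=True)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self._node_table() == other._node_table() and self._edge_set() == other._edge_set()

    def __repr__(self) -> str:
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


_HEADER = ["source_id", "source_kind", "target_id", "target_kind", "interaction"]


def parse_interactome_table(path) -> Interactome:
    """Read an interactome from a tab-separated edge table.

    Expected columns: ``source_id, source_kind, target_id, target_kind,
    interaction``.  Duplicate identical rows collapse to one edge.  Rows with
    empty target fields declare an isolated node (needed so that write/parse
    round trips preserve nodes with no incident edges).
    """
    graph = Interactome()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected header {_HEADER}") from None
        if header != _HEADER:
            raise FormatError(f"{path}: bad header {header}, expected {_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            src, src_kind, tgt, tgt_kind, inter = row
            try:
                graph.add_node(src, src_kind)
                if tgt == "" and inter == "":
                    continue  # node-only declaration
                graph.add_node(tgt, tgt_kind)
                graph.add_edge(src, tgt, inter)
            except (FormatError, NodeKindConflictError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from None
    return graph


def write_interactome_table(graph: Interactome, path) -> None:
    """Write *graph* as a tab-separated edge table (round-trips with the parser).

    Rows are emitted in sorted order so identical graphs serialize
    byte-identically.  Isolated nodes become node-only rows.
    """
    rows = sorted((u, v, k.value) for u, v, k in graph.edges())
    touched = {u for u, v, _ in rows} | {v for _, v, _ in rows}
    isolated = sorted(n for n in graph.nodes() if n not in touched)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for u, v, inter in rows:
            writer.writerow([u, graph.node_kind(u).value, v, graph.node_kind(v).value, inter])
        for n in isolated:
            writer.writerow([n, graph.node_kind(n).value, "", "", ""])


def merge_pathway_collection(
    pathway_edge_sets: Iterable[tuple[Iterable[tuple], Iterable[tuple]]],
) -> Interactome:
    """Union many per-pathway (nodes, edges) sets into one interactome.

    ``nodes`` entries are ``(id, kind)`` or ``(id, kind, label)`` tuples;
    ``edges`` entries are ``(source, target, interaction)``.  Identical
    interaction triples occurring in several pathways merge into one edge;
    an id declared with conflicting kinds raises
    :class:`~palscreen.errors.NodeKindConflictError`.
    """
    graph = Interactome()
    for nodes, edges in pathway_edge_sets:
        for rec in nodes:
            graph.add_node(*rec)
        for src, tgt, inter in edges:
            graph.add_edge(src, tgt, inter)
    return graph
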