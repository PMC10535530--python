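"""Activator/repressor role (ARR) annotation by sign voting.

Each member of a gene-centric pathway is assigned a weight in
{−1, −0.5, 0, +0.5, +1} describing whether it activates or represses the
pathway as seen from the central gene.  Every edge connecting the member to
the central node — directly, or through a process node adjacent to the
central node — casts one vote: +1 for an activation edge, −1 for an
inhibition edge, 0 for an "other" edge.  A process hop itself contributes
sign +1 (the process relays but does not flip the influence).  Votes
aggregate as:

* all nonzero votes positive → +1; all negative → −1 (unanimity),
* strict majority positive/negative → +0.5 / −0.5,
* tie, no votes, or all-zero votes → 0.

The central gene always carries ARR +1.
"""

from __future__ import annotations

from typing import Iterable

from .interactome import Interaction, Interactome, NodeKind
from .pathways import Pathway

__all__ = ["edge_sign", "aggregate_votes", "member_votes", "annotate_gene_centric", "annotate_all"]

_SIGN = {Interaction.ACTIVATION: 1, Interaction.INHIBITION: -1, Interaction.OTHER: 0}


def edge_sign(interaction: Interaction | str) -> int:
    """+1 for activation, −1 for inhibition, 0 for 'other'."""
    return _SIGN[Interaction(interaction)]


def aggregate_votes(votes: Iterable[int]) -> float:
    """Collapse per-edge sign votes into one of the five ARR values."""
    pos = neg = 0
    for v in votes:
        if v > 0:
            pos += 1
        elif v < 0:
            neg += 1
    if pos == 0 and neg == 0:
        return 0.0
    if neg == 0:
        return 1.0
    if pos == 0:
        return -1.0
    if pos > neg:
        return 0.5
    if neg > pos:
        return -0.5
    return 0.0


def member_votes(pathway: Pathway, graph: Interactome, member: str) -> list[int]:
    """All sign votes cast for *member* from its links to the central node.

    One vote per edge (either direction) between the member and the central
    gene, plus one per edge between the member and any process node of the
    pathway adjacent to the central gene (the process hop relays sign +1).
    """
    central = pathway.central_gene
    votes = [edge_sign(inter) for _, _, inter in graph.edges_between(member, central)]
    for bridge in pathway.members:
        if bridge in (member, central):
            continue
        if pathway.member_kind.get(bridge, graph.node_kind(bridge)) is not NodeKind.PROCESS:
            continue
        if not graph.edges_between(bridge, central):
            continue
        votes.extend(edge_sign(inter) for _, _, inter in graph.edges_between(member, bridge))
    return votes


def annotate_gene_centric(pathway: Pathway, graph: Interactome) -> Pathway:
    """Return *pathway* with ARR set for every member.

    Members with no connecting edge to the central node (e.g. pure process
    participants whose process does not touch the center) get ARR 0 —
    unreachable is a neutral role, not an error.
    """
    if pathway.central_gene is None:
        raise ValueError(f"pathway {pathway.id!r} has no central gene; ARR voting needs one")
    arr: dict[str, float] = {}
    for m in pathway.members:
        if m == pathway.central_gene:
            arr[m] = 1.0
        else:
            arr[m] = aggregate_votes(member_votes(pathway, graph, m))
    return pathway.with_arr(arr)


def annotate_all(pathways: Iterable[Pathway], graph: Interactome) -> list[Pathway]:
    return [annotate_gene_centric(pw, graph) for pw in pathways]
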