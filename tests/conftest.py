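import numpy as np
import pytest

from palscreen.interactome import Interaction, Interactome, NodeKind

KINDS = [NodeKind.GENE_PRODUCT, NodeKind.METABOLITE, NodeKind.PROCESS]
LABELS = [Interaction.ACTIVATION, Interaction.INHIBITION, Interaction.OTHER]


def random_interactome(
    rng: np.random.Generator,
    n_nodes: int = 20,
    n_edges: int = 40,
    kind_probs=(0.6, 0.2, 0.2),
    allow_self_loops: bool = False,
) -> Interactome:
    """Small random typed graph for oracle comparisons."""
    g = Interactome()
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    for nid in ids:
        g.add_node(nid, KINDS[rng.choice(3, p=list(kind_probs))])
    for _ in range(n_edges):
        u, v = rng.choice(n_nodes, size=2, replace=False if not allow_self_loops else True)
        g.add_edge(ids[u], ids[v], LABELS[rng.choice(3)])
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_graph() -> Interactome:
    """X activates A, inhibits B; process P (adjacent to X) with participants A, C, M."""
    g = Interactome()
    for nid, kind in [
        ("X", NodeKind.GENE_PRODUCT),
        ("A", NodeKind.GENE_PRODUCT),
        ("B", NodeKind.GENE_PRODUCT),
        ("C", NodeKind.GENE_PRODUCT),
        ("M", NodeKind.METABOLITE),
        ("P", NodeKind.PROCESS),
        ("Z", NodeKind.GENE_PRODUCT),  # isolated
    ]:
        g.add_node(nid, kind)
    g.add_edge("X", "A", Interaction.ACTIVATION)
    g.add_edge("X", "B", Interaction.INHIBITION)
    g.add_edge("X", "P", Interaction.ACTIVATION)
    g.add_edge("P", "A", Interaction.ACTIVATION)
    g.add_edge("P", "C", Interaction.INHIBITION)
    g.add_edge("M", "P", Interaction.OTHER)
    return g
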