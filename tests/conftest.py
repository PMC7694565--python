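"""Shared fixtures: tiny SWC texts and small graphs built programmatically."""

import networkx as nx
import pytest

from excitree.morphology import SOMA, BASAL_DENDRITE, NeuronGraph


MINIMAL_SWC = """\
1 1 0 0 0 1 -1
2 3 0 1 0 0.5 1
3 3 0 2 0 0.5 2
"""

COMMENTED_SWC = (
    "# ORIGINAL_SOURCE NeuroMorpho.Org\n"
    "# some header line\n" + MINIMAL_SWC
)


@pytest.fixture
def minimal_swc() -> str:
    return MINIMAL_SWC


@pytest.fixture
def commented_swc() -> str:
    return COMMENTED_SWC


def chain_graph(n: int, soma_at: int = 1) -> NeuronGraph:
    """Path of n compartments with the soma at a chosen 1-based position."""
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    g.add_edges_from((i, i + 1) for i in range(1, n))
    labels = {i: BASAL_DENDRITE for i in range(1, n + 1)}
    labels[soma_at] = SOMA
    return NeuronGraph(graph=g, soma=soma_at, labels=labels)


def single_compartment() -> NeuronGraph:
    g = nx.Graph()
    g.add_node(1)
    return NeuronGraph(graph=g, soma=1, labels={1: SOMA})
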