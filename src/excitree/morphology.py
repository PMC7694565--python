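"""SWC morphology parsing and tree-topological metrics.

Digital reconstructions (NeuroMorpho-style SWC) are parsed into a validated
compartment tree in which every SWC sample point is one dynamical compartment.
Two normalisations are applied before any analysis:

* all soma-coded points (structure type 1) are contracted into a single soma
  node, because the soma is treated as one dynamical unit that may be
  connected to many branches;
* axon-coded points (structure type 2) are removed entirely -- the dynamics
  and the centrality measure concern the dendritic arbor only.

Distances along the tree are counted in edges on the unique connecting path,
so ``distance(i, i) == 0``.  The centrality of a compartment is its maximum
distance to any dendritic terminal, and the relative centrality of the soma
rescales that value to [0, 1] (1 = most central compartment of the neuron).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import sparse

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4


class SWCError(ValueError):
    """Malformed SWC content (bad record syntax or broken structure)."""


@dataclass(frozen=True)
class MorphologyPoint:
    """One SWC sample point.

    Attributes
    ----------
    id : int
        Sample identifier, unique within the file, > 0.
    structure_type : int
        SWC structure code: 1 soma, 2 axon, 3 basal dendrite, 4 apical
        dendrite; other codes are preserved and treated as dendrite-like.
    x, y, z : float
        Position in micrometres.
    radius : float
        Radius in micrometres, >= 0.
    parent_id : int
        Identifier of the parent sample, or -1 for a root.
    """

    id: int
    structure_type: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


@dataclass
class NeuronGraph:
    """Loop-free compartment tree with a designated soma node.

    The graph is undirected and acyclic; node identifiers are the SWC sample
    ids (the contracted soma keeps the id of the first soma point).  ``labels``
    maps each node to its SWC structure code.
    """

    graph: nx.Graph
    soma: int
    labels: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic structure ---------------------------------------------------

    @property
    def n_compartments(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def compartment_ids(self) -> list[int]:
        return list(self.graph.nodes)

    def degree(self, node: int) -> int:
        return self.graph.degree[node]

    def terminals(self) -> list[int]:
        """Dendritic endpoints: degree-1 nodes, excluding the soma."""
        return [v for v, d in self.graph.degree if d == 1 and v != self.soma]

    def validate(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise SWCError("empty graph")
        if self.soma not in g:
            raise SWCError(f"soma node {self.soma} not in graph")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise SWCError(
                f"not a tree: {g.number_of_nodes()} nodes, "
                f"{g.number_of_edges()} edges"
            )
        if not nx.is_connected(g):
            sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
            raise SWCError(f"graph is disconnected; component sizes {sizes}")

    def adjacency_csr(self) -> tuple[sparse.csr_matrix, list[int]]:
        """Symmetric adjacency as CSR plus the node order it is aligned to."""
        order = self.compartment_ids
        a = nx.to_scipy_sparse_array(self.graph, nodelist=order, format="csr")
        return sparse.csr_matrix(a), order

    def soma_index(self) -> int:
        """Position of the soma in :meth:`compartment_ids` order."""
        return self.compartment_ids.index(self.soma)


@dataclass(frozen=True)
class MorphoSummary:
    """Morphometric summary of one neuron (one table row per reconstruction)."""

    n_compartments: int
    n_bifurcations: int
    n_terminals: int
    somatic_branches: int
    c_soma: int
    c_rel: float

    def to_frame(self, label: str = "") -> pd.DataFrame:
        row = {
            "label": label,
            "n_compartments": self.n_compartments,
            "n_bifurcations": self.n_bifurcations,
            "n_terminals": self.n_terminals,
            "somatic_branches": self.somatic_branches,
            "c_soma": self.c_soma,
            "c_rel": self.c_rel,
        }
        return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------


def read_swc(source: str | IO[str] | Iterable[str]) -> list[MorphologyPoint]:
    """Parse SWC text into a list of :class:`MorphologyPoint`.

    ``source`` may be a string of SWC content, an open text stream, or any
    iterable of lines.  Records have seven whitespace-separated columns
    (``id type x y z radius parent``); lines starting with ``#`` and blank
    lines are skipped.  CRLF endings and non-contiguous ids are tolerated.

    Raises
    ------
    SWCError
        On a malformed record (with its line number), a duplicate id, or a
        parent reference that never resolves.
    """
    if isinstance(source, str):
        lines: Iterable[str] = io.StringIO(source)
    else:
        lines = source

    points: list[MorphologyPoint] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCError(
                f"line {lineno}: expected 7 columns, got {len(cols)}: {line!r}"
            )
        try:
            pid = int(cols[0])
            stype = int(cols[1])
            x, y, z, radius = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from None
        if pid <= 0:
            raise SWCError(f"line {lineno}: non-positive id {pid}")
        if pid in seen:
            raise SWCError(f"line {lineno}: duplicate id {pid}")
        if radius < 0:
            raise SWCError(f"line {lineno}: negative radius {radius}")
        seen.add(pid)
        points.append(MorphologyPoint(pid, stype, x, y, z, radius, parent))

    for p in points:
        if p.parent_id != -1 and p.parent_id not in seen:
            raise SWCError(
                f"point {p.id} references undefined parent {p.parent_id}"
            )
    return points


def load_swc(path: str | Path) -> NeuronGraph:
    """Read an SWC file and build the compartment tree in one step."""
    with open(path, "r", encoding="utf-8") as fh:
        return build_graph(read_swc(fh))


def build_graph(points: Sequence[MorphologyPoint]) -> NeuronGraph:
    """Build the undirected compartment tree from parsed SWC points.

    Axon-coded points are dropped together with their incident edges; all
    soma-coded points are contracted into one node that inherits every edge
    to a non-soma neighbor.  The result must be a single connected tree.

    Raises
    ------
    SWCError
        If no soma point exists, or if removing the axon leaves dendritic
        compartments disconnected from the soma (orphan component sizes are
        reported).
    """
    if not points:
        raise SWCError("no points")
    soma_ids = [p.id for p in points if p.structure_type == SOMA]
    if not soma_ids:
        raise SWCError("no soma-coded (type 1) point in reconstruction")
    soma = soma_ids[0]
    soma_set = set(soma_ids)

    keep = {p.id: p for p in points if p.structure_type != AXON}

    g = nx.Graph()
    labels: dict[int, int] = {}
    for p in keep.values():
        node = soma if p.id in soma_set else p.id
        g.add_node(node)
        labels.setdefault(node, SOMA if node == soma else p.structure_type)
    for p in keep.values():
        if p.parent_id == -1 or p.parent_id not in keep:
            # root, or parent was an axon point (the child becomes orphaned
            # and will be caught by the connectivity check below)
            continue
        u = soma if p.id in soma_set else p.id
        v = soma if p.parent_id in soma_set else p.parent_id
        if u != v:
            g.add_edge(u, v)

    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        orphans = [len(c) for c in comps if soma not in c]
        raise SWCError(
            "dendritic compartments disconnected from the soma after axon "
            f"removal; orphan component sizes {orphans}"
        )
    if g.number_of_edges() != g.number_of_nodes() - 1:
        raise SWCError("reconstruction contains a loop; not a tree")
    return NeuronGraph(graph=g, soma=soma, labels=labels)


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------


def count_bifurcations(g: NeuronGraph) -> int:
    """Number of non-soma compartments with three or more neighbors."""
    return sum(1 for v, d in g.graph.degree if d >= 3 and v != g.soma)


def somatic_branch_count(g: NeuronGraph) -> int:
    """Number of dendritic branches attached to the soma (soma degree)."""
    return g.degree(g.soma)


def centrality(g: NeuronGraph) -> dict[int, int]:
    """Per-compartment centrality C_i: maximum tree distance to a terminal.

    Distances count edges on the unique path.  Uses the two-sweep diameter
    trick: for any node, the farthest member of a vertex set in a tree is an
    endpoint of that set's diameter, so two breadth-first passes suffice.

    Raises
    ------
    SWCError
        If the graph has no dendritic terminal (single-node graph).
    """
    terms = g.terminals()
    if not terms:
        raise SWCError("graph has no dendritic terminal; centrality undefined")

    d0 = nx.single_source_shortest_path_length(g.graph, terms[0])
    a = max(terms, key=lambda t: d0[t])
    da = nx.single_source_shortest_path_length(g.graph, a)
    b = max(terms, key=lambda t: da[t])
    db = nx.single_source_shortest_path_length(g.graph, b)
    return {v: max(da[v], db[v]) for v in g.graph.nodes}


def relative_centrality(g: NeuronGraph, cent: Mapping[int, int] | None = None) -> float:
    """Relative centrality of the soma, in [0, 1].

    ``C_rel = 1 - (C_soma - min C) / (max C - min C)`` over all (non-axonal)
    compartments: 1 means the soma is the most central compartment, 0 the
    least central.  A degenerate tree where all centralities coincide yields
    1.0 with a warning.
    """
    if cent is None:
        cent = centrality(g)
    values = list(cent.values())
    c_min, c_max = min(values), max(values)
    if c_max == c_min:
        warnings.warn(
            "all compartments share the same centrality; C_rel defined as 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - (cent[g.soma] - c_min) / (c_max - c_min)


def summarize(g: NeuronGraph) -> MorphoSummary:
    """Compute the full morphometric row for one neuron."""
    cent = centrality(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c_rel = relative_centrality(g, cent)
    return MorphoSummary(
        n_compartments=g.n_compartments,
        n_bifurcations=count_bifurcations(g),
        n_terminals=len(g.terminals()),
        somatic_branches=somatic_branch_count(g),
        c_soma=cent[g.soma],
        c_rel=c_rel,
    )


def centrality_frame(g: NeuronGraph) -> pd.DataFrame:
    """Per-compartment centrality as a tidy table (compartment_id, c)."""
    cent = centrality(g)
    return pd.DataFrame(
        {"compartment_id": list(cent.keys()), "c": list(cent.values())}
    )


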