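"""Synthetic neurites and fixtures.

The benchmark neurite is a minimal two-branch neuron: a primary branch of N
compartments with the soma at compartment 1, plus a secondary branch of L
compartments attached to primary compartment Q (1-based).  It isolates the
effect of a single bifurcation on the spatial profile of the dynamic range.
Stars (a soma with k identical arms) and uniformly random labeled trees are
provided as additional fixtures, and any generated morphology can be written
to SWC so the file-to-graph path is exercised without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO

import networkx as nx
import numpy as np
import pandas as pd

from excitree.metrics import delta_map, response_curve
from excitree.morphology import APICAL_DENDRITE, BASAL_DENDRITE, SOMA, NeuronGraph
from excitree.presets import PROFILE, Preset

__all__ = [
    "NeuriteSpec",
    "make_neurite",
    "make_star",
    "make_random_tree",
    "write_swc",
    "neurite_delta_profile",
]


@dataclass(frozen=True)
class NeuriteSpec:
    """Benchmark two-branch neurite parameters (N, L, Q).

    n_primary
        Length N of the primary branch in compartments (soma included,
        at compartment 1).
    l_secondary
        Length L of the secondary branch (0 gives a simple chain).
    q_attach
        1-based index Q of the primary compartment the secondary branch
        attaches to.
    """

    n_primary: int
    l_secondary: int = 0
    q_attach: int = 1

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if self.l_secondary < 0:
            raise ValueError("l_secondary must be >= 0")
        if not 1 <= self.q_attach <= self.n_primary:
            raise ValueError(
                f"q_attach must be in [1, {self.n_primary}], got {self.q_attach}"
            )


def make_neurite(spec: NeuriteSpec) -> NeuronGraph:
    """Build the two-branch benchmark neurite.

    Node ids 1..N are the primary branch (1 = soma); N+1..N+L the secondary
    branch hanging off node Q.  Total compartments: N + L.
    """
    n, l, q = spec.n_primary, spec.l_secondary, spec.q_attach
    g = nx.Graph()
    g.add_nodes_from(range(1, n + l + 1))
    g.add_edges_from((i, i + 1) for i in range(1, n))
    if l > 0:
        g.add_edge(q, n + 1)
        g.add_edges_from((i, i + 1) for i in range(n + 1, n + l))
    labels = {i: BASAL_DENDRITE for i in range(2, n + 1)}
    labels.update({i: APICAL_DENDRITE for i in range(n + 1, n + l + 1)})
    labels[1] = SOMA
    return NeuronGraph(graph=g, soma=1, labels=labels)


def make_star(arms: int, arm_length: int) -> NeuronGraph:
    """A soma with ``arms`` identical chains of ``arm_length`` compartments."""
    if arms < 1 or arm_length < 1:
        raise ValueError("arms and arm_length must be >= 1")
    g = nx.Graph()
    g.add_node(1)
    labels = {1: SOMA}
    nid = 1
    for _ in range(arms):
        prev = 1
        for _ in range(arm_length):
            nid += 1
            g.add_edge(prev, nid)
            labels[nid] = BASAL_DENDRITE
            prev = nid
    return NeuronGraph(graph=g, soma=1, labels=labels)


def make_random_tree(n: int, seed: int) -> NeuronGraph:
    """Uniformly random labeled tree on ``n`` nodes with a random soma.

    Deterministic for fixed (n, seed); node ids are 1..n.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    t = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(t, {i: i + 1 for i in range(n)})
    soma = int(rng.integers(1, n + 1))
    labels = {v: (SOMA if v == soma else BASAL_DENDRITE) for v in g.nodes}
    return NeuronGraph(graph=g, soma=soma, labels=labels)


def write_swc(g: NeuronGraph, target: str | Path | IO[str]) -> None:
    """Write a generated morphology as SWC (soma type 1, branches type 3).

    Coordinates are synthetic (a planar BFS layout); only the topology is
    meaningful.  The soma is the root.
    """
    order = list(nx.bfs_tree(g.graph, g.soma).nodes)
    new_id = {v: i + 1 for i, v in enumerate(order)}
    parent = nx.predecessor(g.graph, g.soma)
    lines = ["# generated by excitree (synthetic coordinates)"]
    depth = nx.single_source_shortest_path_length(g.graph, g.soma)
    for v in order:
        pid = -1 if v == g.soma else new_id[parent[v][0]]
        stype = SOMA if v == g.soma else BASAL_DENDRITE
        x = float(depth[v])
        y = float(new_id[v] % 97)
        lines.append(f"{new_id[v]} {stype} {x:.1f} {y:.1f} 0.0 0.5 {pid}")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text, encoding="utf-8")


def neurite_delta_profile(
    spec: NeuriteSpec,
    p_transmit: float = 0.92,
    preset: Preset = PROFILE,
    h_grid: np.ndarray | None = None,
    seed: int = 0,
    reference: str = "analytic",
) -> pd.DataFrame:
    """Dynamic range along the benchmark neurite, by distance from the soma.

    Runs ``preset.n_reps`` independent trials (each a full single-repetition
    response curve of ``preset.t_steps`` steps) and reports per-compartment
    mean and standard deviation of Delta across trials.  The default protocol
    is 10 trials of 10**5 steps.

    Returns a table with columns ``compartment_id, distance, branch,
    delta_mean, delta_sd`` where ``distance`` counts edges from the soma and
    ``branch`` is "primary" or "secondary".
    """
    g = make_neurite(spec)
    one_rep = Preset(t_steps=preset.t_steps, n_reps=1, name="trial")
    trials = []
    for rep in range(preset.n_reps):
        curve = response_curve(
            g,
            h_grid=h_grid,
            p_transmit=p_transmit,
            preset=one_rep,
            seed=(seed * 1_000_003 + rep) % (2**31),
        )
        trials.append(delta_map(curve, reference=reference)["delta_db"].to_numpy())
    deltas = np.vstack(trials)  # (n_trials, n_compartments)

    order = g.compartment_ids
    dist = nx.single_source_shortest_path_length(g.graph, g.soma)
    n = spec.n_primary
    return pd.DataFrame(
        {
            "compartment_id": order,
            "distance": [dist[v] for v in order],
            "branch": ["primary" if v <= n else "secondary" for v in order],
            "delta_mean": np.nanmean(deltas, axis=0),
            "delta_sd": np.nanstd(deltas, axis=0),
        }
    )
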