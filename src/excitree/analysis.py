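"""Cross-neuron synthesis: energy planes, classification, correlations.

Neurons are classified by two topological features -- the number of branches
attached to the soma and the relative centrality of the soma -- which
determine the shape of the relative-energy-consumption profile over the
(h, P) parameter plane:

* Type 1: many somatic branches (>= 4 by default); intrinsically energy
  efficient, with a broad low-energy region.
* Type T: two or three somatic branches; a transition regime between
  Types 1 and 2.
* Type 2: a single somatic branch with a central soma (C_rel >= 0.5).
* Type 3: a single somatic branch with a non-central soma (C_rel < 0.5);
  intrinsically inefficient, E never drops below 1.

The boundaries are approximate and configurable (:class:`ClassBoundaries`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from excitree.dynamics import SimConfig, derive_seeds, simulate
from excitree.metrics import delta_map, dynamic_range, energy, response_curve
from excitree.morphology import MorphoSummary, NeuronGraph, summarize
from excitree.presets import SCALED, Preset

__all__ = [
    "ParameterPlane",
    "energy_plane",
    "NeuronClass",
    "ClassBoundaries",
    "classify",
    "pearson",
    "cohort_report",
]


@dataclass
class ParameterPlane:
    """A quantity (here E) evaluated on an (h, P) grid.

    ``values`` has shape (len(h_grid), len(p_grid)); cells where the soma
    never fired are NaN (missing).
    """

    h_grid: np.ndarray
    p_grid: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (h, p, e)."""
        hh, pp = np.meshgrid(self.h_grid, self.p_grid, indexing="ij")
        return pd.DataFrame(
            {"h": hh.ravel(), "p": pp.ravel(), "e": self.values.ravel()}
        )


def energy_plane(
    g: NeuronGraph,
    h_grid: Sequence[float],
    p_grid: Sequence[float],
    preset: Preset = SCALED,
    seed: int = 0,
) -> ParameterPlane:
    """Relative energy consumption E over the (h, P) parameter plane.

    Each cell averages E over ``preset.n_reps`` independent seeded runs of
    ``preset.t_steps`` steps; cells whose soma never fires are NaN.
    """
    h_grid = np.asarray(h_grid, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)
    seeds = derive_seeds(seed, h_grid.size * p_grid.size * preset.n_reps).reshape(
        h_grid.size, p_grid.size, preset.n_reps
    )
    values = np.full((h_grid.size, p_grid.size), np.nan)
    n = g.n_compartments
    for i, h in enumerate(h_grid):
        for j, p in enumerate(p_grid):
            es = []
            for rep in range(preset.n_reps):
                cfg = SimConfig(
                    h=float(h),
                    p_transmit=float(p),
                    t_steps=preset.t_steps,
                    seed=int(seeds[i, j, rep]),
                )
                res = energy(simulate(g, cfg), n)
                if not res.missing:
                    es.append(res.e)
            if es:
                values[i, j] = float(np.mean(es))
    return ParameterPlane(h_grid=h_grid, p_grid=p_grid, values=values)


class NeuronClass(str, Enum):
    TYPE1 = "Type1"
    TYPE2 = "Type2"
    TYPE3 = "Type3"
    TYPET = "TypeT"


@dataclass(frozen=True)
class ClassBoundaries:
    """Approximate boundaries of the four-class topology scheme."""

    min_branches_type1: int = 4
    transition_branches: frozenset[int] = field(
        default_factory=lambda: frozenset({2, 3})
    )
    c_rel_split: float = 0.5

    def __post_init__(self) -> None:
        overlap = {
            b for b in self.transition_branches if b >= self.min_branches_type1
        }
        if overlap:
            raise ValueError(
                f"transition branches {sorted(overlap)} overlap the Type-1 "
                f"region (>= {self.min_branches_type1})"
            )
        if 1 in self.transition_branches:
            raise ValueError("branch count 1 belongs to Types 2/3, not T")


def classify(
    summary: MorphoSummary, bounds: ClassBoundaries | None = None
) -> NeuronClass:
    """Assign the topological class of one neuron.

    Deterministic and total over valid summaries: >= 4 somatic branches is
    Type 1; 2-3 branches is the transition Type T; a single branch splits
    into Type 2 (central soma) and Type 3 (non-central soma) at
    ``c_rel_split``.
    """
    if bounds is None:
        bounds = ClassBoundaries()
    b = summary.somatic_branches
    if b <= 0:
        raise ValueError("invalid graph: soma has no branches")
    if b >= bounds.min_branches_type1:
        return NeuronClass.TYPE1
    if b in bounds.transition_branches:
        return NeuronClass.TYPET
    if summary.c_rel >= bounds.c_rel_split:
        return NeuronClass.TYPE2
    return NeuronClass.TYPE3


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN when variance vanishes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def cohort_report(
    neurons: Sequence[NeuronGraph],
    labels: Sequence[str] | None = None,
    preset: Preset = SCALED,
    h_grid: np.ndarray | None = None,
    p_soma: float = 0.5,
    p_profile: float = 0.92,
    p_max: float = 0.98,
    seed: int = 0,
    bounds: ClassBoundaries | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-neuron dynamic-range summary and cohort-level correlations.

    For each neuron: the somatic dynamic range at ``p_soma`` and ``p_max``,
    the per-compartment max/min dynamic range at ``p_profile`` with the
    relative Delta ``(soma - min)/(max - min)``, the morphometrics, and the
    topological class.  Cohort-level Pearson correlations follow the pairing
    used in the study: somatic Delta (low P) against the somatic-branch
    count, and maximum Delta (high P) against bifurcation and compartment
    counts.

    Returns (table, correlations).
    """
    if labels is None:
        labels = [f"neuron{i}" for i in range(len(neurons))]
    if len(labels) != len(neurons):
        raise ValueError("labels must match neurons")
    if len(neurons) < 1:
        raise ValueError("cohort_report requires at least one neuron")

    seeds = derive_seeds(seed, 3 * len(neurons)).reshape(len(neurons), 3)
    rows = []
    for k, (g, label) in enumerate(zip(neurons, labels)):
        summ = summarize(g)
        cls = classify(summ, bounds)

        curve_soma = response_curve(
            g, h_grid=h_grid, p_transmit=p_soma, preset=preset, seed=int(seeds[k, 0])
        )
        curve_prof = response_curve(
            g, h_grid=h_grid, p_transmit=p_profile, preset=preset, seed=int(seeds[k, 1])
        )
        curve_max = response_curve(
            g, h_grid=h_grid, p_transmit=p_max, preset=preset, seed=int(seeds[k, 2])
        )

        d_soma_lowp = dynamic_range(curve_soma).delta_db
        d_soma_highp = dynamic_range(curve_max).delta_db
        dm_prof = delta_map(curve_prof)
        dm_max = delta_map(curve_max)
        d_soma = dynamic_range(curve_prof).delta_db
        d_max = float(np.nanmax(dm_prof["delta_db"]))
        d_min = float(np.nanmin(dm_prof["delta_db"]))
        rel = (d_soma - d_min) / (d_max - d_min) if d_max > d_min else 1.0
        rows.append(
            {
                "label": label,
                "n_compartments": summ.n_compartments,
                "n_bifurcations": summ.n_bifurcations,
                "somatic_branches": summ.somatic_branches,
                "c_rel": summ.c_rel,
                "delta_soma_low_p": d_soma_lowp,
                "delta_soma": d_soma,
                "delta_max": d_max,
                "delta_min": d_min,
                "relative_delta": rel,
                "delta_max_high_p": float(np.nanmax(dm_max["delta_db"])),
                "class": cls.value,
            }
        )
    table = pd.DataFrame(rows)

    correlations: dict[str, float] = {}
    if len(neurons) >= 3:
        correlations["delta_soma_vs_branches"] = pearson(
            table["somatic_branches"], table["delta_soma_low_p"]
        )
        correlations["delta_max_vs_bifurcations"] = pearson(
            table["n_bifurcations"], table["delta_max_high_p"]
        )
        correlations["delta_max_vs_compartments"] = pearson(
            table["n_compartments"], table["delta_max_high_p"]
        )
    return table, correlations
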