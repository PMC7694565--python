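"""Response functions, dynamic range, and relative energy consumption.

The response function of a compartment is its mean firing rate as a function
of the external driving rate h at fixed transmission probability P.  Its
dynamic range is

    Delta = 10 * log10(h90 / h10)   [dB],

where h10 and h90 are the driving rates at which the compartment fires at 10%
and 90% of the maximal rate F_max = 1 / ((1 + refractory + 1) * dt).  Crossing
points are located by the first crossing on the h grid with log-linear
interpolation (linear in log10 h).

The relative energy consumption of a run is

    E = (F_D / F_S) / (N - 1),

the mean number of dendritic spikes per somatic spike, normalised by the
number of dendritic compartments: how hard the tree works for each somatic
spike.  E -> 1 both as P -> 1 (every signal visits every compartment exactly
once) and as h -> infinity (every compartment saturates independently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from excitree.dynamics import SimConfig, SpikeCounts, derive_seeds, input_prob, simulate
from excitree.morphology import NeuronGraph
from excitree.presets import SCALED, Preset

__all__ = [
    "firing_rate",
    "f_max",
    "isolated_rate",
    "default_h_grid",
    "ResponseCurve",
    "response_curve",
    "DynamicRange",
    "dynamic_range",
    "EnergyResult",
    "energy",
]


def firing_rate(count: int, t_steps: int, dt: float = 1.0) -> float:
    """Convert a spike count over a run into a mean rate in Hz.

    ``count / (t_steps * dt)`` is a rate per millisecond; multiplied by 1000
    it is in Hz.
    """
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    return count * 1000.0 / (t_steps * dt)


def f_max(refractory_steps: int = 7, dt: float = 1.0) -> float:
    """Maximal attainable firing rate in Hz.

    One step active + ``refractory_steps`` refractory + one step to
    re-activate: ``1 / ((1 + refractory + 1) * dt)`` per millisecond.
    """
    return 1000.0 / ((1 + refractory_steps + 1) * dt)


def isolated_rate(h: float, refractory_steps: int = 7, dt: float = 1.0) -> float:
    """Closed-form firing rate (Hz) of an isolated compartment.

    The inter-spike interval of a single compartment is 1 step active +
    ``refractory_steps`` steps refractory + a geometric wait with mean 1/r, so
    the mean rate is ``1 / (1 + refractory + 1/r)`` per step.
    """
    r = input_prob(h, dt)
    if r == 0.0:
        return 0.0
    return 1000.0 / ((1 + refractory_steps + 1.0 / r) * dt)


def default_h_grid(
    lo: float = 1e-4, hi: float = 1e4, points_per_decade: int = 5
) -> np.ndarray:
    """Log-spaced external-driving grid, by default 10^-4..10^4 Hz."""
    n_dec = math.log10(hi / lo)
    n = int(round(n_dec * points_per_decade)) + 1
    return np.logspace(math.log10(lo), math.log10(hi), n)


@dataclass
class ResponseCurve:
    """Per-compartment mean firing rates over a grid of driving rates.

    ``rates`` has shape (len(h_grid), n_compartments) and holds the mean rate
    in Hz over ``n_reps`` repetitions; ``rates_sd`` the standard deviation
    across repetitions (zero when n_reps == 1).
    """

    h_grid: np.ndarray
    rates: np.ndarray
    rates_sd: np.ndarray
    compartment_ids: list[int]
    soma_index: int
    p_transmit: float
    n_reps: int
    t_steps: int
    dt: float
    refractory_steps: int

    def soma_rates(self) -> np.ndarray:
        return self.rates[:, self.soma_index]

    def compartment_rates(self, index: int) -> np.ndarray:
        return self.rates[:, index]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (compartment_id, h, rate_hz)."""
        n_h, n_c = self.rates.shape
        return pd.DataFrame(
            {
                "compartment_id": np.repeat(self.compartment_ids, n_h),
                "h": np.tile(self.h_grid, n_c),
                "rate_hz": self.rates.T.ravel(),
            }
        )


def response_curve(
    g: NeuronGraph,
    h_grid: np.ndarray | None = None,
    p_transmit: float = 0.96,
    preset: Preset = SCALED,
    seed: int = 0,
    dt: float = 1.0,
    refractory_steps: int = 7,
) -> ResponseCurve:
    """Simulate the response function of every compartment.

    For each h on the grid, ``preset.n_reps`` independent seeded runs of
    ``preset.t_steps`` steps are averaged.  Seeds are derived from ``seed``
    per (h, repetition) cell, so the curve is reproducible and individual
    cells can be recomputed independently.
    """
    if h_grid is None:
        h_grid = default_h_grid()
    h_grid = np.asarray(h_grid, dtype=float)
    if h_grid.size == 0 or np.any(np.diff(h_grid) <= 0):
        raise ValueError("h_grid must be non-empty and strictly increasing")

    seeds = derive_seeds(seed, h_grid.size * preset.n_reps).reshape(
        h_grid.size, preset.n_reps
    )
    n = g.n_compartments
    rates = np.zeros((h_grid.size, n))
    rates_sd = np.zeros((h_grid.size, n))
    order = g.compartment_ids
    for i, h in enumerate(h_grid):
        per_rep = np.zeros((preset.n_reps, n))
        for rep in range(preset.n_reps):
            cfg = SimConfig(
                h=float(h),
                p_transmit=p_transmit,
                dt=dt,
                refractory_steps=refractory_steps,
                t_steps=preset.t_steps,
                seed=int(seeds[i, rep]),
            )
            per_rep[rep] = simulate(g, cfg).rates_hz()
        rates[i] = per_rep.mean(axis=0)
        rates_sd[i] = per_rep.std(axis=0)
    return ResponseCurve(
        h_grid=h_grid,
        rates=rates,
        rates_sd=rates_sd,
        compartment_ids=order,
        soma_index=g.soma_index(),
        p_transmit=p_transmit,
        n_reps=preset.n_reps,
        t_steps=preset.t_steps,
        dt=dt,
        refractory_steps=refractory_steps,
    )


@dataclass
class DynamicRange:
    """h10, h90 and the dynamic range Delta of one response function."""

    h10: float
    h90: float
    delta_db: float
    reference_max: float
    missing: bool = False
    reason: str = ""

    def __bool__(self) -> bool:
        return not self.missing


def _first_crossing(h: np.ndarray, rate: np.ndarray, threshold: float) -> float | None:
    """First h at which the curve reaches ``threshold``, log-linear in h."""
    above = rate >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(h[0])
    r0, r1 = rate[k - 1], rate[k]
    if r1 == r0:
        return float(h[k])
    frac = (threshold - r0) / (r1 - r0)
    return float(10 ** (np.log10(h[k - 1]) + frac * (np.log10(h[k]) - np.log10(h[k - 1]))))


def dynamic_range(
    curve: ResponseCurve,
    compartment: int | None = None,
    reference: str = "analytic",
) -> DynamicRange:
    """Dynamic range Delta = 10*log10(h90/h10) of one compartment's curve.

    Parameters
    ----------
    compartment : int or None
        Position in the curve's compartment order; None selects the soma.
    reference : {"analytic", "empirical"}
        Maximal rate used for the 10%/90% thresholds: the analytic
        ``f_max`` (default, robust at reduced run lengths) or the empirical
        plateau max of the curve itself.

    A curve that never reaches 90% of the reference is flagged missing
    (``missing=True`` with a diagnostic) rather than raising.
    """
    idx = curve.soma_index if compartment is None else int(compartment)
    rate = curve.rates[:, idx]
    if reference == "analytic":
        ref = f_max(curve.refractory_steps, curve.dt)
    elif reference == "empirical":
        ref = float(rate.max())
    else:
        raise ValueError(f"unknown reference {reference!r}")

    h10 = _first_crossing(curve.h_grid, rate, 0.1 * ref)
    h90 = _first_crossing(curve.h_grid, rate, 0.9 * ref)
    if h90 is None or h10 is None:
        top = float(rate.max())
        return DynamicRange(
            h10=math.nan,
            h90=math.nan,
            delta_db=math.nan,
            reference_max=ref,
            missing=True,
            reason=(
                f"curve peaks at {top:.4g} Hz, below "
                f"{0.9 * ref:.4g} Hz (90% of reference {ref:.4g} Hz)"
            ),
        )
    return DynamicRange(
        h10=h10,
        h90=h90,
        delta_db=10.0 * math.log10(h90 / h10),
        reference_max=ref,
    )


def delta_map(curve: ResponseCurve, reference: str = "analytic") -> pd.DataFrame:
    """Dynamic range of every compartment as a tidy table."""
    rows = []
    for i, cid in enumerate(curve.compartment_ids):
        dr = dynamic_range(curve, compartment=i, reference=reference)
        rows.append(
            {
                "compartment_id": cid,
                "h10": dr.h10,
                "h90": dr.h90,
                "delta_db": dr.delta_db,
                "missing": dr.missing,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnergyResult:
    """Relative energy consumption E = (F_D/F_S)/(N-1) of one run."""

    e: float
    f_s: int
    f_d: int
    n: int

    @property
    def missing(self) -> bool:
        return math.isnan(self.e)


def energy(counts: SpikeCounts, n: int | None = None) -> EnergyResult:
    """Relative energy consumption from the spike tallies of one run.

    Marked missing (NaN) when the soma never fired; requires at least two
    compartments.
    """
    if n is None:
        n = counts.counts.size
    if n < 2:
        raise ValueError("energy requires at least 2 compartments")
    f_s = counts.f_soma
    f_d = counts.f_dendrites
    if f_s == 0:
        return EnergyResult(e=math.nan, f_s=f_s, f_d=f_d, n=n)
    return EnergyResult(e=(f_d / f_s) / (n - 1), f_s=f_s, f_d=f_d, n=n)
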