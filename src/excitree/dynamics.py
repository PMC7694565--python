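"""Discrete-time stochastic SIRS automaton on a compartment tree.

Every compartment cycles susceptible -> active -> refractory -> susceptible.
A susceptible compartment i with k_i neighbors activates in one synchronous
time step with probability

    P_i(t + dt) = 1 - (1 - r) * (1 - P) ** (number of active neighbors),

where ``r = 1 - exp(-h * dt)`` converts the external (synaptic) Poisson drive
h into a per-step probability, and P is the probability that an active
neighbor transmits.  An active compartment stays active for exactly one step
and is then refractory for ``refractory_steps`` steps (default 7), so the
shortest possible inter-spike interval is ``refractory_steps + 2`` steps and
the saturated firing rate is ``1 / (1 + refractory_steps + 1)`` per step.

State encoding: 0 susceptible, 1 active, values 2..refractory_steps+1 are a
refractory countdown (a compartment active at t holds value
``refractory_steps + 1`` at t+1, decrements each step, and is susceptible
again at t + refractory_steps + 1).

Propagation is symmetric (the same P forward and backward along an edge), so
backpropagation of somatic activity into the dendrites requires no special
handling.  The inner loop is JIT-compiled with numba; a pure-Python
single-step update (:func:`step`) defines the reference semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from excitree.morphology import NeuronGraph

__all__ = [
    "SimConfig",
    "SpikeCounts",
    "input_prob",
    "activation_prob",
    "step",
    "simulate",
]

SUSCEPTIBLE = 0
ACTIVE = 1


@dataclass(frozen=True)
class SimConfig:
    """All dynamical parameters of one simulation run.

    Parameters
    ----------
    h : float
        External driving rate in Hz (>= 0); each compartment receives
        independent Poisson-like synaptic input at this rate.
    p_transmit : float
        Probability P in [0, 1] that an active compartment activates a
        susceptible neighbor in one step.
    dt : float
        Time step in milliseconds (default 1).
    refractory_steps : int
        Length of the refractory period in steps (default 7).
    t_steps : int
        Number of synchronous updates (default 10**6, i.e. 1000 s at 1 ms).
    seed : int
        Seed for the per-run random stream.
    stimulus_override : tuple of (time, compartment_index)
        Forced activations: at the given step the compartment (by position in
        the graph's node order) becomes active if it is susceptible.  Time 0
        forces the initial state.
    """

    h: float
    p_transmit: float
    dt: float = 1.0
    refractory_steps: int = 7
    t_steps: int = 1_000_000
    seed: int = 0
    stimulus_override: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")
        if not 0.0 <= self.p_transmit <= 1.0:
            raise ValueError(f"p_transmit must be in [0,1], got {self.p_transmit}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be >= 0")
        if self.t_steps < 1:
            raise ValueError("t_steps must be >= 1")

    @property
    def r(self) -> float:
        """Per-step external activation probability for this config."""
        return input_prob(self.h, self.dt)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class SpikeCounts:
    """Per-compartment activation tallies over one run."""

    counts: np.ndarray
    compartment_ids: list[int]
    soma_index: int
    t_steps: int
    dt: float

    @property
    def f_soma(self) -> int:
        """Total number of somatic spikes F_S."""
        return int(self.counts[self.soma_index])

    @property
    def f_dendrites(self) -> int:
        """Total number of dendritic (non-soma) spikes F_D."""
        return int(self.counts.sum() - self.counts[self.soma_index])

    def rates_hz(self) -> np.ndarray:
        """Per-compartment mean firing rate in Hz."""
        return self.counts * (1000.0 / (self.t_steps * self.dt))


def input_prob(h: float, dt: float = 1.0) -> float:
    """Per-step probability of an external activation, r = 1 - exp(-h*dt).

    ``h`` is in Hz and ``dt`` in milliseconds, so the exponent uses
    ``h * dt / 1000``.
    """
    if h < 0:
        raise ValueError(f"h must be >= 0, got {h}")
    return -math.expm1(-h * dt / 1000.0)


def activation_prob(n_active_neighbors: int, r: float, p_transmit: float) -> float:
    """Probability that a susceptible compartment activates this step."""
    return 1.0 - (1.0 - r) * (1.0 - p_transmit) ** n_active_neighbors


# ---------------------------------------------------------------------------
# Reference (pure Python) synchronous update
# ---------------------------------------------------------------------------


def step(
    state: np.ndarray,
    neighbors: Sequence[Sequence[int]],
    cfg: SimConfig,
    rng: np.random.Generator,
    forced: Sequence[int] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """One synchronous update, computed entirely from the state at t.

    Parameters
    ----------
    state : int array
        Current state vector (encoding as in the module docstring).
    neighbors : sequence of index lists
        Adjacency by position, aligned with ``state``.
    forced : indices
        Compartments forced to activate this step if susceptible.

    Returns
    -------
    (new_state, newly_active) : the state at t + dt and the indices of the
    compartments that transitioned into the active state.
    """
    r = cfg.r
    p = cfg.p_transmit
    forced_set = set(int(i) for i in forced)
    new = np.empty_like(state)
    newly: list[int] = []
    for i in range(state.size):
        s = state[i]
        if s == ACTIVE:
            new[i] = cfg.refractory_steps + 1 if cfg.refractory_steps > 0 else 0
        elif s >= 2:
            new[i] = s - 1 if s > 2 else 0
        else:  # susceptible
            if i in forced_set:
                new[i] = ACTIVE
                newly.append(i)
                continue
            n_act = sum(1 for j in neighbors[i] if state[j] == ACTIVE)
            if rng.random() < activation_prob(n_act, r, p):
                new[i] = ACTIVE
                newly.append(i)
            else:
                new[i] = SUSCEPTIBLE
    return new, np.asarray(newly, dtype=np.int64)


# ---------------------------------------------------------------------------
# JIT-compiled run
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sirs_run(
    indptr,
    indices,
    r,
    p,
    refractory,
    t_steps,
    seed,
    forced_t,
    forced_i,
    record_trace,
):  # pragma: no cover - exercised through simulate()
    n = indptr.size - 1
    np.random.seed(seed)
    state = np.zeros(n, dtype=np.int8)
    new = np.zeros(n, dtype=np.int8)
    counts = np.zeros(n, dtype=np.int64)
    if record_trace:
        trace = np.zeros((t_steps + 1, n), dtype=np.int8)
    else:
        trace = np.zeros((1, 1), dtype=np.int8)

    refr_entry = refractory + 1 if refractory > 0 else 0
    q = 1.0 - p
    one_minus_r = 1.0 - r

    # forced activations at t = 0 seed the initial state
    for k in range(forced_t.size):
        if forced_t[k] == 0:
            i = forced_i[k]
            if state[i] == 0:
                state[i] = 1
                counts[i] += 1
    if record_trace:
        trace[0] = state

    for t in range(1, t_steps + 1):
        for i in range(n):
            s = state[i]
            if s == 1:
                new[i] = refr_entry
            elif s >= 2:
                new[i] = s - 1 if s > 2 else 0
            else:
                n_act = 0
                for jj in range(indptr[i], indptr[i + 1]):
                    if state[indices[jj]] == 1:
                        n_act += 1
                fail = one_minus_r
                for _ in range(n_act):
                    fail *= q
                if np.random.random() < 1.0 - fail:
                    new[i] = 1
                    counts[i] += 1
                else:
                    new[i] = 0
        for k in range(forced_t.size):
            if forced_t[k] == t:
                i = forced_i[k]
                if state[i] == 0 and new[i] == 0:
                    new[i] = 1
                    counts[i] += 1
        state, new = new, state
        if record_trace:
            trace[t] = state
    return counts, trace


def simulate(
    g: NeuronGraph,
    cfg: SimConfig,
    record_trace: bool = False,
) -> SpikeCounts | tuple[SpikeCounts, np.ndarray]:
    """Run the automaton for ``cfg.t_steps`` steps on graph ``g``.

    All compartments start susceptible (plus any forced activations at time
    0).  Returns the per-compartment spike counts; with ``record_trace=True``
    also the full (t_steps+1) x N int8 state matrix, which is only sensible
    for small runs.

    Reproducible: identical (graph, config, seed) give identical counts.
    """
    csr, order = g.adjacency_csr()
    forced = sorted(cfg.stimulus_override)
    forced_t = np.asarray([t for t, _ in forced], dtype=np.int64)
    forced_i = np.asarray([i for _, i in forced], dtype=np.int64)
    for t, i in forced:
        if not 0 <= i < len(order):
            raise ValueError(f"forced compartment index {i} out of range")
        if not 0 <= t <= cfg.t_steps:
            raise ValueError(f"forced activation time {t} outside run")

    counts, trace = _sirs_run(
        csr.indptr.astype(np.int64),
        csr.indices.astype(np.int64),
        float(cfg.r),
        float(cfg.p_transmit),
        int(cfg.refractory_steps),
        int(cfg.t_steps),
        int(cfg.seed) % (2**31),
        forced_t,
        forced_i,
        record_trace,
    )
    result = SpikeCounts(
        counts=counts,
        compartment_ids=order,
        soma_index=g.soma_index(),
        t_steps=cfg.t_steps,
        dt=cfg.dt,
    )
    if record_trace:
        return result, trace
    return result


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)
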