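"""SIRS automaton: update rule, wave propagation, closed-form agreement."""

import math

import numpy as np
import pytest

from excitree.dynamics import (
    SimConfig,
    activation_prob,
    input_prob,
    simulate,
    step,
)
from excitree.metrics import f_max, isolated_rate
from excitree.neurites import NeuriteSpec, make_neurite, make_random_tree

from conftest import chain_graph, single_compartment


class TestInputProb:
    def test_zero_drive(self):
        assert input_prob(0.0) == 0.0

    def test_saturation(self):
        assert input_prob(1e6, dt=1.0) == pytest.approx(1.0, abs=1e-12)

    def test_one_khz_gives_1_minus_inv_e(self):
        assert input_prob(1000.0, dt=1.0) == pytest.approx(1 - math.exp(-1))

    def test_negative_drive_rejected(self):
        with pytest.raises(ValueError):
            input_prob(-1.0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=200)
@given(
    n=st.integers(min_value=0, max_value=12),
    r=st.floats(min_value=0.0, max_value=1.0),
    p=st.floats(min_value=0.0, max_value=1.0),
)
def test_activation_prob_is_a_probability_and_monotone(n, r, p):
    q = activation_prob(n, r, p)
    assert 0.0 <= q <= 1.0
    assert q >= r - 1e-12  # external drive alone is a lower bound
    assert activation_prob(n + 1, r, p) >= q - 1e-12


class TestActivationProb:
    def test_single_active_neighbor_pure_transmission(self):
        assert activation_prob(1, r=0.0, p_transmit=0.96) == pytest.approx(0.96)

    def test_two_neighbors_combine_independently(self):
        assert activation_prob(2, r=0.5, p_transmit=0.5) == pytest.approx(0.875)

    def test_no_sources_no_activation(self):
        assert activation_prob(0, r=0.0, p_transmit=1.0) == 0.0


def _neighbors_of_chain(n):
    return [
        [j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)
    ]


class TestStep:
    def test_deterministic_propagation_both_ways(self):
        cfg = SimConfig(h=0.0, p_transmit=1.0, t_steps=1)
        state = np.array([0, 0, 1, 0, 0], dtype=np.int8)
        rng = np.random.default_rng(0)
        new, newly = step(state, _neighbors_of_chain(5), cfg, rng)
        assert list(new) == [0, 1, 8, 1, 0]
        assert sorted(newly) == [1, 3]

    def test_refractory_countdown_ignores_neighbors(self):
        cfg = SimConfig(h=1e9, p_transmit=1.0, t_steps=1)
        state = np.array([1, 3, 0], dtype=np.int8)
        rng = np.random.default_rng(0)
        new, _ = step(state, _neighbors_of_chain(3), cfg, rng)
        assert new[1] == 2

    def test_quiescence_is_absorbing_without_drive(self):
        cfg = SimConfig(h=0.0, p_transmit=1.0, t_steps=1)
        state = np.zeros(4, dtype=np.int8)
        rng = np.random.default_rng(0)
        new, newly = step(state, _neighbors_of_chain(4), cfg, rng)
        assert not new.any() and newly.size == 0

    def test_forced_activation_only_if_susceptible(self):
        cfg = SimConfig(h=0.0, p_transmit=0.0, t_steps=1)
        state = np.array([0, 1], dtype=np.int8)
        rng = np.random.default_rng(0)
        new, newly = step(state, _neighbors_of_chain(2), cfg, rng, forced=[0, 1])
        assert new[0] == 1 and list(newly) == [0]
        assert new[1] == 8  # active compartment enters refractory instead


def _python_reference_run(g, cfg, forced):
    """Trajectory from the pure-Python step(), for deterministic configs."""
    order = g.compartment_ids
    index = {v: i for i, v in enumerate(order)}
    neighbors = [[index[u] for u in g.graph.neighbors(v)] for v in order]
    state = np.zeros(len(order), dtype=np.int8)
    counts = np.zeros(len(order), dtype=np.int64)
    rng = np.random.default_rng(0)
    for t, i in forced:
        if t == 0:
            state[i] = 1
            counts[i] += 1
    states = [state.copy()]
    for t in range(1, cfg.t_steps + 1):
        f = [i for (tt, i) in forced if tt == t]
        state, newly = step(state, neighbors, cfg, rng, forced=f)
        counts[newly] += 1
        states.append(state.copy())
    return counts, np.array(states)


class TestSimulate:
    def test_matches_python_reference_when_deterministic(self):
        # P = 1, h = 0: trajectory has no randomness, so the compiled kernel
        # must agree with the pure-Python reference step for step.
        g = make_neurite(NeuriteSpec(8, 3, 4))
        cfg = SimConfig(
            h=0.0, p_transmit=1.0, t_steps=30, seed=5,
            stimulus_override=((0, 2), (20, 0)),
        )
        counts, trace = simulate(g, cfg, record_trace=True)
        ref_counts, ref_trace = _python_reference_run(
            g, cfg, [(0, 2), (20, 0)]
        )
        assert np.array_equal(counts.counts, ref_counts)
        assert np.array_equal(trace, ref_trace)

    def test_no_drive_no_spikes(self):
        g = make_random_tree(20, seed=1)
        cfg = SimConfig(h=0.0, p_transmit=1.0, t_steps=500, seed=1)
        assert simulate(g, cfg).counts.sum() == 0

    def test_seed_determinism(self):
        g = make_neurite(NeuriteSpec(30, 10, 15))
        cfg = SimConfig(h=5.0, p_transmit=0.8, t_steps=5000, seed=42)
        a = simulate(g, cfg).counts
        b = simulate(g, cfg).counts
        assert np.array_equal(a, b)
        c = simulate(g, cfg.with_seed(43)).counts
        assert not np.array_equal(a, c)

    def test_single_wave_visits_every_compartment_once(self):
        # deterministic transmission, one initiation: the wave covers the
        # whole tree exactly once, then dies at the terminals
        for seed in (0, 1, 2):
            g = make_random_tree(40, seed=seed)
            cfg = SimConfig(
                h=0.0, p_transmit=1.0, t_steps=60, seed=0,
                stimulus_override=((0, 0),),
            )
            counts = simulate(g, cfg)
            assert np.all(counts.counts == 1)

    def test_two_opposing_waves_annihilate(self):
        for n in (10, 11):  # even and odd chains: head-on and same-site
            g = chain_graph(n)
            cfg = SimConfig(
                h=0.0, p_transmit=1.0, t_steps=3 * n, seed=0,
                stimulus_override=((0, 0), (0, n - 1)),
            )
            counts = simulate(g, cfg)
            assert np.all(counts.counts == 1)

    def test_refractory_discipline_on_trace(self):
        g = chain_graph(5)
        cfg = SimConfig(h=500.0, p_transmit=0.7, t_steps=2000, seed=9)
        counts, trace = simulate(g, cfg, record_trace=True)
        active = trace == 1
        for i in range(trace.shape[1]):
            times = np.flatnonzero(active[:, i])
            if times.size > 1:
                assert np.diff(times).min() >= cfg.refractory_steps + 2
        # trace activations equal the reported counts
        assert np.array_equal(active.sum(axis=0), counts.counts)

    def test_counts_never_exceed_refractory_bound(self):
        # min inter-spike interval is refractory + 2 steps, so over a finite
        # run each compartment fires at most T/(refractory+2) + 1 times
        g = make_neurite(NeuriteSpec(12, 4, 6))
        for h, p in [(1e4, 1.0), (1e3, 0.5), (50.0, 0.96)]:
            cfg = SimConfig(h=h, p_transmit=p, t_steps=20_000, seed=3)
            counts = simulate(g, cfg).counts
            assert np.all(counts <= cfg.t_steps / (cfg.refractory_steps + 2) + 1)

    def test_saturated_isolated_compartment_fires_at_f_max(self):
        g = single_compartment()
        cfg = SimConfig(h=1e4, p_transmit=0.5, t_steps=100_000, seed=0)
        rate = simulate(g, cfg).rates_hz()[0]
        assert rate == pytest.approx(111.1, abs=0.5)

    def test_isolated_rate_matches_closed_form_across_decades(self):
        # F(h) = 1/(8 + 1/r) per ms; agreement within 3 Monte-Carlo SE
        g = single_compartment()
        t_steps = 200_000
        for k, h in enumerate([0.1, 1.0, 10.0, 100.0, 1e3, 1e4]):
            cfg = SimConfig(h=h, p_transmit=0.5, t_steps=t_steps, seed=100 + k)
            counts = simulate(g, cfg)
            expected_hz = isolated_rate(h)
            n_exp = expected_hz * t_steps / 1000.0
            se = math.sqrt(max(n_exp, 1.0))
            assert abs(counts.counts[0] - n_exp) <= 3 * se

    def test_forced_index_validation(self):
        g = chain_graph(3)
        with pytest.raises(ValueError):
            simulate(
                g,
                SimConfig(h=0, p_transmit=1, t_steps=10,
                          stimulus_override=((0, 99),)),
            )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"h": -1.0, "p_transmit": 0.5},
            {"h": 1.0, "p_transmit": 1.5},
            {"h": 1.0, "p_transmit": 0.5, "t_steps": 0},
            {"h": 1.0, "p_transmit": 0.5, "refractory_steps": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
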