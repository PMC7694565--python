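# Methods

## Model

Each compartment of a neuron is a three-phase excitable unit updated
synchronously on a discrete time grid (δt = 1 ms by default):

* **Susceptible (state 0).** Activates in one step with probability
  `1 − (1 − r)·(1 − P)^k`, where `k` is the number of currently active
  neighbors, `P` the transmission probability per active neighbor, and
  `r = 1 − exp(−h·δt)` the per-step probability of an external (synaptic)
  activation at Poisson rate `h` (Hz; the exponent uses `h·δt/1000` so Hz
  and ms are dimensionally consistent).
* **Active (state 1).** Lasts exactly one step; a transition into this state
  is one spike.
* **Refractory (countdown states).** Lasts `refractory_steps` steps
  (default 7), during which the compartment ignores all input.

A compartment active at `t` is susceptible again at `t + 8` and — because
activation acts on the *next* state — can fire again at `t + 9` at the
earliest. The saturated rate is therefore `F_max = 1/(1 + 7 + 1)` per ms
≈ 111.1 Hz, and an isolated compartment fires at the closed-form rate
`F(h) = 1/(8 + 1/r)` per ms (1 active + 7 refractory + geometric wait of
mean 1/r). This closed form is the main analytical oracle in the test suite.

Transmission is symmetric along every edge (same `P` in both directions), so
somatic activity re-enters the dendrites (backpropagation) without special
code. `1 − P` lumps together passive attenuation and synaptic inhibition;
neither is modelled explicitly. Two colliding wavefronts annihilate because
each front leaves refractory compartments behind it, and on a loop-free tree
a single wave at `P = 1` visits every compartment exactly once — both
properties are asserted exactly in the tests.

One uniform draw per susceptible compartment per step decides activation
against the aggregated probability above. This is distribution-equivalent to
independent per-edge transmission draws but uses fewer random numbers and
gives a simpler reproducibility contract (a single per-run seed). The inner
loop is JIT-compiled (numba) and seeded explicitly; identical
(graph, config, seed) triples give identical spike counts. All runs start
from the all-susceptible state with no burn-in discarded: run lengths dwarf
the transient, and forced activations (`stimulus_override`) exist for the
deterministic wave experiments.

## Morphology conventions

* SWC sample points are the compartments; no resampling to uniform segment
  length is attempted, so compartment counts reflect reconstruction
  resolution.
* All type-1 (soma) points contract into a single soma node that inherits
  their external edges; the soma obeys the same dynamics as every other
  compartment but may have many neighbors.
* Type-2 (axon) points are excluded everywhere — morphometrics and
  simulation — for consistency; codes ≥ 5 are kept as dendrite-like since
  custom codes are common in public reconstructions.
* Distances count **edges** on the unique path (`distance(i,i) = 0`). The
  centrality `C_i` is the maximum distance from compartment `i` to any
  dendritic terminal (degree-1 non-soma node); an equivalent "number of
  compartments" convention would shift every `C_i` by one and leave `C_rel`
  almost unchanged. `C_rel = 1 − (C_soma − min C)/(max C − min C)`; the
  degenerate all-equal case is defined as 1 with a warning (it cannot arise
  from edge distances on a tree with ≥ 2 nodes, but the guard protects
  externally supplied centralities). Terminals never include the soma, even
  at soma degree 1.
* Centrality uses the two-sweep diameter argument (the farthest member of a
  vertex set from any node is an endpoint of that set's diameter), giving
  O(N) instead of O(T·N); the brute-force all-terminals BFS is kept in the
  test suite as the independent oracle.

## Measured quantities

* **Firing rate**: spike count / (t_steps·δt), reported in Hz.
* **Response curve**: per-compartment mean rate over a log-spaced `h` grid
  (default 10⁻⁴–10⁴ Hz, 5 points per decade) at fixed `P`, averaged over
  `n_reps` independently seeded runs.
* **Dynamic range**: `Δ = 10·log₁₀(h₉₀/h₁₀)` with `h₁₀`, `h₉₀` located by the
  first grid crossing of 10%/90% of the reference maximum, interpolated
  linearly in log₁₀ h. The reference maximum defaults to the analytic
  `F_max` rather than the empirical plateau — robust at reduced run lengths —
  with the empirical option retained. A curve that never reaches 90% of the
  reference is flagged missing with a diagnostic rather than raising.
* **Energy**: `E = (F_D/F_S)/(N − 1)` per run; marked missing (NaN) when the
  soma never fires. `E → 1` both as `P → 1` (each signal visits every
  compartment once) and as `h → ∞` (independent saturation) — both limits
  are acceptance-tested.
* **Classification**: somatic-branch count ≥ 4 → Type 1; 2–3 → Type T;
  1 branch splits into Type 2 / Type 3 at `C_rel = 0.5`. The boundaries are
  approximate by nature and are plain configuration
  (`analysis.ClassBoundaries`); the defaults encode the qualitative anchors
  (single-branch somata are special, the transition happens at two or three
  branches, centrality separates the single-branch types).

## Synthetic data

The generators produce the three fixture families the analyses need:

* `make_neurite(NeuriteSpec(N, L, Q))` — the benchmark two-branch neurite: a
  primary chain of `N` compartments with the soma at compartment 1 (the
  origin of the distance axis) and an `L`-compartment side branch attached
  at compartment `Q` (defaults N=240, L=50, Q=120). The toy soma is not
  dynamically distinct, consistent with the homogeneous dynamics.
* `make_star(arms, arm_length)` — a soma with identical chains attached,
  isolating the effect of the somatic-branch count.
* `make_random_tree(n, seed)` — uniformly random labeled trees with a random
  soma, for property tests.

All of them can be written to SWC (`write_swc`, synthetic planar
coordinates, soma type 1 / branches type 3) so the file→graph path is
exercised without downloads. What these fixtures do **not** emulate:
realistic branch-length and diameter statistics, 3-D geometry, multiple
somatic points, or reconstruction artifacts. Tests passing on them show the
automaton and the metrics are correct on exact topologies; conclusions about
real neurons additionally depend on reconstruction quality and resolution.

## Problem sizes and numerical choices

The full study protocol is 10⁶ steps × 5 repetitions per (h, P) condition
(`presets.FULL`) and 10⁵ steps × 10 trials for benchmark-neurite profiles
(`presets.PROFILE`). The test suite and examples use the scaled preset
(10⁵ steps × 3 repetitions) or smaller, which this package treats as its
routine working scale; at 10⁵ steps the Monte-Carlo standard error of a
per-compartment rate near saturation is below 1 Hz, and the bifurcation
signature of the benchmark neurite (a ≈ 1 dB local boost in Δ at the
junction) is resolved with trial standard deviations of ≈ 0.15 dB.
Statistical assertions use 3-standard-error bands (the geometric-renewal
variance is at most Poisson-like, so √n is conservative); the bifurcation
boost is detected with a one-sided sign test over paired compartments at
α = 0.02. Seeds are derived per (h, P, repetition) cell from a master seed
via `numpy.random.SeedSequence`, so sweep cells can be recomputed
independently and bit-identically.

## Known limitations

* Homogeneous dynamics: no per-compartment `P`, refractory period, or
  direction-dependent propagation; no explicit inhibition; no electrotonic
  (continuous-voltage) modelling. These are deliberate non-goals.
* Geometry is ignored beyond topology: path lengths are in edges, not µm.
* `h₁₀`/`h₉₀` conventions differ across the literature (empirical vs
  analytic maximum, interpolation scheme); results here use the analytic
  maximum with log-linear interpolation, and Δ is stable to < 0.5 dB under
  grid refinement, but absolute Δ values can shift by a fraction of a dB
  under other conventions.
* Reduced run lengths bias `E` upward slightly at very low `h` (few somatic
  spikes) and leave Δ missing for compartments whose curves never reach 90%
  of `F_max` on the chosen grid; both situations are flagged, not silently
  dropped.
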