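"""Deterministic generators for test inputs.

Everything a test or demonstration needs is generated from a (name, seed)
pair and regenerates bit-identically: the 20-neuron down-scaled network
(16 excitatory / 4 inhibitory, out-degree 5 -- small enough to debug by
hand, large enough to spike and have a non-trivial connectivity matrix),
synthetic spike trains with analytically known statistics (regular trains
with LV = 0, Poisson trains with LV -> 1 and pairwise CC -> 0), and the
strong-drive single-neuron scenario that exposes the fixed-point overflow
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    StimulusSeries,
    Topology,
    build_topology,
    init_weights,
    make_stimulus,
)
from .solvers import RS, IzhikevichParams
from .stats import SpikeData

__all__ = [
    "FixtureBundle",
    "OverflowScenario",
    "make_test_network",
    "make_poisson_trains",
    "make_regular_trains",
    "make_overflow_scenario",
]


@dataclass
class FixtureBundle:
    """A named artifact set: topology, weights, stimulus, plus a manifest of
    the properties tests may rely on."""

    name: str
    seed: int
    topology: Topology
    weights: np.ndarray
    stimulus: StimulusSeries
    manifest: dict = field(default_factory=dict)


def make_test_network(seed: int = 0, stimulus_ms: int = 60_000) -> FixtureBundle:
    """The 20-neuron down-scaled network: 16 E / 4 I, out-degree 5.

    Same construction rules as the full model (uniform 1..20 ms excitatory
    delays, 1 ms inhibitory delays, weights 6.0 / -5.0, inhibitory sources
    target excitatory neurons only), so every topology invariant can be
    exercised at debuggable scale.
    """
    rng = np.random.default_rng(seed)
    top = build_topology(n_exc=16, n_inh=4, out_degree=5, seed=rng)
    weights = init_weights(top)
    stim = make_stimulus(stimulus_ms, top.n_neurons, rng)
    manifest = {
        "n_exc": 16,
        "n_inh": 4,
        "out_degree": 5,
        "n_synapses": 20 * 5,
        "inhibitory_targets_below": 16,
        "excitatory_weight": 6.0,
        "inhibitory_weight": -5.0,
    }
    return FixtureBundle("test_network", seed, top, weights, stim, manifest)


def make_poisson_trains(
    n: int, rate_hz: float, duration_ms: float, seed: int = 0
) -> SpikeData:
    """Independent homogeneous Poisson spike trains (continuous times)."""
    if rate_hz <= 0 or duration_ms <= 0:
        raise ValueError("rate and duration must be positive")
    rng = np.random.default_rng(seed)
    rate_per_ms = rate_hz / 1000.0
    trains = []
    for _ in range(n):
        # draw enough exponential ISIs to cover the duration with margin
        n_draw = max(16, int(rate_per_ms * duration_ms * 1.5) + 40)
        t = np.cumsum(rng.exponential(1.0 / rate_per_ms, size=n_draw))
        while t.size and t[-1] < duration_ms:
            t = np.concatenate(
                [t, t[-1] + np.cumsum(rng.exponential(1.0 / rate_per_ms, size=n_draw))]
            )
        trains.append(t[t < duration_ms])
    return SpikeData(trains, duration_ms, resolution_ms=None)


def make_regular_trains(
    n: int, period_ms: float, duration_ms: float, phase_ms: float | None = None
) -> SpikeData:
    """Constant-ISI trains: rate 1/period, local variation exactly 0."""
    if period_ms <= 0:
        raise ValueError("period must be positive")
    phase = period_ms if phase_ms is None else phase_ms
    times = np.arange(phase, duration_ms, period_ms)
    return SpikeData([times.copy() for _ in range(n)], duration_ms, resolution_ms=None)


@dataclass(frozen=True)
class OverflowScenario:
    """A single-neuron drive profile that exposes the s16.15 overflow artifact.

    Under the 3-substep scheme without precise threshold detection, the
    membrane potential overshoots the threshold by orders of magnitude
    before the grid-point test catches it; squaring such values in s16.15
    wraps past 2^16 and the wrap counter registers events.  The same drive
    under the 16-substep precise-threshold scheme stays within range and
    registers none.
    """

    params: IzhikevichParams = RS
    current_pa: float = 800.0
    duration_ms: int = 300
    v0: float = -65.0
    u0: float = -13.0


def make_overflow_scenario() -> OverflowScenario:
    return OverflowScenario()
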