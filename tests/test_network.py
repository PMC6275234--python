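"""Network topology, delayed delivery, buffered STDP, frozen-state replay."""

import numpy as np
import pytest

from polychron.network import (
    ArtifactError,
    ConfigurationError,
    NetworkSimulation,
    ProtocolError,
    STDPParams,
    StimulusSeries,
    Topology,
    apply_batched_updates,
    build_topology,
    init_weights,
    make_stimulus,
    replay_frozen,
    run_network,
    run_with_stdp,
    stdp_increment,
)
from polychron.solvers import RS, SolverSpec, simulate_neuron


class TestTopology:
    def test_default_sizes(self):
        t = build_topology(seed=0)
        assert t.n_syn == 800 * 100 + 200 * 100
        assert t.n_plastic == 800 * 100

    def test_invariants_on_fixture_scale(self, test_net):
        t = test_net.topology
        assert t.n_syn == 20 * 5
        src = t.source_of()
        for i in range(t.n_neurons):
            sl = slice(t.ptr[i], t.ptr[i + 1])
            tgts = t.targets[sl]
            assert len(set(tgts)) == t.out_degree  # no duplicates
            assert i not in tgts  # no autapses
            if i >= t.n_exc:
                assert np.all(tgts < t.n_exc)  # inhibitory -> excitatory only
                assert np.all(t.delays[sl] == 1)
            else:
                assert np.all((1 <= t.delays[sl]) & (t.delays[sl] <= 20))
        assert np.all(src[: t.n_plastic] < t.n_exc)

    def test_same_seed_same_topology(self):
        a = build_topology(16, 4, 5, seed=11)
        b = build_topology(16, 4, 5, seed=11)
        assert np.array_equal(a.targets, b.targets)
        assert np.array_equal(a.delays, b.delays)

    def test_excessive_out_degree_rejected(self):
        with pytest.raises(ConfigurationError):
            build_topology(4, 2, 6, seed=0)

    def test_initial_weights(self, test_net):
        t = test_net.topology
        w = init_weights(t)
        assert np.all(w[: t.n_plastic] == 6.0)
        assert np.all(w[t.n_plastic:] == -5.0)
        t_full = build_topology(seed=3)
        assert init_weights(t_full).sum() == pytest.approx(
            800 * 100 * 6.0 + 200 * 100 * (-5.0)
        )


class TestSTDP:
    @pytest.mark.parametrize(
        "dt, expect",
        [
            (0.0, 0.1),
            (20.0, 0.1 * np.exp(-1.0)),
            (-20.0, -0.12 * np.exp(-1.0)),
        ],
    )
    def test_increment(self, dt, expect):
        assert stdp_increment(dt) == pytest.approx(expect, rel=1e-12)

    def test_batched_update(self, test_net):
        t = test_net.topology
        w = init_weights(t)
        p = STDPParams()
        buf = np.zeros(t.n_syn)
        assert np.array_equal(apply_batched_updates(w, buf, t, p, 1000), w)
        buf[0] = 0.1
        buf[-1] = 42.0  # inhibitory slot: must be ignored
        out = apply_batched_updates(w, buf, t, p, 2000)
        assert out[0] == pytest.approx(6.1)
        assert out[-1] == -5.0
        assert buf[0] == 0.0
        buf[1] = 1e9
        out = apply_batched_updates(out, buf, t, p, 3000)
        assert out[1] == p.w_max  # clipped

    def test_off_schedule_update_rejected(self, test_net):
        t = test_net.topology
        with pytest.raises(ProtocolError):
            apply_batched_updates(
                init_weights(t), np.zeros(t.n_syn), t, STDPParams(), 1500
            )

    def test_weights_stay_within_bounds_during_plastic_run(self, test_net):
        b = run_with_stdp(
            5000, [1000, 3000, 5000], seed=5,
            topology=test_net.topology, stimulus=test_net.stimulus,
        )
        p = STDPParams()
        for w in b.snapshots.values():
            plastic = w[: test_net.topology.n_plastic]
            assert plastic.min() >= p.w_min and plastic.max() <= p.w_max

    def test_stdp_disabled_leaves_weights_at_w0(self, test_net):
        b = run_with_stdp(
            3000, [0, 3000], seed=5, enable_stdp=False,
            topology=test_net.topology, stimulus=test_net.stimulus,
        )
        assert np.array_equal(b.snapshots[0], b.snapshots[3000])
        assert np.array_equal(b.snapshots[0], init_weights(test_net.topology))


def _two_neuron_topology(delay: int) -> Topology:
    ptr = np.array([0, 1, 1], dtype=np.int64)
    return Topology(
        n_exc=2, n_inh=0, out_degree=1, ptr=ptr,
        targets=np.array([1], dtype=np.int32),
        delays=np.array([delay], dtype=np.int32),
    )


class TestDynamics:
    def test_silent_without_drive(self, test_net):
        r = run_network(
            test_net.topology, test_net.weights, None, SolverSpec.euler16(), 500
        )
        assert r.spikes.total_spikes == 0

    def test_delayed_delivery_at_exactly_emission_plus_delay(self):
        top = _two_neuron_topology(delay=15)
        w = np.array([400.0])  # suprathreshold kick on arrival
        sim = NetworkSimulation(top, w, SolverSpec.euler16())
        sim._v[0] = 40.0  # force neuron 0 above threshold
        times, ids = sim.advance(40)
        t0 = times[ids == 0][0]
        t1 = times[ids == 1]
        assert t0 == 1.0  # crossing latched in the first step
        assert t1.size == 1
        # arrival at t0 + 15 drives the crossing during that grid step
        assert t1[0] == t0 + 15 + 1

    def test_no_delivery_at_other_steps(self):
        top = _two_neuron_topology(delay=15)
        w = np.array([0.5])  # subthreshold: must never excite neuron 1
        sim = NetworkSimulation(top, w, SolverSpec.euler16())
        sim._v[0] = 40.0
        times, ids = sim.advance(200)
        assert np.all(ids == 0)

    def test_bit_identical_repetition(self, test_net):
        runs = []
        for _ in range(2):
            r = run_network(
                test_net.topology, test_net.weights, test_net.stimulus,
                SolverSpec.euler16(), 1000,
            )
            runs.append(r.spikes.to_times_ids())
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    @pytest.mark.parametrize("arith", ["float64", "s16.15"])
    def test_network_kernel_matches_scalar_single_neuron(self, arith):
        # a 1-neuron, 0-synapse network driven by the per-step stimulus must
        # reproduce the scalar simulator bitwise
        top = Topology(
            n_exc=1, n_inh=0, out_degree=0,
            ptr=np.zeros(2, dtype=np.int64),
            targets=np.empty(0, dtype=np.int32),
            delays=np.empty(0, dtype=np.int32),
        )
        spec = (
            SolverSpec.euler16() if arith == "float64" else SolverSpec.euler16_fxp()
        )
        stim = StimulusSeries(np.zeros(400, dtype=np.int64), amplitude=5.0)
        sim = NetworkSimulation(top, np.empty(0), spec, stimulus=stim, u0=-13.0)
        times, ids = sim.advance(400)
        trace = simulate_neuron(spec, RS, 5.0, 400, -65.0, -13.0)
        assert np.array_equal(times, trace.spike_times)
        assert sim.membrane[0] == trace.v[-1]

    def test_fxp_with_stdp_rejected(self, test_net):
        with pytest.raises(ConfigurationError):
            NetworkSimulation(
                test_net.topology, test_net.weights, SolverSpec.euler16_fxp(),
                stdp=STDPParams(),
            )


class TestReplay:
    def test_replay_is_pure_and_weight_stationary(self, test_net):
        b = run_with_stdp(
            4000, [4000], seed=9,
            topology=test_net.topology, stimulus=test_net.stimulus,
        )
        w = b.snapshots[4000]
        r1 = replay_frozen(test_net.topology, w, b.stimulus_head,
                           SolverSpec.euler16(), 3000)
        r2 = replay_frozen(test_net.topology, w, b.stimulus_head,
                           SolverSpec.euler16(), 3000)
        assert np.array_equal(r1.spikes.to_times_ids()[0], r2.spikes.to_times_ids()[0])
        assert np.array_equal(r1.weights, w)  # max |dW| over the replay == 0

    def test_float_and_fxp_replays_generally_differ(self, test_net):
        w = init_weights(test_net.topology)
        ra = replay_frozen(test_net.topology, w, test_net.stimulus,
                           SolverSpec.euler16(), 5000)
        rb = replay_frozen(test_net.topology, w, test_net.stimulus,
                           SolverSpec.euler16_fxp(), 5000)
        ta, _ = ra.spikes.to_times_ids()
        tb, _ = rb.spikes.to_times_ids()
        assert ta.size > 0 and tb.size > 0
        assert (ta.size != tb.size) or not np.array_equal(ta, tb)

    def test_zero_weights_and_no_stimulus_are_silent(self, test_net):
        w = np.zeros(test_net.topology.n_syn)
        stim = StimulusSeries(np.full(2000, -1, dtype=np.int64))
        r = replay_frozen(test_net.topology, w, stim, SolverSpec.euler16(), 2000)
        assert r.spikes.total_spikes == 0

    def test_dimension_mismatch_rejected(self, test_net):
        with pytest.raises(ArtifactError):
            replay_frozen(test_net.topology, np.ones(7), test_net.stimulus,
                          SolverSpec.euler16(), 1000)
        with pytest.raises(ArtifactError):
            replay_frozen(
                test_net.topology, init_weights(test_net.topology),
                StimulusSeries(np.zeros(10, dtype=np.int64)),
                SolverSpec.euler16(), 1000,
            )

    def test_stimulus_determinism(self):
        a = make_stimulus(1000, 20, seed=3)
        b = make_stimulus(1000, 20, seed=3)
        assert np.array_equal(a.indices, b.indices)
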