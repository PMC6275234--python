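"""The polychronization network: topology, delays, stimulus, STDP, replay.

The model: 800 regular-spiking excitatory neurons connect with fixed
out-degree 100 to the whole network, with plastic initial weight 6.0 and
integer conduction delays drawn uniformly from 1..20 ms; 200 fast-spiking
inhibitory neurons connect with the same out-degree to excitatory neurons
only, with fixed weight -5.0 and delay 1 ms.  Every 1 ms step a single
uniformly chosen neuron receives a constant 20 pA stimulus.  Excitatory
synapses follow an additive exponential STDP rule (A+ = 0.1, A- = 0.12,
tau = 20 ms) whose increments are buffered and applied to all plastic
synapses simultaneously once per biological second.

The frozen-state protocol: run the network *with* STDP, snapshotting the
weight matrix W(t_i) at selected times and saving the connectivity A, delays
D and the first 60 s of the stimulus series I(t); then replay each frozen
state for 60 s with STDP off under two arithmetic pipelines and compare the
resulting spike recordings statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .qformat import S16_15, q_encode
from .solvers import FS, RS, IzhikevichParams, SolverSpec
from .stats import SpikeData

__all__ = [
    "Topology",
    "STDPParams",
    "StimulusSeries",
    "RunResult",
    "FrozenStateBundle",
    "ConfigurationError",
    "ProtocolError",
    "ArtifactError",
    "build_topology",
    "init_weights",
    "stdp_increment",
    "apply_batched_updates",
    "make_stimulus",
    "NetworkSimulation",
    "run_network",
    "run_with_stdp",
    "replay_frozen",
]


class ConfigurationError(ValueError):
    pass


class ProtocolError(RuntimeError):
    pass


class ArtifactError(ValueError):
    pass


MAX_DELAY_MS = 20
STIM_AMPLITUDE_PA = 20.0


@dataclass
class Topology:
    """Connectivity in CSR-by-source form.

    ``targets[ptr[i]:ptr[i+1]]`` are neuron ``i``'s targets; synapses of
    excitatory sources (indices < ``n_exc``) occupy the first
    ``ptr[n_exc]`` slots, so a synapse is plastic iff its index is below
    ``ptr[n_exc]``.
    """

    n_exc: int
    n_inh: int
    out_degree: int
    ptr: np.ndarray      # int64, shape (n_neurons + 1,)
    targets: np.ndarray  # int32, shape (n_syn,)
    delays: np.ndarray   # int32 ms, shape (n_syn,)

    @property
    def n_neurons(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def n_syn(self) -> int:
        return int(self.ptr[-1])

    @property
    def n_plastic(self) -> int:
        return int(self.ptr[self.n_exc])

    def source_of(self) -> np.ndarray:
        """Per-synapse source index (expanded from CSR)."""
        src = np.empty(self.n_syn, dtype=np.int32)
        for i in range(self.n_neurons):
            src[self.ptr[i]:self.ptr[i + 1]] = i
        return src


@dataclass(frozen=True)
class STDPParams:
    a_plus: float = 0.1
    a_minus: float = 0.12
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    batch_ms: int = 1000
    # weight bounds are not part of the published model description; the
    # values follow the reference implementation family and are configurable
    w_min: float = 0.0
    w_max: float = 10.0

    def __post_init__(self) -> None:
        if min(self.a_plus, self.a_minus, self.tau_plus, self.tau_minus) <= 0:
            raise ConfigurationError("STDP parameters must be positive")
        if self.batch_ms <= 0:
            raise ConfigurationError("batch period must be positive")


@dataclass
class StimulusSeries:
    """One stimulated neuron index per 1 ms step (-1: none), fixed amplitude."""

    indices: np.ndarray  # int64
    amplitude: float = STIM_AMPLITUDE_PA

    @property
    def n_steps(self) -> int:
        return self.indices.size

    def head(self, n_steps: int) -> "StimulusSeries":
        return StimulusSeries(self.indices[:n_steps].copy(), self.amplitude)


def build_topology(
    n_exc: int = 800,
    n_inh: int = 200,
    out_degree: int = 100,
    seed: int | np.random.Generator | None = None,
    *,
    allow_autapses: bool = False,
) -> Topology:
    """Random fixed-out-degree connectivity with uniform integer delays.

    Excitatory sources target any neuron, inhibitory sources target
    excitatory neurons only.  Autapses and duplicate (source, target) pairs
    are excluded by default (sampling without replacement).  Excitatory
    delays are i.i.d. uniform on {1..20} ms, inhibitory delays are 1 ms.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_exc + n_inh
    if out_degree > (n - 1 if not allow_autapses else n):
        raise ConfigurationError("out_degree exceeds the excitatory target pool")
    if out_degree > n_exc:
        raise ConfigurationError("out_degree exceeds the inhibitory target pool")
    targets = np.empty(n * out_degree, dtype=np.int32)
    delays = np.empty(n * out_degree, dtype=np.int32)
    for i in range(n):
        lo = i * out_degree
        if i < n_exc:
            pool = np.arange(n)
            if not allow_autapses:
                pool = np.delete(pool, i)
            tgt = rng.choice(pool, size=out_degree, replace=False)
            dly = rng.integers(1, MAX_DELAY_MS + 1, size=out_degree)
        else:
            tgt = rng.choice(n_exc, size=out_degree, replace=False)
            dly = np.ones(out_degree, dtype=np.int64)
        targets[lo:lo + out_degree] = tgt
        delays[lo:lo + out_degree] = dly
    ptr = np.arange(n + 1, dtype=np.int64) * out_degree
    return Topology(n_exc, n_inh, out_degree, ptr, targets, delays)


def init_weights(t: Topology) -> np.ndarray:
    """Initial weights: 6.0 on every excitatory, -5.0 on every inhibitory synapse."""
    w = np.empty(t.n_syn)
    w[: t.n_plastic] = 6.0
    w[t.n_plastic:] = -5.0
    return w


def stdp_increment(dt: float, params: STDPParams = STDPParams()) -> float:
    """Buffered weight increment for a pairing with time difference ``dt``.

    ``dt`` = last post-synaptic spike time minus last pre-synaptic (arrival)
    time: ``+A+ exp(-dt/tau+)`` for ``dt >= 0``, ``-A- exp(dt/tau-)``
    otherwise.
    """
    if dt >= 0:
        return params.a_plus * float(np.exp(-dt / params.tau_plus))
    return -params.a_minus * float(np.exp(dt / params.tau_minus))


def apply_batched_updates(
    weights: np.ndarray,
    buffer: np.ndarray,
    topology: Topology,
    params: STDPParams,
    clock_ms: int,
) -> np.ndarray:
    """Apply the buffered increments to all plastic synapses simultaneously.

    Only valid at whole batch periods (multiples of 1000 ms by default).
    Plastic weights are clipped to [w_min, w_max]; inhibitory weights are
    never modified; the buffer is zeroed.
    """
    if clock_ms % params.batch_ms != 0:
        raise ProtocolError(
            f"batched update at t={clock_ms} ms, not a multiple of {params.batch_ms}"
        )
    np_l = topology.n_plastic
    out = weights.copy()
    out[:np_l] = np.clip(out[:np_l] + buffer[:np_l], params.w_min, params.w_max)
    buffer[:np_l] = 0.0
    return out


def make_stimulus(
    n_steps: int,
    n_neurons: int,
    seed: int | np.random.Generator | None = None,
    amplitude: float = STIM_AMPLITUDE_PA,
) -> StimulusSeries:
    """Uniformly random stimulated-neuron series, one index per 1 ms step."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return StimulusSeries(rng.integers(0, n_neurons, size=n_steps), amplitude)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

_NETWORK_VARIANTS = ("c_grid", "euler3", "euler16_precise", "euler16_precise_fxp")


def _neuron_params(t: Topology) -> tuple[np.ndarray, ...]:
    def per_neuron(attr):
        arr = np.empty(t.n_neurons)
        arr[: t.n_exc] = getattr(RS, attr)
        arr[t.n_exc:] = getattr(FS, attr)
        return arr

    return tuple(per_neuron(x) for x in "abcd")


def _enc_raw(x: float) -> np.int64:
    return np.int64(q_encode(x, S16_15).raw)


def _enc_array(arr: np.ndarray) -> np.ndarray:
    # C-cast semantics: truncate toward zero, like the scalar encoder
    return np.trunc(arr * 32768.0).astype(np.int64)


class NetworkSimulation:
    """Stateful grid simulation of the network under one solver/arithmetic.

    All state lives in arrays; :meth:`advance` is resumable, so a run can be
    chunked (for weight snapshots) without changing its trajectory.  Bitwise
    deterministic for identical inputs.
    """

    def __init__(
        self,
        topology: Topology,
        weights: np.ndarray,
        solver_spec: SolverSpec,
        *,
        stimulus: StimulusSeries | None = None,
        stdp: STDPParams | None = None,
        v0: float | None = None,
        u0: float | None = None,
    ) -> None:
        if solver_spec.variant == "esr":
            raise NotImplementedError("the ESR solver variant is not implemented")
        if solver_spec.variant not in _NETWORK_VARIANTS:
            raise ConfigurationError(
                f"solver variant {solver_spec.variant!r} cannot drive the network"
            )
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (topology.n_syn,):
            raise ArtifactError("weight vector does not match the topology")
        self.topology = topology
        self.spec = solver_spec
        self.stdp = stdp
        self.fxp = solver_spec.is_fixed_point
        if self.fxp and stdp is not None:
            raise ConfigurationError(
                "plasticity runs in the float64 pipeline only; replay frozen "
                "weights with STDP off in fixed point"
            )
        n = topology.n_neurons
        pa, pb, pc, pd = _neuron_params(topology)
        self._targets64 = topology.targets.astype(np.int64)
        self._delays64 = topology.delays.astype(np.int64)
        self.clock_ms = 0
        self._P = MAX_DELAY_MS + 2
        self._ring_syn = np.zeros((self._P, topology.n_syn), dtype=np.int64)
        self._ring_count = np.zeros(self._P, dtype=np.int64)
        self._wraps = np.zeros(1, dtype=np.int64)
        if stimulus is None:
            stimulus = StimulusSeries(np.empty(0, dtype=np.int64))
        self.stimulus = stimulus
        if v0 is None:
            v0 = RS.c
        vi = np.full(n, float(v0))
        ui = pb * vi if u0 is None else np.full(n, float(u0))

        if self.fxp:
            self._v = _enc_array(vi)
            self._u = _enc_array(ui)
            self._w_raw = _enc_array(weights)
            prescaled = solver_spec.uses_prescaled_ordering
            self._prescaled = prescaled
            scale = 256.0 if prescaled else 1.0
            self._pa = _enc_array(pa * scale)
            self._pb = _enc_array(pb * scale)
            self._pc = _enc_array(pc)
            self._pd = _enc_array(pd)
            self._quad = _enc_raw(10.24 if prescaled else 0.04)
            self._h = _enc_raw(1.0 / solver_spec.substeps)
            self._I_buf = np.zeros(n, dtype=np.int64)
            self.weights = weights  # reference copy of the imported doubles
        else:
            self._v = vi
            self._u = ui
            self.weights = weights.copy()
            self._pa, self._pb, self._pc, self._pd = pa, pb, pc, pd
            self._I_buf = np.zeros(n)
            self._last_spike = np.full(n, _kernels.NO_TIME)
            self._last_arrival = np.full(topology.n_syn, _kernels.NO_TIME)
            self._dw = np.zeros(topology.n_syn)
            self._mode = (
                _kernels.MODE_PRECISE
                if solver_spec.precise_threshold
                else _kernels.MODE_GRID
            )
            # plastic in-synapse lists, CSR by target
            plastic_idx = np.arange(topology.n_plastic, dtype=np.int64)
            tgt = topology.targets[: topology.n_plastic].astype(np.int64)
            order = np.argsort(tgt, kind="stable")
            self._in_syn = plastic_idx[order]
            self._in_ptr = np.zeros(n + 1, dtype=np.int64)
            np.add.at(self._in_ptr, tgt + 1, 1)
            self._in_ptr = np.cumsum(self._in_ptr)

    # -- properties ------------------------------------------------------
    @property
    def wrap_count(self) -> int:
        return int(self._wraps[0])

    @property
    def membrane(self) -> np.ndarray:
        """Current membrane potentials, decoded to float."""
        return self._v * 2.0 ** -15 if self.fxp else self._v.copy()

    def current_weights(self) -> np.ndarray:
        """Weights as floats (decoded from raw words in fixed point)."""
        if self.fxp:
            return self._w_raw * 2.0 ** -15
        return self.weights.copy()

    def stdp_buffer(self) -> np.ndarray:
        if self.fxp:
            raise ConfigurationError("no plasticity state in the fixed-point pipeline")
        return self._dw.copy()

    # -- stepping --------------------------------------------------------
    def advance(
        self, n_steps: int, record: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance ``n_steps`` grid steps; return (times, neuron_ids) emitted."""
        stim = self.stimulus.indices
        lo = self.clock_ms
        seg = np.full(n_steps, -1, dtype=np.int64)
        avail = max(0, min(n_steps, stim.size - lo))
        if avail:
            seg[:avail] = stim[lo:lo + avail]
        cap = max(4096, self.topology.n_neurons * 64)
        rec_t = np.empty(cap)
        rec_i = np.empty(cap, dtype=np.int64)
        n_rec = 0
        done = 0
        while done < n_steps:
            if self.fxp:
                step_done, n_rec = _kernels.run_fxp(
                    self._v, self._u, self.clock_ms,
                    self._pa, self._pb, self._pc, self._pd,
                    self.topology.ptr, self._targets64, self._delays64, self._w_raw,
                    self._ring_syn, self._ring_count,
                    seg[done:], _enc_raw(self.stimulus.amplitude),
                    self.spec.precise_threshold, self.spec.substeps, self._prescaled,
                    self._quad, self._h,
                    n_steps - done, record, rec_t, rec_i, n_rec,
                    self._I_buf, self._wraps,
                )
            else:
                stdp = self.stdp
                step_done, n_rec = _kernels.run_float(
                    self._v, self._u, self.clock_ms,
                    self._pa, self._pb, self._pc, self._pd,
                    self.topology.ptr, self._targets64, self._delays64, self.weights,
                    self.topology.n_plastic,
                    self._in_ptr, self._in_syn,
                    self._ring_syn, self._ring_count,
                    self._last_spike, self._last_arrival, self._dw,
                    stdp is not None,
                    stdp.a_plus if stdp else 0.0,
                    stdp.a_minus if stdp else 0.0,
                    stdp.tau_plus if stdp else 1.0,
                    stdp.tau_minus if stdp else 1.0,
                    stdp.batch_ms if stdp else 10**9,
                    stdp.w_min if stdp else 0.0,
                    stdp.w_max if stdp else 0.0,
                    seg[done:], self.stimulus.amplitude,
                    self._mode, self.spec.substeps,
                    n_steps - done, record, rec_t, rec_i, n_rec,
                    self._I_buf,
                )
            done += step_done
            self.clock_ms += step_done
            if done < n_steps:  # record buffer was too small: grow and resume
                rec_t = np.concatenate([rec_t, np.empty(rec_t.size)])
                rec_i = np.concatenate([rec_i, np.empty(rec_i.size, dtype=np.int64)])
        return rec_t[:n_rec].copy(), rec_i[:n_rec].copy()

    def step(self) -> tuple[np.ndarray, np.ndarray]:
        """One 1 ms grid step; returns the spikes emitted at this step."""
        return self.advance(1)


@dataclass
class RunResult:
    spikes: SpikeData
    weights: np.ndarray
    wrap_count: int
    simulation: NetworkSimulation


def run_network(
    topology: Topology,
    weights: np.ndarray,
    stimulus: StimulusSeries | None,
    solver_spec: SolverSpec,
    duration_ms: int,
    *,
    stdp: STDPParams | None = None,
    record: bool = True,
) -> RunResult:
    """Run the network for ``duration_ms`` from the customary initial state."""
    sim = NetworkSimulation(
        topology, weights, solver_spec, stimulus=stimulus, stdp=stdp
    )
    times, ids = sim.advance(int(duration_ms), record=record)
    # a crossing in the final grid step is stamped at t = duration, outside
    # the half-open recording window; it belongs to the next window
    keep = times < duration_ms
    spikes = SpikeData.from_times_ids(
        times[keep], ids[keep], topology.n_neurons, float(max(duration_ms, 1))
    )
    return RunResult(spikes, sim.current_weights(), sim.wrap_count, sim)


@dataclass
class FrozenStateBundle:
    """Everything needed to replay frozen network states (the A/D/W/I set)."""

    topology: Topology
    initial_weights: np.ndarray
    snapshots: dict[int, np.ndarray]  # clock ms -> weight vector
    stimulus_head: StimulusSeries     # first 60 s of the stimulus series
    stdp: STDPParams
    seed: int | None = None
    spikes: SpikeData | None = None


def run_with_stdp(
    duration_ms: int,
    snapshot_times_ms: list[int],
    seed: int | None = None,
    solver_spec: SolverSpec | None = None,
    *,
    topology: Topology | None = None,
    weights: np.ndarray | None = None,
    stdp: STDPParams | None = None,
    stimulus: StimulusSeries | None = None,
    record: bool = False,
    stimulus_head_ms: int = 60_000,
    enable_stdp: bool = True,
) -> FrozenStateBundle:
    """Plastic phase of the frozen-state protocol.

    Builds (or accepts) the network, runs it with STDP under the random
    single-neuron stimulus, snapshots the weight vector at the requested
    times (taken *after* a coincident batch update), and keeps the first
    60 s of the stimulus series for later replays.
    """
    solver_spec = solver_spec or SolverSpec.euler16()
    stdp = stdp or STDPParams()
    rng = np.random.default_rng(seed)
    if topology is None:
        topology = build_topology(seed=rng)
    if weights is None:
        weights = init_weights(topology)
    if stimulus is None:
        stimulus = make_stimulus(int(duration_ms), topology.n_neurons, rng)
    times = sorted(int(t) for t in snapshot_times_ms)
    if times and (times[0] < 0 or times[-1] > duration_ms):
        raise ConfigurationError("snapshot times must lie within the run")
    sim = NetworkSimulation(
        topology, weights, solver_spec, stimulus=stimulus,
        stdp=stdp if enable_stdp else None,
    )
    snapshots: dict[int, np.ndarray] = {}
    all_t: list[np.ndarray] = []
    all_i: list[np.ndarray] = []
    prev = 0
    for t_snap in times:
        if t_snap > prev:
            rt, ri = sim.advance(t_snap - prev, record=record)
            all_t.append(rt)
            all_i.append(ri)
            prev = t_snap
        snapshots[t_snap] = sim.current_weights()
    if prev < duration_ms:
        rt, ri = sim.advance(int(duration_ms) - prev, record=record)
        all_t.append(rt)
        all_i.append(ri)
    spikes = None
    if record:
        rt = np.concatenate(all_t) if all_t else np.empty(0)
        ri = np.concatenate(all_i) if all_i else np.empty(0, dtype=np.int64)
        keep = rt < duration_ms
        spikes = SpikeData.from_times_ids(
            rt[keep], ri[keep], topology.n_neurons, float(duration_ms)
        )
    return FrozenStateBundle(
        topology,
        np.asarray(weights, dtype=float),
        snapshots,
        stimulus.head(min(stimulus_head_ms, stimulus.n_steps)),
        stdp,
        seed if isinstance(seed, int) else None,
        spikes,
    )


def replay_frozen(
    topology: Topology,
    weights: np.ndarray,
    stimulus: StimulusSeries,
    solver_spec: SolverSpec,
    duration_ms: int = 60_000,
) -> RunResult:
    """Replay one frozen state for 60 s with STDP off; weights stay constant.

    A pure function of its artifacts: identical inputs give bit-identical
    spike recordings.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (topology.n_syn,):
        raise ArtifactError("weight vector does not match the topology")
    if stimulus.n_steps < duration_ms:
        raise ArtifactError(
            f"stimulus covers {stimulus.n_steps} ms < replay duration {duration_ms} ms"
        )
    return run_network(
        topology, weights, stimulus, solver_spec, duration_ms, stdp=None
    )
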