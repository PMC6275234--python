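# Methods

## Model and scope

The simulated system is the classic polychronization network: 800
regular-spiking (RS) excitatory and 200 fast-spiking (FS) inhibitory
Izhikevich neurons on a 1 ms simulation grid, sparse fixed-out-degree
connectivity with integer conduction delays, delta-current synapses, a
one-neuron-per-millisecond random 20 pA stimulus, and additive STDP with
batched (once per biological second) weight application.  The package's
purpose is not the biology of this network but *model substantiation*:
running the same mathematical model under different numerical pipelines and
quantifying the statistical agreement of the resulting activity.  Everything
needed for that workflow — solver variants, bit-exact s16.15 fixed-point
emulation, frozen-state replay, spike statistics — is first-class, tested
code.

Out of scope by design: execution on actual neuromorphic hardware, the
closed-form "ESR" solver used by one hardware software stack (recognised as
a variant name, deliberately unimplemented), and the detection/counting of
polychronous groups.

## Numerical schemes

All grid solvers use the semi-implicit (symplectic) forward Euler ordering:
u is always advanced from the already-updated v.

* **`c_grid`** — v advanced in two sequential 0.5 ms half-steps, u in one
  1 ms step; threshold tested at grid points only, *before* integrating.
  Because the spike onset is a near-vertical slope, grid-locked detection
  lets v overshoot the 30 mV threshold by orders of magnitude (values in
  the thousands under strong drive).  The overshoot feeds back through u
  and delays all subsequent spikes; the per-spike lag against the adaptive
  reference grows monotonically.
* **`euler3`** — identical structure with three h/3 v-substeps.  The extra
  substep increases the chance that an overshooting v is squared, which in
  s16.15 arithmetic wraps past 2^16 and produces spike artifacts.
* **`euler16_precise`** — both equations sub-stepped at h/16 = 0.0625 ms
  (a power of two: exactly representable in s16.15 and applied as a
  multiplication, never a division), threshold tested after every substep
  with the reset applied immediately.  Multiple crossings within one grid
  step merge into one emitted spike.
* **`euler16_precise_fxp`** — the same scheme in emulated s16.15 with the
  overflow-safe evaluation order described below.
* **`reference_adaptive`** — scipy's adaptive embedded Runge–Kutta 4(5)
  (Dormand–Prince) with `atol` = 1e-6 (the configurable target accuracy),
  `rtol` = 1e-12 so the absolute tolerance governs, and `max_step` = 1 ms
  so no threshold crossing can be stepped over.  The v = 30 crossing is a
  terminal event located by root-finding on the dense output (well below
  1e-6 ms), the reset is applied at the event, and integration restarts;
  spike times are continuous.  Tightening `atol` to 1e-8 moves spike times
  by < 1e-3 ms (tested).

**Spike timestamp convention.**  A crossing detected during the grid step
ending at grid point t is stamped t — for grid-point detection this is the
step at whose start v was found at/above threshold, for per-substep
detection the grid point closing the crossing step.  The two conventions
therefore stamp the same crossing identically, spikes are delivered at
stamp + delay, and a grid solver's spike time can never precede the
continuous reference's for the same crossing.

**Initial conditions.**  The paper-family default is (v, u) = (c, b·c) =
(−65, −13), used by the network simulator.  The single-neuron verification
protocol (constant 5 pA, 500 ms, five reference spikes, growing Euler lag)
instead starts at the post-reset state (c, b·c + d) = (−65, −5): a
stimulus-response trace conventionally begins where a spike cycle begins,
and the first-spike latency from this state (≈ 87 ms) is what yields five
spikes in 500 ms.  Both are configurable everywhere.

## Fixed-point emulation

`polychron.qformat` models 32-bit signed Q-format words (s16.15 and s8.23;
range −2^i … 2^i − 2^−f):

* **Conversion** truncates toward zero (C cast semantics; `floor` mode
  available).  0.04 → raw 1310 (0x0000051E) in s16.15, decoding to
  0.039978…, a loss that noticeably delays spikes.
* **Multiplication** models an ARM long-multiply: exact 64-bit product of
  the raw words, one arithmetic right shift by f, wrap to 32 bits.  The
  intermediate width is a package choice; truncation makes the operation
  non-associative, so expression order is caller-specified and never
  reordered.
* **Overflow wraps** (never saturates) and raises no flag; an optional
  diagnostic counter tallies wrap events so overflow artifacts can be
  demonstrated and excluded.

The overflow-safe ("pre-scaled") evaluation of the quadratic holds 0.04 as
10.24 = 0.04·2^8 (s8.23-equivalent fractional precision inside an s16.15
word) and evaluates strictly as `((10.24·v) >> 8) · v + 5·v + 140 − u + I`;
multiplying 10.24 by v² directly could overflow.  The neuron constants a
and b are likewise held pre-scaled by 2^8 with a compensating 8-bit shift
at use; the factor 2^8 mirrors the 10.24 treatment (the scale itself is a
package choice).

A documented print-precision quirk: evaluating the degraded-coefficient
slope at v = −75 gives −10.1235962 with the exact fraction 1310/32768 and
−10.1236375 with the 8-digit decimal 0.03997802, while the figure commonly
quoted is −10.1236357; the three agree to ~4·10⁻⁶ relative and the package
reports its exactly-computed value.  Similarly, the full fixed-point pre-scaled
evaluation at v = −75 lands on exactly −10.0 (the 8-bit shift of
−767.99927 truncates to −3.0 exactly), within 2·10⁻⁵ relative of the
decimal-arithmetic value −10.00021375.

## Network implementation

The inner loops are numba-compiled kernels (one float64, one s16.15)
sharing a per-step structure: deliver arrivals from a ring buffer of
synapse indices, advance all neurons one grid step, process emitted spikes
(record, pair for STDP, enqueue at emission + delay), and apply the batched
weight update at each whole second.  State lives in plain arrays, so runs
are resumable (for weight snapshots) without perturbing the trajectory,
and everything is bitwise deterministic for identical inputs.  The
fixed-point kernel operates on raw two's-complement words in int64 (32-bit
products fit exactly) and mirrors the scalar `qformat` machinery; a test
pins bitwise agreement between a 1-neuron network and the scalar
single-neuron simulator in both arithmetics.

**Topology.**  Out-neighbour sets are sampled without replacement (no
autapses, no duplicate synapses — the reference implementation family's
convention; configurable).  Excitatory delays are drawn i.i.d. uniform on
{1..20} ms as the model description states, *not* partitioned evenly
across delays as one historical implementation did.

**STDP conventions.**  Pairing uses the single most recent opposing event.
The pre-synaptic event is timed at *arrival* (emission + delay).  On a
post-synaptic spike at t, every plastic in-synapse with a past arrival at
t_a contributes +A₊·exp(−(t−t_a)/τ₊) to the buffer (Δt = 0 included); on an
arrival at t_a, the synapse contributes −A₋·exp((t_post−t_a)/τ₋) against
the target's last spike, which by in-step ordering (arrivals processed
before updates) is strictly earlier except for the Δt = 0 coincidence,
which takes the potentiation branch per the rule's Δt ≥ 0 case.  Buffered
increments are applied simultaneously to all plastic synapses at each
whole second, clipped to [w_min, w_max] = [0, 10] — bounds that are *not*
part of the published model description; they follow the reference
implementation family and are configurable.  Weight snapshots that
coincide with a batch boundary are taken after the update.  Plasticity is
implemented in the float64 pipeline only: in the replay protocol the
plastic phase always runs in double precision and fixed point is used only
to replay frozen (constant) weights.

**Fixed-point weight import** truncates each double weight toward zero at
2^−15 resolution, so |w| never grows in conversion (negative weights
become slightly less negative — one of the residual discrepancy sources
between the pipelines).

## Frozen-state substantiation protocol

Default study conditions, chosen so the full workflow runs on one CPU in
minutes: a 600-second plastic phase (euler16_precise, float64) with weight
snapshots every 120 s (five network states), saving A, D, W(t_i) and the
first 60 s of the stimulus series; then 60-second replays of a frozen
state with STDP off under the float64 and s16.15 pipelines; then the
statistical comparison.  The full-length multi-hour plastic phase is the
same code path with a larger duration argument.

Measures, all computed through one shared code path for both inputs:

* **FR** — per-neuron spike count / duration (Hz).
* **LV** — local variation, 3/(m−1)·Σ((Iₖ−Iₖ₊₁)/(Iₖ+Iₖ₊₁))²; the standard
  definition is pinned here because the protocol description only cites
  it.  0 for regular trains, 1 in expectation for Poisson trains (both are
  test oracles).  Neurons with < 3 spikes are excluded and counted.
* **CC** — Pearson correlation of 2 ms-binned counts over all unordered
  pairs; the final partial bin is dropped; zero-variance trains are
  excluded and counted rather than silently dropped.
* **Effect size** — pooled-SD Cohen's d (the protocol fixes only "the
  normalized difference between the means"); zero pooled variance yields 0
  for equal means and signed infinity otherwise.  Histograms use 70 equal
  bins over the union of both samples' ranges.

## What the synthetic inputs do and do not show

The generators reproduce the model's own study conditions (sizes, rates,
weights, stimulus), a 20-neuron down-scaled network for debuggable-scale
tests, statistical oracle trains (regular, Poisson), and a strong-drive
(800 pA) single-neuron scenario constructed so the coarse fixed-point
scheme wraps and the precise scheme does not.  They contain no recorded
biological data; passing tests demonstrate internal consistency of the two
executable pipelines and correctness of the arithmetic and statistics, not
that the model describes cortex, and the scaled 600 s plastic phase probes
an earlier, less-structured stage of weight evolution than a multi-hour
run would.

## Known limitations

* The adaptive reference is Dormand–Prince 4(5) rather than Fehlberg 4(5);
  both are embedded 4(5) pairs and the result is controlled by the 1e-6
  absolute tolerance (invariance under tightening is tested).
* Spike emission is grid-locked for all grid solvers; sub-millisecond
  emission is intentionally not modelled.
* s8.23 is provided for arithmetic demonstrations only; network state is
  always s16.15 in the fixed-point pipeline.
* Whether the random stimulus may re-select the same neuron in consecutive
  steps is unspecified in the protocol; selection here is i.i.d. uniform.
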