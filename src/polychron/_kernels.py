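"""Numba-compiled inner loops for the network simulator.

One kernel per arithmetic (float64 / emulated s16.15).  Both share the same
per-step structure so float and fixed-point runs are directly comparable:

1.  deliver spikes arriving this step (ring buffer of synapse indices);
    record per-synapse arrival times and, with plasticity on, the depression
    increment against the target's last spike;
2.  advance every neuron one 1 ms grid step with the configured scheme
    (grid-point threshold test for the historical schemes, per-substep test
    with immediate reset for the precise schemes);
3.  for every emitted spike: record it, update pairing bookkeeping, apply
    the potentiation increment for its plastic in-synapses, and enqueue its
    out-synapses at emission time + delay;
4.  at each whole biological second, apply the buffered weight changes to
    all plastic synapses simultaneously (clipped to bounds) and clear the
    buffer.

Spike timestamps: grid-point detection stamps the grid time at which v was
found at/above threshold; per-substep detection stamps the grid point ending
the step during which v crossed.  Either way the stamp is the grid point at
the end of the crossing step, so the two conventions are consistent.

The fixed-point kernel mirrors the scalar s16.15 machinery in
``polychron.qformat``/``polychron.solvers`` on raw two's-complement words
held in int64 (products of 32-bit words fit exactly); a test pins bitwise
agreement between the two paths.  All overflow wraps; wrap events are
tallied.  Plasticity is float64-only (the plastic phase of the protocol runs
in the double-precision pipeline).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NO_TIME = -1.0e12  # sentinel: no spike/arrival seen yet

# neuron update modes
MODE_GRID = 0      # threshold at grid point, v sub-stepped, u one full step
MODE_PRECISE = 1   # v and u sub-stepped, threshold after every substep

_F15 = 15
_HALF32 = np.int64(1) << np.int64(31)
_MASK32 = (np.int64(1) << np.int64(32)) - np.int64(1)


@njit(cache=True, inline="always")
def _wrap32(x, wraps):
    w = ((x + _HALF32) & _MASK32) - _HALF32
    if w != x:
        wraps[0] += 1
    return w


@njit(cache=True, inline="always")
def _qmul(a, b, wraps):
    return _wrap32((a * b) >> _F15, wraps)


@njit(cache=True)
def run_float(
    # state
    v, u, clock0,
    # per-neuron parameters
    pa, pb, pc, pd,
    # topology (CSR by source) and weights
    ptr, targets, delays, weights, n_exc_syn,
    # plastic in-synapse CSR (by target)
    in_ptr, in_syn,
    # delivery ring: synapse-index lists per slot
    ring_syn, ring_count,
    # plasticity state
    last_spike, last_arrival, dw,
    stdp_on, a_plus, a_minus, tau_plus, tau_minus, batch_ms, w_min, w_max,
    # stimulus: neuron index per step (-1 = none), injected amplitude
    stim_idx, stim_amp,
    # solver
    mode, substeps,
    # run control / outputs
    n_steps, record, rec_times, rec_ids, n_rec0,
    I_buf,
):
    """Advance ``n_steps`` grid steps in float64.  Returns (steps_done, n_rec).

    Stops early (at a step boundary) if the spike record buffer could not
    hold a worst-case step; the caller grows the buffer and resumes.
    """
    n = v.shape[0]
    P = ring_syn.shape[0]
    theta = 30.0
    h = 1.0 / substeps
    n_rec = n_rec0
    for k in range(n_steps):
        t = clock0 + k
        if record and n_rec + n > rec_times.shape[0]:
            return k, n_rec
        # 1. deliveries
        for i in range(n):
            I_buf[i] = 0.0
        slot = t % P
        for j in range(ring_count[slot]):
            s = ring_syn[slot, j]
            tgt = targets[s]
            I_buf[tgt] += weights[s]
            if stdp_on and s < n_exc_syn:
                lp = last_spike[tgt]
                if lp > NO_TIME:
                    dw[s] -= a_minus * np.exp((lp - t) / tau_minus)
            last_arrival[s] = t
        ring_count[slot] = 0
        si = stim_idx[k]
        if si >= 0:
            I_buf[si] += stim_amp
        # 2 & 3. neuron updates and spike handling
        for i in range(n):
            spike_time = NO_TIME
            vi = v[i]
            ui = u[i]
            if mode == MODE_GRID:
                if vi >= theta:
                    spike_time = float(t)
                    vi = pc[i]
                    ui = ui + pd[i]
                for _ in range(substeps):
                    vi += h * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + I_buf[i])
                ui += pa[i] * (pb[i] * vi - ui)
            else:  # MODE_PRECISE
                crossed = False
                for _ in range(substeps):
                    vi += h * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + I_buf[i])
                    ui += h * (pa[i] * (pb[i] * vi - ui))
                    if vi >= theta:
                        crossed = True
                        vi = pc[i]
                        ui = ui + pd[i]
                if crossed:
                    spike_time = float(t + 1)
            v[i] = vi
            u[i] = ui
            if spike_time > NO_TIME:
                if record:
                    rec_times[n_rec] = spike_time
                    rec_ids[n_rec] = i
                    n_rec += 1
                last_spike[i] = spike_time
                if stdp_on:
                    for jj in range(in_ptr[i], in_ptr[i + 1]):
                        s = in_syn[jj]
                        la = last_arrival[s]
                        if la > NO_TIME:
                            dw[s] += a_plus * np.exp(-(spike_time - la) / tau_plus)
                for s in range(ptr[i], ptr[i + 1]):
                    slot2 = (int(spike_time) + delays[s]) % P
                    ring_syn[slot2, ring_count[slot2]] = s
                    ring_count[slot2] += 1
        # 4. batched plasticity
        if stdp_on and (t + 1) % batch_ms == 0:
            for s in range(n_exc_syn):
                wnew = weights[s] + dw[s]
                if wnew < w_min:
                    wnew = w_min
                elif wnew > w_max:
                    wnew = w_max
                weights[s] = wnew
                dw[s] = 0.0
    return n_steps, n_rec


@njit(cache=True)
def run_fxp(
    # state: raw s16.15 words in int64
    v, u, clock0,
    # per-neuron raw parameters; pa/pb pre-scaled by 2**8 when prescaled is on
    pa, pb, pc, pd,
    ptr, targets, delays, weights_raw,
    ring_syn, ring_count,
    stim_idx, stim_amp_raw,
    # solver: quad_const = enc(10.24) with prescaled, enc(0.04) otherwise
    precise, substeps, prescaled, quad_const, h_raw,
    n_steps, record, rec_times, rec_ids, n_rec0,
    I_buf, wraps,
):
    """Advance ``n_steps`` grid steps in emulated s16.15 (no plasticity)."""
    n = v.shape[0]
    P = ring_syn.shape[0]
    theta = np.int64(30) << np.int64(_F15)
    c5 = np.int64(5) << np.int64(_F15)
    c140 = np.int64(140) << np.int64(_F15)
    n_rec = n_rec0
    for k in range(n_steps):
        t = clock0 + k
        if record and n_rec + n > rec_times.shape[0]:
            return k, n_rec
        for i in range(n):
            I_buf[i] = 0
        slot = t % P
        for j in range(ring_count[slot]):
            s = ring_syn[slot, j]
            I_buf[targets[s]] = _wrap32(I_buf[targets[s]] + weights_raw[s], wraps)
        ring_count[slot] = 0
        si = stim_idx[k]
        if si >= 0:
            I_buf[si] = _wrap32(I_buf[si] + stim_amp_raw, wraps)
        for i in range(n):
            spike_time = -1
            vi = v[i]
            ui = u[i]
            Ii = I_buf[i]
            if precise:
                crossed = False
                for _ in range(substeps):
                    # dv/dt in the mandated operation order
                    if prescaled:
                        tq = _qmul(quad_const, vi, wraps)   # 10.24 * v
                        tq = tq >> 8                        # * 0.00390625
                        tq = _qmul(tq, vi, wraps)           # * v
                    else:
                        tq = _qmul(quad_const, vi, wraps)
                        tq = _qmul(tq, vi, wraps)
                    tq = _wrap32(tq + _qmul(c5, vi, wraps), wraps)
                    tq = _wrap32(tq + c140, wraps)
                    tq = _wrap32(tq - ui, wraps)
                    tq = _wrap32(tq + Ii, wraps)
                    vi = _wrap32(vi + _qmul(h_raw, tq, wraps), wraps)
                    if prescaled:
                        bv = _qmul(pb[i], vi, wraps) >> 8
                        du = _qmul(pa[i], _wrap32(bv - ui, wraps), wraps) >> 8
                    else:
                        bv = _qmul(pb[i], vi, wraps)
                        du = _qmul(pa[i], _wrap32(bv - ui, wraps), wraps)
                    ui = _wrap32(ui + _qmul(h_raw, du, wraps), wraps)
                    if vi >= theta:
                        crossed = True
                        vi = pc[i]
                        ui = _wrap32(ui + pd[i], wraps)
                if crossed:
                    spike_time = t + 1
            else:
                if vi >= theta:
                    spike_time = t
                    vi = pc[i]
                    ui = _wrap32(ui + pd[i], wraps)
                for _ in range(substeps):
                    if prescaled:
                        tq = _qmul(quad_const, vi, wraps)
                        tq = tq >> 8
                        tq = _qmul(tq, vi, wraps)
                    else:
                        tq = _qmul(quad_const, vi, wraps)
                        tq = _qmul(tq, vi, wraps)
                    tq = _wrap32(tq + _qmul(c5, vi, wraps), wraps)
                    tq = _wrap32(tq + c140, wraps)
                    tq = _wrap32(tq - ui, wraps)
                    tq = _wrap32(tq + Ii, wraps)
                    vi = _wrap32(vi + _qmul(h_raw, tq, wraps), wraps)
                if prescaled:
                    bv = _qmul(pb[i], vi, wraps) >> 8
                    du = _qmul(pa[i], _wrap32(bv - ui, wraps), wraps) >> 8
                else:
                    bv = _qmul(pb[i], vi, wraps)
                    du = _qmul(pa[i], _wrap32(bv - ui, wraps), wraps)
                ui = _wrap32(ui + du, wraps)
            v[i] = vi
            u[i] = ui
            if spike_time >= 0:
                if record:
                    rec_times[n_rec] = float(spike_time)
                    rec_ids[n_rec] = i
                    n_rec += 1
                for s in range(ptr[i], ptr[i + 1]):
                    slot2 = (spike_time + delays[s]) % P
                    ring_syn[slot2, ring_count[slot2]] = s
                    ring_count[slot2] += 1
    return n_steps, n_rec
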