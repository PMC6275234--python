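"""Single-neuron dynamics: update schemes, threshold handling, references."""

import numpy as np
import pytest

from polychron.qformat import S16_15, q_decode, q_encode
from polychron.solvers import (
    FS,
    RS,
    FxpNeuron,
    NeuronState,
    SolverSpec,
    apply_reset,
    fxp_quadratic,
    reference_adaptive,
    rhs_u,
    rhs_v,
    simulate_neuron,
    spike_lag,
    step_c_grid,
    step_fxp_prescaled,
    step_substepped,
)

# the single-neuron verification protocol starts the neuron at its
# post-reset state (c, b*c + d); see docs/methods.md
PROTO_INIT = (-65.0, -5.0)


class TestRightHandSides:
    @pytest.mark.parametrize(
        "v, u, I, expect",
        [(-75.0, 0.0, 0.0, -10.0), (30.0, 0.0, 0.0, 326.0), (-70.0, -14.0, 0.0, 0.0)],
    )
    def test_rhs_v(self, v, u, I, expect):
        assert rhs_v(v, u, I) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize(
        "v, u, p", [(-65.0, -13.0, RS), (-70.0, -14.0, RS), (0.0, 0.0, FS)]
    )
    def test_rhs_u_nullcline(self, v, u, p):
        assert rhs_u(v, u, p) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "state, p, expect",
        [
            (NeuronState(31.0, 0.0), RS, NeuronState(-65.0, 8.0)),
            (NeuronState(29.9, 0.0), RS, NeuronState(29.9, 0.0)),
            (NeuronState(30.0, 5.0), FS, NeuronState(-65.0, 7.0)),
        ],
    )
    def test_reset(self, state, p, expect):
        assert apply_reset(state, p) == expect


class TestGridSteppers:
    def test_c_grid_hand_evaluated_step(self):
        # two 0.5 ms half-steps for v, one full step for u, from (-75, 0)
        s, spiked = step_c_grid(NeuronState(-75.0, 0.0), 0.0, RS)
        assert not spiked
        assert s.v == pytest.approx(-82.0, abs=1e-12)
        assert s.u == pytest.approx(-0.328, abs=1e-12)

    def test_c_grid_threshold_first_then_integrate(self):
        s, spiked = step_c_grid(NeuronState(31.0, 0.0), 0.0, RS)
        assert spiked
        # integration proceeded from the reset state (-65, 8)
        s2, _ = step_substepped(
            NeuronState(-65.0, 8.0), 0.0, RS,
            SolverSpec("euler3", substeps=2, precise_threshold=False),
        )
        assert s.v == pytest.approx(s2.v)
        assert s.u == pytest.approx(s2.u)

    def test_fixed_point_of_dynamics_is_stationary(self):
        fp = NeuronState(-70.0, -14.0)
        for step in (
            lambda s: step_c_grid(s, 0.0, RS),
            lambda s: step_substepped(s, 0.0, RS, SolverSpec.euler16()),
        ):
            out, spiked = step(fp)
            assert not spiked
            assert out.v == pytest.approx(fp.v, abs=1e-12)
            assert out.u == pytest.approx(fp.u, abs=1e-12)

    def test_single_substep_reduces_to_plain_euler(self):
        s0 = NeuronState(-60.0, -12.0)
        spec = SolverSpec("euler16_precise", substeps=1, precise_threshold=True)
        out, _ = step_substepped(s0, 3.0, RS, spec)
        v1 = s0.v + rhs_v(s0.v, s0.u, 3.0)
        u1 = s0.u + rhs_u(v1, s0.u, RS)
        assert out.v == pytest.approx(v1)
        assert out.u == pytest.approx(u1)

    def test_first_spike_matches_fine_step_oracle(self):
        # brute-force h/1000 Euler locates the first crossing; the h/16
        # precise-threshold scheme must agree to within one grid step
        v, u = -65.0, -13.0
        h = 1e-3
        t_fine = None
        for k in range(500_000):
            v += h * rhs_v(v, u, 5.0)
            u += h * rhs_u(v, u, RS)
            if v >= 30.0:
                t_fine = (k + 1) * h
                break
        assert t_fine is not None
        tr = simulate_neuron(SolverSpec.euler16(), RS, 5.0, 500, -65.0, -13.0)
        assert abs(tr.spike_times[0] - t_fine) <= 1.0


class TestFixedPointEvaluation:
    def test_quadratic_worked_examples(self):
        assert fxp_quadratic(mode="float") == -10.0
        # the s16.15 coefficient error makes the slope noticeably more negative
        assert fxp_quadratic(mode="s16.15") == pytest.approx(-10.1236357, rel=1e-4)
        assert fxp_quadratic(mode="s8.23") == pytest.approx(-10.00021375, rel=1e-4)
        assert fxp_quadratic(mode="prescaled") == pytest.approx(-10.00021375, rel=1e-4)

    def test_error_ordering_of_coefficient_precisions(self):
        exact = fxp_quadratic(mode="float")
        naive = fxp_quadratic(mode="s16.15")
        prescaled = fxp_quadratic(mode="prescaled")
        assert naive < exact
        assert naive < prescaled <= exact

    def test_quadratic_vanishes_at_zero(self):
        assert abs(fxp_quadratic(0.0, 0.0, 0.0, mode="s16.15") - 140.0) < 2**-15
        assert abs(fxp_quadratic(0.0, 0.0, 0.0, mode="prescaled") - 140.0) < 2**-15

    def test_step_fxp_prescaled_spikes_and_resets(self):
        s, spiked = step_fxp_prescaled(NeuronState(29.9, -13.0), 20.0, RS)
        assert spiked
        assert s.v <= 30.0  # post-reset, already re-integrating from c

    def test_scalar_fxp_step_matches_float_structure_at_fixed_point(self):
        # at the (v, u) fixed point the fixed-point step must stay put up to
        # coefficient quantization (a few LSB per ms)
        n = FxpNeuron(RS, prescaled_ordering=True)
        v, u = n.encode_state(NeuronState(-70.0, -14.0))
        v2, u2, spiked = n.step(v, u, q_encode(0.0, S16_15),
                                substeps=16, precise_threshold=True)
        assert not spiked
        assert abs(q_decode(v2) - (-70.0)) < 0.01
        assert abs(q_decode(u2) - (-14.0)) < 0.01


class TestSimulation:
    def test_flat_at_fixed_point_for_all_grid_solvers(self):
        for spec in (SolverSpec.c_grid(), SolverSpec.euler3(), SolverSpec.euler16()):
            tr = simulate_neuron(spec, RS, 0.0, 100, -70.0, -14.0)
            assert tr.spike_times.size == 0
            assert np.allclose(tr.v, -70.0, atol=1e-9)

    def test_reference_flat_at_fixed_point(self):
        tr = simulate_neuron(SolverSpec.reference(), RS, 0.0, 100, -70.0, -14.0)
        assert tr.spike_times.size == 0

    def test_reference_five_spikes_in_protocol_run(self):
        tr = simulate_neuron(SolverSpec.reference(), RS, 5.0, 500, *PROTO_INIT)
        assert tr.spike_times.size == 5

    def test_reference_spike_times_converged_in_tolerance(self):
        a = reference_adaptive(RS, 5.0, 500, abs_err=1e-6, v0=-65.0, u0=-5.0)
        b = reference_adaptive(RS, 5.0, 500, abs_err=1e-8, v0=-65.0, u0=-5.0)
        assert np.max(np.abs(a.spike_times - b.spike_times)) < 1e-3

    def test_euler_lags_reference_and_lag_grows(self):
        ref = simulate_neuron(SolverSpec.reference(), RS, 5.0, 500, *PROTO_INIT)
        eu = simulate_neuron(SolverSpec.euler16(), RS, 5.0, 500, *PROTO_INIT)
        lags = spike_lag(eu.spike_times, ref.spike_times)
        assert np.all(lags >= 0)
        assert np.all(np.diff(lags) >= 0)

    def test_substep_refinement_converges_toward_reference(self):
        ref = simulate_neuron(SolverSpec.reference(), RS, 5.0, 500, *PROTO_INIT)
        lag16 = spike_lag(
            simulate_neuron(
                SolverSpec("euler16_precise", substeps=16), RS, 5.0, 500, *PROTO_INIT
            ).spike_times,
            ref.spike_times,
        )
        lag64 = spike_lag(
            simulate_neuron(
                SolverSpec("euler16_precise", substeps=64), RS, 5.0, 500, *PROTO_INIT
            ).spike_times,
            ref.spike_times,
        )
        assert np.all(lag64 <= lag16)

    def test_grid_threshold_overshoots_precise_does_not(self):
        # grid-locked detection lets v overshoot by orders of magnitude
        coarse = simulate_neuron(SolverSpec.c_grid(), RS, 800.0, 200, -65.0, -13.0)
        precise = simulate_neuron(SolverSpec.euler16(), RS, 800.0, 200, -65.0, -13.0)
        assert coarse.v.max() > 300.0
        # precise-threshold samples exceed theta by at most one substep of growth
        assert precise.v.max() < 100.0

    def test_spike_lag_basics(self):
        assert np.array_equal(spike_lag([1.0, 2.0], [1.0, 2.0]), [0.0, 0.0])
        assert np.array_equal(spike_lag([11.0, 21.0], [10.0, 20.0]), [1.0, 1.0])
        assert spike_lag([1.0], []).size == 0

    def test_deterministic_repetition(self):
        a = simulate_neuron(SolverSpec.euler16_fxp(), RS, 5.0, 200, *PROTO_INIT)
        b = simulate_neuron(SolverSpec.euler16_fxp(), RS, 5.0, 200, *PROTO_INIT)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_esr_variant_is_rejected(self):
        with pytest.raises(NotImplementedError):
            simulate_neuron(SolverSpec("esr"), RS, 5.0, 100)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            SolverSpec("rk4_magic")
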