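"""Single-neuron Izhikevich dynamics under interchangeable numerical schemes.

The Izhikevich model couples a quadratic membrane potential ``v`` (mV) to a
linear recovery variable ``u``::

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

Grid-based simulators advance this system on a 1 ms grid with a semi-implicit
(symplectic) forward Euler scheme: ``u`` is always updated from the already
updated ``v``.  This module provides every update scheme this package can
compare:

``c_grid``
    The historical scheme: ``v`` in two 0.5 ms half-steps, ``u`` in one 1 ms
    step, threshold tested only at grid points.  Above-threshold overshoot of
    ``v`` can reach two orders of magnitude above the 30 mV threshold.
``euler3``
    As ``c_grid`` but ``v`` in three h/3 steps; still grid-point threshold
    detection.  In s16.15 fixed point the larger overshoot makes the squared
    ``v`` wrap around, producing spike artifacts.
``euler16_precise``
    Both equations sub-stepped at h/16 = 0.0625 ms (a power of two, exactly
    representable and applied as a multiplication, never a division) with the
    threshold tested after every substep and the reset applied immediately;
    spikes are still emitted on the 1 ms grid.
``euler16_precise_fxp``
    The same scheme in emulated s16.15 arithmetic with the overflow-safe
    operation ordering for the quadratic term (the 0.04 coefficient held as
    10.24 with a compensating 8-bit right shift) and pre-scaled a, b.
``reference_adaptive``
    An adaptive embedded Runge-Kutta 4(5) reference with continuous-time
    threshold-event localization.
``esr``
    The closed-form Explicit Solver Reduction used by the SpiNNaker software
    stack; recognised as a variant name but deliberately not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .qformat import (
    S16_15,
    QValue,
    WrapCounter,
    q_add,
    q_decode,
    q_encode,
    q_mul,
    q_shr,
    q_sub,
)

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "SolverSpec",
    "SingleNeuronTrace",
    "RS",
    "FS",
    "THETA",
    "rhs_v",
    "rhs_u",
    "apply_reset",
    "step_c_grid",
    "step_substepped",
    "step_fxp_prescaled",
    "simulate_neuron",
    "reference_adaptive",
    "spike_lag",
    "FxpNeuron",
    "fxp_quadratic",
]

THETA = 30.0  # spike threshold (mV)


@dataclass(frozen=True)
class IzhikevichParams:
    """Neuron constants (a, b, c, d) and the fixed 30 mV threshold."""

    a: float
    b: float
    c: float
    d: float
    theta: float = THETA


#: regular-spiking preset (excitatory population)
RS = IzhikevichParams(0.02, 0.2, -65.0, 8.0)
#: fast-spiking preset (inhibitory population)
FS = IzhikevichParams(0.1, 0.2, -65.0, 2.0)


@dataclass(frozen=True)
class NeuronState:
    v: float  # membrane potential (mV)
    u: float  # recovery variable


def default_initial_state(p: IzhikevichParams) -> NeuronState:
    """Customary initialization (v, u) = (c, b*c)."""
    return NeuronState(p.c, p.b * p.c)


def rhs_v(v: float, u: float, I: float) -> float:
    """dv/dt = 0.04 v^2 + 5 v + 140 - u + I."""
    return 0.04 * v * v + 5.0 * v + 140.0 - u + I


def rhs_u(v: float, u: float, p: IzhikevichParams) -> float:
    """du/dt = a (b v - u)."""
    return p.a * (p.b * v - u)


def apply_reset(s: NeuronState, p: IzhikevichParams) -> NeuronState:
    """Hard reset: if v >= theta, (v, u) <- (c, u + d); otherwise unchanged."""
    if s.v >= p.theta:
        return NeuronState(p.c, s.u + p.d)
    return s


_VARIANTS = (
    "c_grid",
    "euler3",
    "euler16_precise",
    "euler16_precise_fxp",
    "reference_adaptive",
    "esr",
)


@dataclass(frozen=True)
class SolverSpec:
    """Which update scheme, how many substeps, and in which arithmetic."""

    variant: str
    substeps: int = 16
    arithmetic: str = "float64"  # or "s16.15"
    precise_threshold: bool = True

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown solver variant {self.variant!r}")
        if self.arithmetic not in ("float64", "s16.15"):
            raise ValueError(f"unknown arithmetic {self.arithmetic!r}")

    # -- presets ---------------------------------------------------------
    @classmethod
    def c_grid(cls) -> "SolverSpec":
        return cls("c_grid", substeps=2, arithmetic="float64", precise_threshold=False)

    @classmethod
    def euler3(cls, arithmetic: str = "float64") -> "SolverSpec":
        return cls("euler3", substeps=3, arithmetic=arithmetic, precise_threshold=False)

    @classmethod
    def euler16(cls) -> "SolverSpec":
        return cls("euler16_precise", substeps=16, arithmetic="float64",
                   precise_threshold=True)

    @classmethod
    def euler16_fxp(cls) -> "SolverSpec":
        return cls("euler16_precise_fxp", substeps=16, arithmetic="s16.15",
                   precise_threshold=True)

    @classmethod
    def reference(cls) -> "SolverSpec":
        return cls("reference_adaptive", arithmetic="float64")

    @property
    def is_fixed_point(self) -> bool:
        return self.arithmetic == "s16.15"

    @property
    def uses_prescaled_ordering(self) -> bool:
        """Overflow-safe quadratic ordering (10.24 with 8-bit shift)."""
        return self.variant == "euler16_precise_fxp"


@dataclass
class SingleNeuronTrace:
    """Grid-sampled state trajectory plus spike times.

    ``t``, ``v``, ``u`` have length ``T + 1`` (samples at 0..T ms) for grid
    solvers.  ``spike_times`` are on the 1 ms grid for grid solvers and
    continuous for the adaptive reference.
    """

    t: np.ndarray
    v: np.ndarray
    u: np.ndarray
    spike_times: np.ndarray
    wrap_count: int = 0


# ---------------------------------------------------------------------------
# float64 steppers
# ---------------------------------------------------------------------------

def step_c_grid(s: NeuronState, I: float, p: IzhikevichParams) -> tuple[NeuronState, bool]:
    """One 1 ms grid step of the historical scheme.

    Threshold test and reset happen at the grid point *first*; then ``v`` is
    advanced in two sequential 0.5 ms half-steps and ``u`` in a single 1 ms
    step from the already updated ``v`` (symplectic ordering).
    """
    spiked = s.v >= p.theta
    if spiked:
        s = apply_reset(s, p)
    v, u = s.v, s.u
    v += 0.5 * rhs_v(v, u, I)
    v += 0.5 * rhs_v(v, u, I)
    u += rhs_u(v, u, p)
    return NeuronState(v, u), spiked


def step_substepped(
    s: NeuronState,
    I: float,
    p: IzhikevichParams,
    spec: SolverSpec,
) -> tuple[NeuronState, bool]:
    """One 1 ms grid step with ``spec.substeps`` symplectic Euler substeps.

    With ``precise_threshold`` the threshold is tested after every substep
    and the reset applied immediately; multiple crossings within the grid
    step merge into a single emitted spike.  Without it (the ``euler3``
    style), only ``v`` is sub-stepped, ``u`` takes one full step, and the
    threshold is tested at the grid point first -- exactly like
    :func:`step_c_grid` but with more ``v`` substeps and hence a higher
    chance of squaring a very large overshoot.
    """
    if spec.is_fixed_point:
        raise ValueError("use FxpNeuron for s16.15 arithmetic")
    n = spec.substeps
    h = 1.0 / n
    if spec.precise_threshold:
        v, u = s.v, s.u
        spiked = False
        for _ in range(n):
            v += h * rhs_v(v, u, I)
            u += h * rhs_u(v, u, p)
            if v >= p.theta:
                spiked = True
                v = p.c
                u = u + p.d
        return NeuronState(v, u), spiked
    spiked = s.v >= p.theta
    if spiked:
        s = apply_reset(s, p)
    v, u = s.v, s.u
    for _ in range(n):
        v += h * rhs_v(v, u, I)
    u += rhs_u(v, u, p)
    return NeuronState(v, u), spiked


# ---------------------------------------------------------------------------
# emulated s16.15 steppers
# ---------------------------------------------------------------------------

def _enc(x: float) -> QValue:
    return q_encode(x, S16_15)


class FxpNeuron:
    """Scalar s16.15 fixed-point Izhikevich stepper.

    ``prescaled_ordering=True`` evaluates the quadratic as
    ``((10.24 * v) >> 8) * v`` -- the coefficient 0.04 held pre-scaled by
    2^8 so it carries s8.23-equivalent fractional precision inside an s16.15
    word -- and holds ``a`` and ``b`` pre-scaled by 2^8 with a compensating
    8-bit right shift at use.  ``prescaled_ordering=False`` uses the naive directly
    encoded constants (the configuration whose coefficient error delays
    spikes noticeably).

    All overflow wraps (never saturates); wrap events are tallied in
    ``wraps``.
    """

    def __init__(self, p: IzhikevichParams, *, prescaled_ordering: bool) -> None:
        self.params = p
        self.prescaled = prescaled_ordering
        self.wraps = WrapCounter()
        self.c_five = _enc(5.0)
        self.c_140 = _enc(140.0)
        self.c_theta = _enc(p.theta)
        self.c_c = _enc(p.c)
        self.c_d = _enc(p.d)
        if prescaled_ordering:
            self.c_quad = _enc(10.24)          # 0.04 * 2^8
            self.c_a = _enc(p.a * 256.0)       # a * 2^8
            self.c_b = _enc(p.b * 256.0)       # b * 2^8
        else:
            self.c_quad = _enc(0.04)
            self.c_a = _enc(p.a)
            self.c_b = _enc(p.b)

    def encode_state(self, s: NeuronState) -> tuple[QValue, QValue]:
        return _enc(s.v), _enc(s.u)

    @staticmethod
    def decode_state(v: QValue, u: QValue) -> NeuronState:
        return NeuronState(q_decode(v), q_decode(u))

    def rhs_v(self, v: QValue, u: QValue, I: QValue) -> QValue:
        """The quadratic right-hand side, in the exact operation order."""
        w = self.wraps
        if self.prescaled:
            t = q_mul(self.c_quad, v, counter=w)   # 10.24 * v
            t = q_shr(t, 8)                        # * 0.00390625 as a shift
            t = q_mul(t, v, counter=w)             # * v
        else:
            t = q_mul(self.c_quad, v, counter=w)   # 0.04 * v
            t = q_mul(t, v, counter=w)             # * v
        t = q_add(t, q_mul(self.c_five, v, counter=w), counter=w)
        t = q_add(t, self.c_140, counter=w)
        t = q_sub(t, u, counter=w)
        return q_add(t, I, counter=w)

    def rhs_u(self, v: QValue, u: QValue) -> QValue:
        w = self.wraps
        if self.prescaled:
            bv = q_shr(q_mul(self.c_b, v, counter=w), 8)
            return q_shr(q_mul(self.c_a, q_sub(bv, u, counter=w), counter=w), 8)
        bv = q_mul(self.c_b, v, counter=w)
        return q_mul(self.c_a, q_sub(bv, u, counter=w), counter=w)

    def step(
        self,
        v: QValue,
        u: QValue,
        I: QValue,
        *,
        substeps: int,
        precise_threshold: bool,
    ) -> tuple[QValue, QValue, bool]:
        """One 1 ms grid step; mirrors the float64 steppers' structure."""
        w = self.wraps
        h = _enc(1.0 / substeps)
        if precise_threshold:
            spiked = False
            for _ in range(substeps):
                v = q_add(v, q_mul(h, self.rhs_v(v, u, I), counter=w), counter=w)
                u = q_add(u, q_mul(h, self.rhs_u(v, u), counter=w), counter=w)
                if v.raw >= self.c_theta.raw:
                    spiked = True
                    v = self.c_c
                    u = q_add(u, self.c_d, counter=w)
            return v, u, spiked
        spiked = v.raw >= self.c_theta.raw
        if spiked:
            v = self.c_c
            u = q_add(u, self.c_d, counter=w)
        for _ in range(substeps):
            v = q_add(v, q_mul(h, self.rhs_v(v, u, I), counter=w), counter=w)
        u = q_add(u, self.rhs_u(v, u), counter=w)
        return v, u, spiked


def step_fxp_prescaled(
    s: NeuronState,
    I: float,
    p: IzhikevichParams,
    neuron: FxpNeuron | None = None,
) -> tuple[NeuronState, bool]:
    """One grid step of the overflow-safe fixed-point scheme (16 substeps,
    precise threshold detection, quadratic evaluated as
    ``((10.24 * v) >> 8) * v`` in that exact order)."""
    if neuron is None:
        neuron = FxpNeuron(p, prescaled_ordering=True)
    v, u = neuron.encode_state(s)
    v, u, spiked = neuron.step(v, u, _enc(I), substeps=16, precise_threshold=True)
    return neuron.decode_state(v, u), spiked


def fxp_quadratic(v: float = -75.0, u: float = 0.0, I: float = 0.0,
                  *, mode: str = "s16.15") -> float:
    """Evaluate dv/dt at (v, u, I) under a given arithmetic, decoded to float.

    Modes: ``"float"`` (exact 0.04), ``"s16.15"`` (directly encoded 0.04),
    ``"prescaled"`` (10.24 with 8-bit shift, s8.23-equivalent coefficient precision
    inside s16.15 words), ``"s8.23"`` (full evaluation in the s8.23 format).
    """
    if mode == "float":
        return rhs_v(v, u, I)
    if mode in ("s16.15", "prescaled"):
        n = FxpNeuron(RS, prescaled_ordering=(mode == "prescaled"))
        return q_decode(n.rhs_v(_enc(v), _enc(u), _enc(I)))
    if mode == "s8.23":
        from .qformat import S8_23
        e = lambda x: q_encode(x, S8_23)
        t = q_mul(q_mul(e(0.04), e(v)), e(v))
        t = q_add(t, q_mul(e(5.0), e(v)))
        t = q_add(t, e(140.0))
        t = q_sub(t, e(u))
        return q_decode(q_add(t, e(I)))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

def simulate_neuron(
    spec: SolverSpec,
    p: IzhikevichParams,
    I_const: float,
    T: float,
    v0: float | None = None,
    u0: float | None = None,
) -> SingleNeuronTrace:
    """Simulate one neuron under a constant current for ``T`` ms.

    Grid solvers sample (v, u) at every 1 ms grid point and emit spikes on
    the grid: a crossing detected during the step ending at grid point ``t``
    is time-stamped ``t``.  The adaptive reference returns continuous spike
    times.  Deterministic for fixed inputs.
    """
    if T <= 0:
        raise ValueError("duration must be positive")
    if spec.variant == "esr":
        raise NotImplementedError(
            "the closed-form ESR solver is a recognised variant name but is "
            "not implemented in this package"
        )
    if v0 is None or u0 is None:
        init = default_initial_state(p)
        v0 = init.v if v0 is None else v0
        u0 = init.u if u0 is None else u0
    if spec.variant == "reference_adaptive":
        return reference_adaptive(p, I_const, T, v0=v0, u0=u0)

    n_steps = int(round(T))
    t = np.arange(n_steps + 1, dtype=float)
    v_arr = np.empty(n_steps + 1)
    u_arr = np.empty(n_steps + 1)
    spikes: list[float] = []

    if spec.is_fixed_point:
        neuron = FxpNeuron(p, prescaled_ordering=spec.uses_prescaled_ordering)
        qv, qu = _enc(v0), _enc(u0)
        qI = _enc(I_const)
        v_arr[0], u_arr[0] = q_decode(qv), q_decode(qu)
        for k in range(n_steps):
            if not spec.precise_threshold and qv.raw >= neuron.c_theta.raw:
                spikes.append(float(k))
            qv, qu, spiked = neuron.step(
                qv, qu, qI,
                substeps=spec.substeps,
                precise_threshold=spec.precise_threshold,
            )
            if spec.precise_threshold and spiked:
                spikes.append(float(k + 1))
            v_arr[k + 1], u_arr[k + 1] = q_decode(qv), q_decode(qu)
        return SingleNeuronTrace(t, v_arr, u_arr, np.asarray(spikes),
                                 wrap_count=neuron.wraps.count)

    s = NeuronState(v0, u0)
    v_arr[0], u_arr[0] = s.v, s.u
    for k in range(n_steps):
        if spec.variant == "c_grid":
            if s.v >= p.theta:
                spikes.append(float(k))
            s, _ = step_c_grid(s, I_const, p)
        elif spec.precise_threshold:
            s, spiked = step_substepped(s, I_const, p, spec)
            if spiked:
                spikes.append(float(k + 1))
        else:
            if s.v >= p.theta:
                spikes.append(float(k))
            s, _ = step_substepped(s, I_const, p, spec)
        v_arr[k + 1], u_arr[k + 1] = s.v, s.u
    return SingleNeuronTrace(t, v_arr, u_arr, np.asarray(spikes))


def reference_adaptive(
    p: IzhikevichParams,
    I,
    T: float,
    abs_err: float = 1e-6,
    v0: float | None = None,
    u0: float | None = None,
) -> SingleNeuronTrace:
    """High-accuracy adaptive embedded Runge-Kutta 4(5) reference.

    ``I`` may be a constant or a callable ``I(t)``.  The v = 30 mV crossing
    is localized in continuous time by root-finding on the dense solver
    output (tolerance well below 1e-6 ms), the reset applied, and the
    integration restarted; spike times are therefore not grid-locked.
    """
    if abs_err <= 0:
        raise ValueError("abs_err must be positive")
    if v0 is None or u0 is None:
        init = default_initial_state(p)
        v0 = init.v if v0 is None else v0
        u0 = init.u if u0 is None else u0
    current = I if callable(I) else (lambda t, _I=float(I): _I)

    def f(t, y):
        v, u = y
        return (rhs_v(v, u, current(t)), rhs_u(v, u, p))

    def crossing(t, y):
        return y[0] - p.theta

    crossing.terminal = True
    crossing.direction = 1

    grid = np.arange(int(round(T)) + 1, dtype=float)
    v_samples = np.full(grid.shape, np.nan)
    u_samples = np.full(grid.shape, np.nan)
    spikes: list[float] = []
    t0 = 0.0
    y = [float(v0), float(u0)]
    guard = 0
    while t0 < T:
        t_eval = grid[(grid >= t0) & (grid <= T)]
        sol = solve_ivp(
            f, (t0, T), y, method="RK45", events=crossing,
            t_eval=t_eval if t_eval.size else None,
            rtol=1e-12, atol=abs_err, max_step=1.0, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"reference integration failed: {sol.message}")
        for ti, vi, ui in zip(sol.t, sol.y[0], sol.y[1]):
            idx = int(round(ti))
            if abs(ti - idx) < 1e-9 and 0 <= idx < grid.size:
                v_samples[idx] = vi
                u_samples[idx] = ui
        if sol.t_events[0].size:
            t_ev = float(sol.t_events[0][0])
            u_ev = float(sol.y_events[0][0][1])
            spikes.append(t_ev)
            y = [p.c, u_ev + p.d]
            t0 = t_ev
            guard += 1
            if guard > 100000:
                raise RuntimeError("event loop did not terminate")
        else:
            break
    return SingleNeuronTrace(grid, v_samples, u_samples, np.asarray(spikes))


def spike_lag(test: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-spike lag ``test_k - ref_k`` (ms), compared up to the shorter length."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = min(test.size, ref.size)
    return test[:n] - ref[:n]
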