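"""Software emulation of 32-bit signed fixed-point (Q-format) arithmetic.

Neuromorphic ARM-based platforms such as SpiNNaker have no hardware floating
point unit and hold membrane voltages and neuron parameters as 32-bit signed
fixed-point words.  A format ``s<i>.<f>`` splits the word into one sign bit,
``i`` integer bits and ``f`` fraction bits; the representable range is
``[-2**i, 2**i - 2**-f]``.  Calculations are carried out as if the words were
plain two's-complement integers: addition is integer addition, multiplication
is an exact integer product followed by an arithmetic right shift of ``f``
bits.  On overflow the value *wraps around* (non-saturating), producing a
negative number -- the mechanism behind the spike artifacts this package can
demonstrate in fixed-point network simulations.

Two formats are used throughout: :data:`S16_15` (the platform's native
accum type) and :data:`S8_23` (higher fractional precision, narrower range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "QFormat",
    "QValue",
    "WrapCounter",
    "S16_15",
    "S8_23",
    "q_range",
    "q_encode",
    "q_decode",
    "q_add",
    "q_sub",
    "q_mul",
    "q_shr",
]

_WORD_BITS = 32
_WRAP_MOD = 1 << _WORD_BITS          # 2**32
_WRAP_HALF = 1 << (_WORD_BITS - 1)   # 2**31


class QFormatError(ValueError):
    """Invalid Q format or mismatched formats in a binary operation."""


def _wrap32(x: int) -> int:
    """Reduce an integer into signed 32-bit two's-complement range."""
    return ((x + _WRAP_HALF) % _WRAP_MOD) - _WRAP_HALF


@dataclass(frozen=True)
class QFormat:
    """A signed fixed-point format with ``int_bits`` + ``frac_bits`` + sign = 32."""

    int_bits: int
    frac_bits: int

    def __post_init__(self) -> None:
        if self.int_bits < 0 or self.frac_bits < 0:
            raise QFormatError("bit counts must be non-negative")
        if self.int_bits + self.frac_bits + 1 != _WORD_BITS:
            raise QFormatError(
                f"s{self.int_bits}.{self.frac_bits} does not fit a "
                f"{_WORD_BITS}-bit word (need int_bits + frac_bits + 1 == {_WORD_BITS})"
            )

    @property
    def resolution(self) -> float:
        """Smallest representable increment, ``2**-frac_bits``."""
        return 2.0 ** -self.frac_bits

    def __str__(self) -> str:
        return f"s{self.int_bits}.{self.frac_bits}"


S16_15 = QFormat(16, 15)
S8_23 = QFormat(8, 23)


class WrapCounter:
    """Optional diagnostic counter of wrap-around (overflow) events.

    The arithmetic itself never signals overflow -- wrapping is the defined
    behaviour -- but callers investigating overflow artifacts can pass a
    counter to every operation and inspect ``count`` afterwards.
    """

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0

    def hit(self) -> None:
        self.count += 1


@dataclass(frozen=True)
class QValue:
    """A fixed-point value: a raw two's-complement word plus its format."""

    raw: int
    fmt: QFormat

    def __post_init__(self) -> None:
        if not (-_WRAP_HALF <= self.raw < _WRAP_HALF):
            raise QFormatError(f"raw word {self.raw} outside signed 32-bit range")

    def decode(self) -> float:
        return q_decode(self)

    @property
    def hex(self) -> str:
        """Raw word as unsigned hex, e.g. ``0x0000051E``."""
        return f"0x{self.raw & (_WRAP_MOD - 1):08X}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"QValue({self.hex} {self.fmt} = {self.decode()!r})"


def q_range(fmt: QFormat) -> tuple[float, float]:
    """Exact representable range ``(-2**i, 2**i - 2**-f)`` of a format."""
    lo = -(2.0 ** fmt.int_bits)
    hi = 2.0 ** fmt.int_bits - 2.0 ** -fmt.frac_bits
    return lo, hi


def q_encode(
    x: float,
    fmt: QFormat,
    *,
    rounding: str = "trunc",
    counter: WrapCounter | None = None,
) -> QValue:
    """Convert a real number to fixed point.

    The value is scaled by ``2**f`` and the fraction discarded: by default
    truncated toward zero (C cast semantics); ``rounding="floor"`` truncates
    toward minus infinity instead.  Values outside the representable range
    wrap (no saturation).
    """
    if not math.isfinite(x):
        raise ValueError("cannot encode non-finite value")
    scaled = x * (1 << fmt.frac_bits)
    if rounding == "trunc":
        raw = math.trunc(scaled)
    elif rounding == "floor":
        raw = math.floor(scaled)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    wrapped = _wrap32(raw)
    if wrapped != raw and counter is not None:
        counter.hit()
    return QValue(wrapped, fmt)


def q_decode(q: QValue) -> float:
    """Exact real value ``raw * 2**-f`` (a dyadic rational; no rounding)."""
    return q.raw * 2.0 ** -q.fmt.frac_bits


def _check_fmt(a: QValue, b: QValue) -> None:
    if a.fmt != b.fmt:
        raise QFormatError(f"format mismatch: {a.fmt} vs {b.fmt}")


def q_add(a: QValue, b: QValue, *, counter: WrapCounter | None = None) -> QValue:
    """Fixed-point addition: integer sum of raw words, wrapped mod 2**32."""
    _check_fmt(a, b)
    s = a.raw + b.raw
    wrapped = _wrap32(s)
    if wrapped != s and counter is not None:
        counter.hit()
    return QValue(wrapped, a.fmt)


def q_sub(a: QValue, b: QValue, *, counter: WrapCounter | None = None) -> QValue:
    _check_fmt(a, b)
    s = a.raw - b.raw
    wrapped = _wrap32(s)
    if wrapped != s and counter is not None:
        counter.hit()
    return QValue(wrapped, a.fmt)


def q_mul(a: QValue, b: QValue, *, counter: WrapCounter | None = None) -> QValue:
    """Fixed-point multiplication.

    The raw words are multiplied exactly (modelling an ARM long multiply into
    a 64-bit intermediate), then arithmetically right-shifted by ``f`` bits
    (truncation toward minus infinity on the raw word) and wrapped to 32 bits.

    Truncation makes the operation non-associative; expression order matters
    and is never reordered by this package.
    """
    _check_fmt(a, b)
    prod = (a.raw * b.raw) >> a.fmt.frac_bits  # Python >> is arithmetic
    wrapped = _wrap32(prod)
    if wrapped != prod and counter is not None:
        counter.hit()
    return QValue(wrapped, a.fmt)


def q_shr(a: QValue, n: int) -> QValue:
    """Arithmetic right shift by ``n`` bits (sign-preserving; == * 2**-n truncated)."""
    if not (0 <= n <= 31):
        raise ValueError(f"shift count {n} out of range [0, 31]")
    return QValue(a.raw >> n, a.fmt)
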