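"""Spike-train statistics for comparing two executable models of one network.

Two implementations of the same mathematical model (different arithmetic,
solver, or hardware) cannot be expected to agree spike-for-spike, so their
agreement is judged statistically ("substantiation"): distributions of
per-neuron firing rates (FR), per-neuron local variation (LV, a regularity
measure built from adjacent inter-spike-interval ratios), and pairwise
Pearson correlation coefficients of 2 ms binned spike counts (CC) are
compared via the effect size (Cohen's d, pooled-SD form), separately per
measure -- agreement on one level does not imply agreement on another.

Both inputs to a comparison pass through the single code path in this
module, so discrepancies cannot arise from the comparison machinery itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeData",
    "MeasureDistribution",
    "MeasureComparison",
    "ComparisonReport",
    "firing_rates",
    "local_variation",
    "pairwise_correlation",
    "cohens_d",
    "compare",
    "effect_size_summary",
]

MEASURES = ("FR", "LV", "CC")


@dataclass
class SpikeData:
    """Per-neuron sorted spike-time lists (ms) with duration metadata."""

    trains: list[np.ndarray]
    duration_ms: float
    resolution_ms: float | None = 1.0  # None: continuous times

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        clean = []
        for tr in self.trains:
            tr = np.asarray(tr, dtype=float)
            if tr.size and (tr[0] < 0 or tr[-1] >= self.duration_ms):
                raise ValueError("spike times must lie in [0, duration)")
            if tr.size > 1 and np.any(np.diff(tr) <= 0):
                raise ValueError("spike times must be strictly increasing")
            clean.append(tr)
        self.trains = clean

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @classmethod
    def from_times_ids(
        cls,
        times: np.ndarray,
        ids: np.ndarray,
        n_neurons: int,
        duration_ms: float,
        resolution_ms: float | None = 1.0,
    ) -> "SpikeData":
        times = np.asarray(times, dtype=float)
        ids = np.asarray(ids, dtype=np.int64)
        order = np.lexsort((times,))
        times, ids = times[order], ids[order]
        trains = [times[ids == i] for i in range(n_neurons)]
        return cls(trains, duration_ms, resolution_ms)

    def to_times_ids(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (time, neuron_id) pairs, time-sorted (id breaks ties)."""
        times = np.concatenate([t for t in self.trains]) if self.trains else np.empty(0)
        ids = np.concatenate(
            [np.full(t.size, i, dtype=np.int64) for i, t in enumerate(self.trains)]
        ) if self.trains else np.empty(0, dtype=np.int64)
        order = np.lexsort((ids, times))
        return times[order], ids[order]

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))


@dataclass
class MeasureDistribution:
    """Values of one measure (per neuron for FR/LV, per pair for CC)."""

    measure: str
    values: np.ndarray
    n_excluded: int = 0


def firing_rates(s: SpikeData) -> MeasureDistribution:
    """Per-neuron mean firing rate in Hz (spike count / duration)."""
    dur_s = s.duration_ms / 1000.0
    vals = np.array([t.size / dur_s for t in s.trains])
    return MeasureDistribution("FR", vals)


def local_variation(s: SpikeData, min_spikes: int = 3) -> MeasureDistribution:
    """Local variation LV of each spike train (Shinomoto-style).

    For the m inter-spike intervals I_1..I_m of a train,

        LV = 3/(m-1) * sum_k ((I_k - I_{k+1}) / (I_k + I_{k+1}))**2

    LV = 0 for a perfectly regular train and 1 in expectation for a Poisson
    process.  Neurons with fewer than ``min_spikes`` spikes (fewer than two
    intervals) are excluded and counted in ``n_excluded``.
    """
    if min_spikes < 3:
        raise ValueError("need at least 3 spikes (2 ISIs) for LV")
    vals = []
    excluded = 0
    for tr in s.trains:
        if tr.size < min_spikes:
            excluded += 1
            continue
        isi = np.diff(tr)
        ratio = (isi[:-1] - isi[1:]) / (isi[:-1] + isi[1:])
        vals.append(3.0 * np.mean(ratio**2))
    if not vals:
        warnings.warn("all neurons excluded from LV (too few spikes)")
    return MeasureDistribution("LV", np.asarray(vals), excluded)


def _binned_counts(s: SpikeData, bin_ms: float) -> np.ndarray:
    n_bins = int(s.duration_ms // bin_ms)  # final partial bin dropped
    if n_bins < 2:
        raise ValueError("duration too short for the requested bin width")
    edges_end = n_bins * bin_ms
    out = np.empty((s.n_neurons, n_bins))
    for i, tr in enumerate(s.trains):
        tr = tr[tr < edges_end]
        out[i] = np.bincount((tr / bin_ms).astype(np.int64), minlength=n_bins)
    return out


def pairwise_correlation(s: SpikeData, bin_ms: float = 2.0) -> MeasureDistribution:
    """Pearson correlation of binned spike counts for all unordered pairs.

    Pairs involving a zero-variance binned train (e.g. a silent neuron) have
    an undefined coefficient; they are excluded and counted.
    """
    X = _binned_counts(s, bin_ms)
    var = X.var(axis=1)
    keep = var > 0
    n = s.n_neurons
    total_pairs = n * (n - 1) // 2
    Xk = X[keep]
    k = Xk.shape[0]
    if k < 2:
        warnings.warn("fewer than two non-degenerate trains; no CC values")
        return MeasureDistribution("CC", np.empty(0), total_pairs)
    Xc = Xk - Xk.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    iu = np.triu_indices(k, 1)
    vals = corr[iu]
    return MeasureDistribution("CC", vals, total_pairs - k * (k - 1) // 2)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Effect size d = (mean(x) - mean(y)) / pooled SD.

    ``s_pooled = sqrt(((n_x-1) s_x^2 + (n_y-1) s_y^2) / (n_x + n_y - 2))``.
    With zero pooled variance the result is 0 for equal means and signed
    infinity otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two values per sample")
    dm = x.mean() - y.mean()
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if pooled == 0.0:
        return 0.0 if dm == 0.0 else float(np.sign(dm)) * float("inf")
    return float(dm / np.sqrt(pooled))


@dataclass
class MeasureComparison:
    """Two distributions of one measure, shared-range histograms, and d."""

    dist_a: MeasureDistribution
    dist_b: MeasureDistribution
    edges: np.ndarray
    hist_a: np.ndarray
    hist_b: np.ndarray
    d: float


@dataclass
class ComparisonReport:
    measures: dict[str, MeasureComparison] = field(default_factory=dict)

    def effect_sizes(self, absolute: bool = False) -> dict[str, float]:
        return {
            m: (abs(c.d) if absolute else c.d) for m, c in self.measures.items()
        }


def _shared_histograms(
    a: np.ndarray, b: np.ndarray, bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pooled = np.concatenate([a, b])
    if pooled.size == 0:
        edges = np.linspace(0.0, 1.0, bins + 1)
        zero = np.zeros(bins, dtype=np.int64)
        return edges, zero, zero
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:  # degenerate: widen so the single value falls in one bin
        lo, hi = lo - 0.5, hi + 0.5
    hist_a, edges = np.histogram(a, bins=bins, range=(lo, hi))
    hist_b, _ = np.histogram(b, bins=bins, range=(lo, hi))
    return edges, hist_a, hist_b


def compare(
    a: SpikeData,
    b: SpikeData,
    *,
    bin_ms: float = 2.0,
    bins: int = 70,
    min_spikes: int = 3,
) -> ComparisonReport:
    """Full substantiation comparison of two spike recordings.

    Computes FR, LV, and CC distributions for both inputs through the same
    code path, 70-bin histograms on the union of the two samples' ranges,
    and Cohen's d per measure.
    """
    if a.n_neurons != b.n_neurons:
        raise ValueError("inputs must have the same number of neurons")
    if a.duration_ms != b.duration_ms:
        raise ValueError("inputs must have the same duration")
    report = ComparisonReport()
    extractors = {
        "FR": firing_rates,
        "LV": lambda s: local_variation(s, min_spikes),
        "CC": lambda s: pairwise_correlation(s, bin_ms),
    }
    for name, fn in extractors.items():
        da, db = fn(a), fn(b)
        edges, ha, hb = _shared_histograms(da.values, db.values, bins)
        d = cohens_d(da.values, db.values) if (
            da.values.size >= 2 and db.values.size >= 2
        ) else float("nan")
        report.measures[name] = MeasureComparison(da, db, edges, ha, hb, d)
    return report


def effect_size_summary(
    reports: list[ComparisonReport], absolute: bool = True
) -> dict[str, tuple[float, float]]:
    """Mean and standard deviation of the effect size across network states."""
    out: dict[str, tuple[float, float]] = {}
    for m in MEASURES:
        ds = np.array([r.effect_sizes(absolute)[m] for r in reports])
        out[m] = (float(ds.mean()), float(ds.std()))
    return out
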