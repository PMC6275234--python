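"""Plain-text artifact files for the frozen-state replay protocol.

All artifacts are line-oriented text with ``#``-prefixed header lines:

topology file
    header carries ``n_exc``, ``n_inh``, ``out_degree``; one
    ``source target delay_ms`` triple per line, grouped by source.
weight file
    one ``source target weight`` per line in synapse (CSR) order; weights
    printed with 17 significant digits for a lossless float64 round-trip.
stimulus file
    one stimulated-neuron index per line (line number = millisecond, -1 for
    none); amplitude in the header.
spike file
    one ``time_ms neuron_id`` pair per line, time-sorted; duration and
    neuron count in the header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .network import ArtifactError, FrozenStateBundle, StimulusSeries, Topology
from .stats import SpikeData

__all__ = [
    "save_topology",
    "load_topology",
    "save_weights",
    "load_weights",
    "save_stimulus",
    "load_stimulus",
    "save_spikes",
    "load_spikes",
    "save_bundle",
]


def _header(path: Path, expected: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    if meta.get("kind") != expected:
        raise ArtifactError(f"{path} is not a {expected} file")
    return meta


def save_topology(path: str | Path, t: Topology) -> None:
    src = t.source_of()
    with open(path, "w") as fh:
        fh.write(
            f"# kind=topology n_exc={t.n_exc} n_inh={t.n_inh} "
            f"out_degree={t.out_degree}\n# source target delay_ms\n"
        )
        for s, tgt, d in zip(src, t.targets, t.delays):
            fh.write(f"{s} {tgt} {d}\n")


def load_topology(path: str | Path) -> Topology:
    path = Path(path)
    meta = _header(path, "topology")
    data = np.loadtxt(path, dtype=np.int64, comments="#", ndmin=2)
    n_exc, n_inh = int(meta["n_exc"]), int(meta["n_inh"])
    out_degree = int(meta["out_degree"])
    n = n_exc + n_inh
    if data.shape[0] != n * out_degree:
        raise ArtifactError("synapse count does not match the header")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(ptr, data[:, 0] + 1, 1)
    ptr = np.cumsum(ptr)
    return Topology(
        n_exc, n_inh, out_degree, ptr,
        data[:, 1].astype(np.int32), data[:, 2].astype(np.int32),
    )


def save_weights(path: str | Path, t: Topology, weights: np.ndarray) -> None:
    if weights.shape != (t.n_syn,):
        raise ArtifactError("weight vector does not match the topology")
    src = t.source_of()
    with open(path, "w") as fh:
        fh.write(f"# kind=weights n_syn={t.n_syn}\n# source target weight\n")
        for s, tgt, w in zip(src, t.targets, weights):
            fh.write(f"{s} {tgt} {w:.17g}\n")


def load_weights(path: str | Path, t: Topology | None = None) -> np.ndarray:
    path = Path(path)
    meta = _header(path, "weights")
    data = np.loadtxt(path, comments="#", ndmin=2)
    w = data[:, 2]
    if int(meta["n_syn"]) != w.size or (t is not None and w.size != t.n_syn):
        raise ArtifactError("weight count mismatch")
    return w


def save_stimulus(path: str | Path, s: StimulusSeries) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# kind=stimulus amplitude={s.amplitude:.17g} n_steps={s.n_steps}\n"
            "# neuron index per 1 ms step (-1: none)\n"
        )
        for i in s.indices:
            fh.write(f"{i}\n")


def load_stimulus(path: str | Path) -> StimulusSeries:
    path = Path(path)
    meta = _header(path, "stimulus")
    idx = np.loadtxt(path, dtype=np.int64, comments="#", ndmin=1)
    return StimulusSeries(idx, float(meta["amplitude"]))


def save_spikes(path: str | Path, s: SpikeData) -> None:
    times, ids = s.to_times_ids()
    with open(path, "w") as fh:
        fh.write(
            f"# kind=spikes n_neurons={s.n_neurons} duration_ms={s.duration_ms:.17g}\n"
            "# time_ms neuron_id\n"
        )
        for t, i in zip(times, ids):
            fh.write(f"{t:.17g} {i}\n")


def load_spikes(path: str | Path) -> SpikeData:
    path = Path(path)
    meta = _header(path, "spikes")
    data = np.loadtxt(path, comments="#", ndmin=2)
    n = int(meta["n_neurons"])
    dur = float(meta["duration_ms"])
    if data.size == 0:
        return SpikeData([np.empty(0)] * n, dur)
    return SpikeData.from_times_ids(data[:, 0], data[:, 1].astype(np.int64), n, dur)


def save_bundle(directory: str | Path, bundle: FrozenStateBundle) -> dict[str, Path]:
    """Write a frozen-state bundle (A, D, W(t_i), I) as text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    p = directory / "topology.txt"
    save_topology(p, bundle.topology)
    written["topology"] = p
    for t_ms, w in bundle.snapshots.items():
        p = directory / f"weights_t{t_ms:08d}ms.txt"
        save_weights(p, bundle.topology, w)
        written[f"weights_{t_ms}"] = p
    p = directory / "stimulus.txt"
    save_stimulus(p, bundle.stimulus_head)
    written["stimulus"] = p
    if bundle.spikes is not None:
        p = directory / "spikes.txt"
        save_spikes(p, bundle.spikes)
        written["spikes"] = p
    return written
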