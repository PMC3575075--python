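"""Plain-text spike files, voltage traces, and config handling.

Spike files carry one event per line, ``time_ms<TAB>unit_id``, with
``#``-prefixed header comment lines.  Voltage traces are columnar text
(time plus one column per recorded neuron); an HDF5 container is offered
for larger trace sets.  Configs are YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .core import SimResult, SpikeData

__all__ = ["write_spikes", "read_spikes", "write_traces", "read_traces",
           "write_traces_hdf5", "load_config", "save_config", "config_hash",
           "write_report"]


def write_spikes(path, spikes: SpikeData, header: dict | None = None) -> None:
    p = Path(path)
    with p.open("w") as fh:
        fh.write("# spikesim spike file\n")
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        for t, u in zip(spikes.times, spikes.units):
            fh.write(f"{t:.6g}\t{int(u)}\n")


def read_spikes(path) -> SpikeData:
    times, units = [], []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'time_ms<TAB>unit_id', "
                                 f"got {line!r}")
            try:
                times.append(float(parts[0]))
                units.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed event {line!r}") from exc
    return SpikeData(times, units)


def write_traces(path, result: SimResult) -> None:
    if result.trace_times is None:
        raise ValueError("result carries no voltage traces")
    ids = sorted(result.traces)
    header = "time_ms\t" + "\t".join(f"v_{i}" for i in ids)
    data = np.column_stack([result.trace_times] + [result.traces[i] for i in ids])
    np.savetxt(path, data, delimiter="\t", header=header, comments="# ")


def read_traces(path) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    with Path(path).open() as fh:
        header = fh.readline().lstrip("# ").split()
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    ids = [int(c.split("_", 1)[1]) for c in header[1:]]
    return data[:, 0], {i: data[:, k + 1] for k, i in enumerate(ids)}


def write_traces_hdf5(path, result: SimResult) -> None:
    import h5py

    if result.trace_times is None:
        raise ValueError("result carries no voltage traces")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_ms", data=result.trace_times)
        grp = fh.create_group("v")
        for i, v in result.traces.items():
            grp.create_dataset(str(i), data=v)


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def write_report(path, report: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    with Path(path).open("w") as fh:
        json.dump(report, fh, indent=2, default=_default, sort_keys=True)
        fh.write("\n")
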