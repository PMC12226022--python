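"""Readers and writers for the pipeline's plain-text and HDF5 artifacts.

Formats: whitespace-delimited edge lists with a node-table sidecar, two-column
spike files (`source_id time_ms`), tab-separated synapse tables, JSON stimulus
schedules, and HDF5 plasticity traces.  Every writer emits a JSON provenance
block (seed, parameters, package version).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .plasticity import PlasticityTrace
from .synthetic import DirectedNetwork, SpikeTrains, StimulusSchedule

__all__ = [
    "provenance_block",
    "write_network", "read_network",
    "write_spikes", "read_spikes",
    "write_synapses", "read_synapses",
    "write_schedule", "read_schedule",
    "write_trace", "read_trace",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def provenance_block(seed=None, **params) -> str:
    return json.dumps({"version": __version__, "seed": seed,
                       "parameters": _jsonable(params)}, sort_keys=True)


def write_network(network: DirectedNetwork, edge_path, node_path, seed=None, **params):
    edge_path, node_path = Path(edge_path), Path(node_path)
    with open(edge_path, "w") as f:
        f.write(f"# provenance: {provenance_block(seed, **params)}\n")
        for u, v in network.edges:
            f.write(f"{u} {v}\n")
    with open(node_path, "w") as f:
        f.write(f"# provenance: {provenance_block(seed, **params)}\n")
        network.nodes.to_csv(f, sep="\t", index=False)


def read_network(edge_path, node_path) -> DirectedNetwork:
    edges = []
    with open(edge_path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split()
            edges.append((int(u), int(v)))
    nodes = pd.read_csv(node_path, sep="\t", comment="#")
    return DirectedNetwork(nodes=nodes, edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2))


def write_spikes(spikes: SpikeTrains, path, seed=None, **params):
    with open(path, "w") as f:
        f.write(f"# provenance: {provenance_block(seed, **params)}\n")
        f.write("source_id\ttime_ms\n")
        for s in sorted(spikes):
            for t in spikes[s]:
                f.write(f"{s}\t{t:.6f}\n")


def read_spikes(path) -> SpikeTrains:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = SpikeTrains()
    for s, grp in df.groupby("source_id"):
        out[int(s)] = np.sort(grp["time_ms"].to_numpy(float))
    return out


def write_synapses(syn_table: pd.DataFrame, path, seed=None, **params):
    with open(path, "w") as f:
        f.write(f"# provenance: {provenance_block(seed, **params)}\n")
        syn_table.to_csv(f, sep="\t", index=False)


def read_synapses(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_schedule(schedule: StimulusSchedule, path, seed=None, **params):
    payload = {
        "provenance": json.loads(provenance_block(seed, **params)),
        "fiber_locations": schedule.fiber_locations.tolist(),
        "bundle_of": schedule.bundle_of.tolist(),
        "patterns": {k: sorted(v) for k, v in schedule.patterns.items()},
        "pattern_bundles": {k: sorted(v) for k, v in schedule.pattern_bundles.items()},
        "presentations": [[lab, t] for lab, t in schedule.presentations],
        "isi_ms": schedule.isi_ms,
        "stim_duration_ms": schedule.stim_duration_ms,
        "nonspecific_fibers": sorted(schedule.nonspecific_fibers),
    }
    Path(path).write_text(json.dumps(payload))


def read_schedule(path) -> StimulusSchedule:
    d = json.loads(Path(path).read_text())
    return StimulusSchedule(
        fiber_locations=np.asarray(d["fiber_locations"], float),
        bundle_of=np.asarray(d["bundle_of"], int),
        patterns={k: frozenset(v) for k, v in d["patterns"].items()},
        pattern_bundles={k: frozenset(v) for k, v in d["pattern_bundles"].items()},
        presentations=[(lab, float(t)) for lab, t in d["presentations"]],
        isi_ms=float(d["isi_ms"]),
        stim_duration_ms=float(d["stim_duration_ms"]),
        nonspecific_fibers=frozenset(d["nonspecific_fibers"]),
    )


def write_trace(trace: PlasticityTrace, path, seed=None, **params):
    with h5py.File(path, "w") as h:
        h.create_dataset("report_times", data=trace.report_times_s)
        h.create_dataset("rho", data=trace.rho)
        h.create_dataset("U_SE", data=trace.u_se)
        h.create_dataset("g_AMPA", data=trace.g_ampa)
        h.create_dataset("syn_ids", data=trace.syn_ids)
        h.attrs["provenance"] = provenance_block(seed, **params)


def read_trace(path) -> PlasticityTrace:
    with h5py.File(path, "r") as h:
        return PlasticityTrace(
            syn_ids=h["syn_ids"][...],
            report_times_s=h["report_times"][...],
            rho=h["rho"][...],
            u_se=h["U_SE"][...],
            g_ampa=h["g_AMPA"][...],
        )
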