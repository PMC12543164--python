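"""Readers and writers for the package's external formats.

Traces and spike/event tables travel as CSV, culture parameters as JSON,
movies as TIFF stacks, connectivity graphs as GraphML or edge-list CSV,
metric and memory reports as JSON, and trial logs as JSON lines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .culture import ActivityRecord, CultureParams, TraceSet
from .imaging import ROI, EventTrain
from .network import Adjacency, NetworkMetrics
from .reservoir import MemoryResult

__all__ = [
    "traces_to_csv", "traces_from_csv",
    "spikes_to_csv", "spikes_from_csv",
    "events_to_csv", "events_from_csv",
    "params_to_json", "params_from_json",
    "save_stack", "load_stack",
    "rois_to_json", "rois_from_json",
    "adjacency_to_graphml", "adjacency_to_edgelist",
    "metrics_to_json", "memory_to_json", "memory_to_csv",
    "trial_log_to_jsonl",
]


def traces_to_csv(traces: TraceSet, path) -> None:
    cols = {"time_s": traces.times}
    for i in range(traces.n_neurons):
        cols[f"neuron_{i}"] = traces.data[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def traces_from_csv(path) -> TraceSet:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 10.0
    data = df[[c for c in df.columns if c.startswith("neuron_")]].to_numpy().T
    return TraceSet(data=data, sample_rate=float(round(rate, 6)))


def spikes_to_csv(record: ActivityRecord, path) -> None:
    ids = np.concatenate(
        [np.full(len(ts), i) for i, ts in enumerate(record.spike_times)]
    ) if any(len(ts) for ts in record.spike_times) else np.empty(0, dtype=int)
    ts = np.concatenate(record.spike_times) if ids.size else np.empty(0)
    pd.DataFrame({"neuron_id": ids.astype(int), "time_s": ts}).to_csv(path, index=False)


def spikes_from_csv(path, n_neurons: int, duration: float) -> ActivityRecord:
    df = pd.read_csv(path)
    spikes = [
        np.sort(df.loc[df["neuron_id"] == i, "time_s"].to_numpy())
        for i in range(n_neurons)
    ]
    return ActivityRecord(spike_times=spikes, rates=None, rate_times=None,
                          duration=duration)


def events_to_csv(events: Sequence[EventTrain], path) -> None:
    rows = [(e.neuron, t) for e in events for t in e.times]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(path, index=False)


def events_from_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        EventTrain(times=np.sort(g["time_s"].to_numpy()), neuron=int(nid))
        for nid, g in df.groupby("neuron_id")
    ]


def params_to_json(params: CultureParams, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(params), indent=2))


def params_from_json(path) -> CultureParams:
    return CultureParams(**json.loads(Path(path).read_text()))


def save_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def load_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def rois_to_json(rois: Sequence[ROI], path) -> None:
    payload = [
        {
            "pixels": r.pixels.tolist(),
            "centroid": list(r.centroid),
            "eccentricity": r.eccentricity,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload))


def rois_from_json(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [
        ROI(
            pixels=np.asarray(d["pixels"], dtype=int),
            centroid=tuple(d["centroid"]),
            area=len(d["pixels"]),
            eccentricity=float(d["eccentricity"]),
        )
        for d in payload
    ]


def adjacency_to_graphml(adj: Adjacency, path) -> None:
    nx.write_graphml(adj.to_networkx(), path)


def adjacency_to_edgelist(adj: Adjacency, path) -> None:
    rows = np.argwhere(np.triu(adj.matrix, 1))
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, index=False)


def metrics_to_json(metrics: NetworkMetrics, path) -> None:
    d = dataclasses.asdict(metrics)
    d["partition"] = {str(k): int(v) for k, v in d["partition"].items()}
    Path(path).write_text(json.dumps(d, indent=2))


def memory_to_json(result: MemoryResult, path) -> None:
    Path(path).write_text(json.dumps({
        "mc": result.mc,
        "decay_tau_fit": result.decay_tau_fit,
        "lambda": result.lam,
        "f_tau": {str(k): v for k, v in result.f_tau.items()},
    }, indent=2))


def memory_to_csv(result: MemoryResult, path) -> None:
    pd.DataFrame(
        {"tau": list(result.f_tau.keys()), "f_tau": list(result.f_tau.values())}
    ).to_csv(path, index=False)


def trial_log_to_jsonl(log, path) -> None:
    with open(path, "w") as fh:
        for rec in log.frames.to_dict(orient="records"):
            fh.write(json.dumps(rec) + "\n")
        for rec in log.outcomes.to_dict(orient="records"):
            fh.write(json.dumps({"outcome": rec}) + "\n")
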