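"""Readers and writers for the pipeline's on-disk formats.

Spike times, ground truth, labels and PETHs travel as plain CSV; manifests,
summaries and reports as JSON; raw voltage traces as HDF5 (one dataset per
neuron, with sampling metadata in attributes).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .trains import SpikeTrain

__all__ = [
    "spike_table_frame",
    "spike_table_text",
    "write_spike_table",
    "read_spike_table",
    "write_ground_truth",
    "read_ground_truth",
    "write_json",
    "read_json",
    "write_traces",
    "read_traces",
]


def spike_table_frame(trains: Sequence[SpikeTrain]) -> pd.DataFrame:
    """Long-format spike table: one row per spike."""
    rows = {
        "neuron_id": np.concatenate(
            [np.full(tr.n_spikes, tr.neuron_id, dtype=int) for tr in trains]
        )
        if trains
        else np.empty(0, dtype=int),
        "group": np.concatenate([np.full(tr.n_spikes, tr.group, dtype=object) for tr in trains])
        if trains
        else np.empty(0, dtype=object),
        "region": np.concatenate([np.full(tr.n_spikes, tr.region, dtype=object) for tr in trains])
        if trains
        else np.empty(0, dtype=object),
        "t": np.concatenate([tr.times for tr in trains]) if trains else np.empty(0),
    }
    return pd.DataFrame(rows)


def spike_table_text(trains: Sequence[SpikeTrain]) -> str:
    return spike_table_frame(trains).to_csv(index=False)


def write_spike_table(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    Path(path).write_text(spike_table_text(trains))


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Rebuild per-neuron spike trains from a long-format spike CSV."""
    df = pd.read_csv(path, dtype={"group": str, "region": str})
    trains: list[SpikeTrain] = []
    for nid, sub in df.groupby("neuron_id", sort=True):
        trains.append(
            SpikeTrain(
                neuron_id=int(nid),
                times=np.sort(sub["t"].to_numpy(float)),
                group=str(sub["group"].iloc[0]),
                region=str(sub["region"].iloc[0]),
            )
        )
    return trains


def write_ground_truth(truths: Iterable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "neuron_id": [g.neuron_id for g in truths],
            "true_type": [g.true_type for g in truths],
            "r_be": [g.r_be for g in truths],
            "r_tt": [g.r_tt for g in truths],
            "r_pe": [g.r_pe for g in truths],
        }
    )
    df.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_traces(traces: Sequence, path: str | Path) -> None:
    """Store raw traces in HDF5: dataset ``neuron_<k>`` per trace."""
    with h5py.File(path, "w") as f:
        for k, tr in enumerate(traces):
            d = f.create_dataset(f"neuron_{k}", data=tr.samples)
            d.attrs["sampling_rate"] = tr.sampling_rate
            d.attrs["noise_sd"] = tr.noise_sd
            d.attrs["t_start"] = tr.t_start
            d.attrs["true_spike_times"] = tr.true_spike_times


def read_traces(path: str | Path) -> list[dict]:
    """Load traces as dicts (samples, sampling_rate, noise_sd, t_start, true_spike_times)."""
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            d = f[name]
            out.append(
                {
                    "samples": d[()],
                    "sampling_rate": float(d.attrs["sampling_rate"]),
                    "noise_sd": float(d.attrs["noise_sd"]),
                    "t_start": float(d.attrs["t_start"]),
                    "true_spike_times": np.asarray(d.attrs["true_spike_times"]),
                }
            )
    return out
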