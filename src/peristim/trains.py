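"""Spike-train container.

All spike times are in seconds relative to stimulation onset (t = 0);
negative times are pre-stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SpikeTrain:
    """One neuron's spike times aligned to stimulation onset.

    Parameters
    ----------
    neuron_id
        Identifier, unique within a cohort.
    times
        Strictly increasing spike times in seconds; t = 0 is stimulation onset.
    group
        Experimental group label (e.g. ``control``, ``rotenone``, ``rotenone_bm``).
    region
        Recorded structure (e.g. ``SNc``, ``SNr``).
    """

    neuron_id: int
    times: np.ndarray
    group: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"spike times of neuron {self.neuron_id} are not strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)
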