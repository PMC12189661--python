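"""Peri-event time histograms, rasters and window firing rates.

The analysis partitions each aligned record into three contiguous half-open
windows: BE ``[t0, 0)`` before the event, TT ``[0, t2)`` during tetanization,
and PE ``[t2, t3)`` after it.  Mean firing rates inside the windows (M_BE,
M_TT, M_PE) are the basis for response classification and the fold-change
ratio tables; PETHs (summed and averaged across neurons) and the difference
curve are the time-resolved views of the same data.

Conventions
-----------
* All windows and bins are half-open ``[a, b)``; a spike exactly at a
  boundary belongs to the bin on the right.
* The difference curve is the averaged per-neuron bin rate minus the pooled
  baseline (BE) rate of the same set of neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trains import SpikeTrain

__all__ = [
    "WindowDef",
    "WindowRates",
    "PethResult",
    "window_rates",
    "pooled_window_rates",
    "pool_rates",
    "build_peth",
    "raster",
]


@dataclass(frozen=True)
class WindowDef:
    """The BE / TT / PE analysis windows, in seconds relative to onset.

    Defaults follow a 20 s baseline, a 1 s stimulation train and a 20 s
    post-stimulus period: BE = [-20, 0), TT = [0, 1), PE = [1, 21).
    """

    be: tuple[float, float] = (-20.0, 0.0)
    tt: tuple[float, float] = (0.0, 1.0)
    pe: tuple[float, float] = (1.0, 21.0)

    def __post_init__(self) -> None:
        b0, b1 = self.be
        t0, t1 = self.tt
        p0, p1 = self.pe
        if not (b0 < b1 and t0 < t1 and p0 < p1):
            raise ValueError("each window must have positive duration")
        if b1 != t0 or t1 != p0:
            raise ValueError("windows must be contiguous: BE.end == TT.start, TT.end == PE.start")
        if t0 != 0.0:
            raise ValueError("TT must start at t = 0 (stimulation onset)")

    @property
    def span(self) -> tuple[float, float]:
        return (self.be[0], self.pe[1])

    @property
    def durations(self) -> tuple[float, float, float]:
        return (
            self.be[1] - self.be[0],
            self.tt[1] - self.tt[0],
            self.pe[1] - self.pe[0],
        )


@dataclass(frozen=True)
class WindowRates:
    """Mean firing rates (spikes/s) and raw counts per analysis window."""

    m_be: float
    m_tt: float
    m_pe: float
    counts: tuple[int, int, int]
    durations: tuple[float, float, float]

    @classmethod
    def from_counts(
        cls, counts: Sequence[int], durations: Sequence[float]
    ) -> "WindowRates":
        c = tuple(int(x) for x in counts)
        d = tuple(float(x) for x in durations)
        if any(x < 0 for x in c) or any(x <= 0 for x in d):
            raise ValueError("counts must be >= 0 and durations > 0")
        return cls(c[0] / d[0], c[1] / d[1], c[2] / d[2], c, d)


@dataclass(frozen=True)
class PethResult:
    """Summed and averaged peri-event time histogram over a set of neurons.

    ``summed_counts[i]`` is the total number of spikes of all neurons in
    ``[bin_edges[i], bin_edges[i+1])``; ``averaged_rate`` divides by the
    number of neurons and the bin width (spikes/s per neuron);
    ``difference_curve`` subtracts the pooled BE rate from ``averaged_rate``.
    """

    bin_edges: np.ndarray
    summed_counts: np.ndarray
    averaged_rate: np.ndarray
    difference_curve: np.ndarray
    n_neurons: int
    pooled_be_rate: float
    truncated: bool


def _count_in(times: np.ndarray, lo: float, hi: float) -> int:
    # times are sorted; half-open [lo, hi)
    return int(np.searchsorted(times, hi, side="left") - np.searchsorted(times, lo, side="left"))


def window_rates(train: SpikeTrain, windows: WindowDef | None = None) -> WindowRates:
    """Mean firing rate of one neuron in each of the BE/TT/PE windows.

    Spikes outside the overall span are ignored.
    """
    w = windows or WindowDef()
    t = train.times
    counts = (
        _count_in(t, *w.be),
        _count_in(t, *w.tt),
        _count_in(t, *w.pe),
    )
    return WindowRates.from_counts(counts, w.durations)


def pool_rates(rates: Sequence[WindowRates]) -> WindowRates:
    """Pool per-neuron window rates: total count / (n_neurons x duration).

    All entries must share the same window durations.  With equal durations
    this equals the arithmetic mean of the per-neuron rates.
    """
    if not rates:
        raise ValueError("cannot pool an empty list of window rates")
    d0 = rates[0].durations
    for r in rates:
        if r.durations != d0:
            raise ValueError("pooling requires identical window durations")
    n = len(rates)
    totals = tuple(sum(r.counts[k] for r in rates) for k in range(3))
    return WindowRates(
        totals[0] / (n * d0[0]),
        totals[1] / (n * d0[1]),
        totals[2] / (n * d0[2]),
        totals,
        d0,
    )


def pooled_window_rates(
    trains: Sequence[SpikeTrain], windows: WindowDef | None = None
) -> WindowRates:
    """Window rates pooled over a set of neurons.

    Counts are summed across neurons and divided by ``n_neurons x duration``,
    matching the normalisation of summed histograms.  For a single train this
    reduces to :func:`window_rates`.
    """
    if not trains:
        raise ValueError("cannot pool an empty list of spike trains")
    w = windows or WindowDef()
    return pool_rates([window_rates(tr, w) for tr in trains])


def build_peth(
    trains: Sequence[SpikeTrain],
    bin_width: float = 1.0,
    span: WindowDef | None = None,
) -> PethResult:
    """Summed/averaged PETH and difference curve over a group of neurons.

    The span runs from the start of BE to the end of PE.  If ``bin_width``
    does not divide the span evenly the last partial bin is dropped and the
    result is flagged ``truncated``.
    """
    if not trains:
        raise ValueError("build_peth requires at least one spike train")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    w = span or WindowDef()
    t0, t1 = w.span
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("span shorter than one bin")
    truncated = abs(t0 + n_bins * bin_width - t1) > 1e-9
    edges = t0 + bin_width * np.arange(n_bins + 1)
    all_times = np.concatenate([tr.times for tr in trains]) if trains else np.empty(0)
    summed, _ = np.histogram(all_times, bins=edges)
    n = len(trains)
    averaged = summed / (n * bin_width)
    pooled_be = pooled_window_rates(trains, w).m_be
    return PethResult(
        bin_edges=edges,
        summed_counts=summed.astype(int),
        averaged_rate=averaged,
        difference_curve=averaged - pooled_be,
        n_neurons=n,
        pooled_be_rate=pooled_be,
        truncated=truncated,
    )


def raster(trains: Sequence[SpikeTrain]) -> list[tuple[int, np.ndarray]]:
    """Per-neuron ordered spike-time lists, for plotting or export.

    A lossless, order-preserving restructuring: flattening the returned rows
    recovers exactly the input spike times.
    """
    return [(tr.neuron_id, tr.times.copy()) for tr in trains]
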