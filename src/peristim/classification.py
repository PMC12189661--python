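"""Four-way tetanic / post-tetanic response classification.

A neuron's peri-stimulus label compares its tetanization-window rate M_TT
with the baseline M_BE: tetanic depression (TD) if the rate drops, tetanic
potentiation (TP) if it rises.  The post-stimulus label does the same with
the post-event rate M_PE (PTD / PTP).  A relative dead-band ``epsilon``
around the baseline absorbs ties: changes smaller than ``epsilon * M_BE``
in either direction are "no response" (NR), and NR neurons are excluded
from the four-type proportion table.

Fold changes use the magnitude convention max/min >= 1, so both excitatory
and inhibitory effects are reported as ratios above 1; group-level ratios
are computed from pooled window rates (total spikes over neurons), not from
averaging per-neuron ratios, which avoids ratio-of-small-counts bias in the
1 s tetanization window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .peth import WindowRates, pool_rates
from .synthetic import TYPE_ORDER

__all__ = [
    "ResponseLabel",
    "GroupSummary",
    "classify_neuron",
    "fold_change",
    "summarize_group",
    "labels_frame",
]

NR = "NR"


@dataclass(frozen=True)
class ResponseLabel:
    """Peri-stimulus class (TD/TP/NR) x post-stimulus class (PTD/PTP/NR)."""

    peri: str
    post: str

    def __post_init__(self) -> None:
        if self.peri not in ("TD", "TP", NR):
            raise ValueError(f"invalid peri label {self.peri!r}")
        if self.post not in ("PTD", "PTP", NR):
            raise ValueError(f"invalid post label {self.post!r}")

    @property
    def combined(self) -> str:
        if self.peri == NR or self.post == NR:
            return NR
        return f"{self.peri}-{self.post}"


def _direction(m_be: float, m_x: float, epsilon: float) -> int:
    """-1 = decrease, +1 = increase, 0 = within the dead-band."""
    if m_be == 0:
        return 1 if m_x > 0 else 0  # convention: silent baseline, any firing = increase
    if m_x < m_be * (1 - epsilon):
        return -1
    if m_x > m_be * (1 + epsilon):
        return 1
    return 0


def classify_neuron(rates: WindowRates, epsilon: float = 0.05) -> ResponseLabel:
    """Assign the peri/post response label from the window-rate triple.

    ``epsilon`` is the relative dead-band: M_TT (resp. M_PE) must differ
    from M_BE by more than ``epsilon * M_BE`` to count as TD/TP (PTD/PTP).
    A silent baseline with non-zero activity counts as an increase; an
    all-zero triple is NR.
    """
    if not all(math.isfinite(v) for v in (rates.m_be, rates.m_tt, rates.m_pe)):
        raise ValueError("window rates must be finite")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    d_tt = _direction(rates.m_be, rates.m_tt, epsilon)
    d_pe = _direction(rates.m_be, rates.m_pe, epsilon)
    peri = {-1: "TD", 0: NR, 1: "TP"}[d_tt]
    post = {-1: "PTD", 0: NR, 1: "PTP"}[d_pe]
    return ResponseLabel(peri, post)


def fold_change(m_be: float, m_x: float, cap: float = 1e6) -> float:
    """Magnitude fold change max/min >= 1 between two rates.

    Reported ratios are above 1 for both directions of effect.  If exactly
    one rate is zero the ratio is returned capped at ``cap``; if both are
    zero it is undefined and NaN is returned.
    """
    if m_be < 0 or m_x < 0:
        raise ValueError("rates must be non-negative")
    lo, hi = min(m_be, m_x), max(m_be, m_x)
    if hi == 0:
        return math.nan
    if lo == 0:
        return cap
    return min(hi / lo, cap)


@dataclass(frozen=True)
class GroupSummary:
    """Per-condition counts, proportions and fold-change ratios by type.

    ``proportions`` are exact percentages of classified (non-NR) neurons;
    ``proportions_int`` rounds them to integer percent for report parity.
    ``ratio_tt`` / ``ratio_pe`` are magnitude fold changes of the pooled
    window rates of each type's neurons.
    """

    group: str
    region: str
    n_neurons: int
    n_classified: int
    n_nr: int
    counts: Mapping[str, int]
    proportions: Mapping[str, float]
    proportions_int: Mapping[str, int]
    ratio_tt: Mapping[str, float]
    ratio_pe: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "region": self.region,
            "n_neurons": self.n_neurons,
            "n_classified": self.n_classified,
            "n_nr": self.n_nr,
            "counts": dict(self.counts),
            "proportions": dict(self.proportions),
            "proportions_int": dict(self.proportions_int),
            "ratio_tt": dict(self.ratio_tt),
            "ratio_pe": dict(self.ratio_pe),
        }


def summarize_group(
    labels: Sequence[ResponseLabel],
    rates: Sequence[WindowRates],
    group: str = "",
    region: str = "",
) -> GroupSummary:
    """Aggregate per-neuron labels and rates into the table-shaped summary.

    Proportions are taken over classified (non-NR) neurons; the per-type
    ratios come from pooling the window rates of that type's members and
    applying the magnitude fold change.  Raises if no neuron is classified.
    """
    if len(labels) != len(rates):
        raise ValueError("labels and rates must align one-to-one")
    if not labels:
        raise ValueError("summarize_group requires at least one neuron")
    by_type: dict[str, list[WindowRates]] = {t: [] for t in TYPE_ORDER}
    n_nr = 0
    for lab, r in zip(labels, rates):
        c = lab.combined
        if c == NR:
            n_nr += 1
        else:
            by_type[c].append(r)
    n_classified = len(labels) - n_nr
    if n_classified == 0:
        raise ValueError(
            f"all {len(labels)} neurons are NR (within the dead-band); "
            "nothing to tabulate — check windows, epsilon, or firing rates"
        )
    counts = {t: len(v) for t, v in by_type.items()}
    proportions = {t: 100.0 * counts[t] / n_classified for t in TYPE_ORDER}
    proportions_int = {t: int(round(proportions[t])) for t in TYPE_ORDER}
    ratio_tt: dict[str, float] = {}
    ratio_pe: dict[str, float] = {}
    for t in TYPE_ORDER:
        if counts[t] == 0:
            ratio_tt[t] = math.nan
            ratio_pe[t] = math.nan
            continue
        pooled = pool_rates(by_type[t])
        ratio_tt[t] = fold_change(pooled.m_be, pooled.m_tt)
        ratio_pe[t] = fold_change(pooled.m_be, pooled.m_pe)
    return GroupSummary(
        group=group,
        region=region,
        n_neurons=len(labels),
        n_classified=n_classified,
        n_nr=n_nr,
        counts=counts,
        proportions=proportions,
        proportions_int=proportions_int,
        ratio_tt=ratio_tt,
        ratio_pe=ratio_pe,
    )


def labels_frame(
    neuron_ids: Sequence[int],
    rates: Sequence[WindowRates],
    labels: Sequence[ResponseLabel],
) -> pd.DataFrame:
    """Per-neuron label table (neuron_id, m_be, m_tt, m_pe, peri, post, combined)."""
    if not (len(neuron_ids) == len(rates) == len(labels)):
        raise ValueError("neuron_ids, rates and labels must align")
    return pd.DataFrame(
        {
            "neuron_id": list(neuron_ids),
            "m_be": [r.m_be for r in rates],
            "m_tt": [r.m_tt for r in rates],
            "m_pe": [r.m_pe for r in rates],
            "c_be": [r.counts[0] for r in rates],
            "c_tt": [r.counts[1] for r in rates],
            "c_pe": [r.counts[2] for r in rates],
            "peri": [l.peri for l in labels],
            "post": [l.post for l in labels],
            "combined": [l.combined for l in labels],
        }
    )


def frame_to_labels(
    df: pd.DataFrame, durations: tuple[float, float, float]
) -> tuple[list[ResponseLabel], list[WindowRates]]:
    """Rebuild labels and window rates from a labels table (see labels_frame)."""
    labels = [ResponseLabel(p, q) for p, q in zip(df["peri"], df["post"])]
    rates = [
        WindowRates.from_counts((a, b, c), durations)
        for a, b, c in zip(df["c_be"], df["c_tt"], df["c_pe"])
    ]
    return labels, rates
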