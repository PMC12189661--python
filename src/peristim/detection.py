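"""Spike detection by threshold crossing with amplitude-window discrimination.

Mirrors a hardware window discriminator: a candidate event is a contiguous
run of samples beyond the threshold; the event is accepted only if the run's
extremum lies inside the configured amplitude window, and events closer than
the refractory period to the previously accepted one are dropped.  Event
times are reported at the extremum sample on the trace's clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import RawTrace

__all__ = ["DetectionConfig", "detect_spikes", "score_detection"]


@dataclass(frozen=True)
class DetectionConfig:
    """Threshold and amplitude window for spike selection.

    ``amplitude_window`` bounds the accepted extremum voltage (mV);
    ``threshold`` must lie inside it for the chosen polarity.  For
    ``polarity="negative"`` both threshold and window are interpreted on the
    negative-going signal (more negative = larger excursion).
    """

    threshold: float
    amplitude_window: tuple[float, float]
    refractory_ms: float = 1.0
    polarity: str = "positive"

    def __post_init__(self) -> None:
        a, b = self.amplitude_window
        if a > b:
            raise ValueError("amplitude_window must satisfy a_min <= a_max")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if not (a <= self.threshold <= b):
            raise ValueError("threshold must lie inside the amplitude window")


def detect_spikes(trace: RawTrace, config: DetectionConfig) -> np.ndarray:
    """Spike times (s) recovered from a raw trace.

    One event per threshold crossing whose local extremum falls inside the
    amplitude window; an empty result is valid.  NaN samples are rejected.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size == 0:
        raise ValueError("trace is empty")
    if np.isnan(x).any():
        raise ValueError("trace contains NaN samples")
    a, b = config.amplitude_window
    thr = config.threshold
    if config.polarity == "negative":
        x = -x
        thr, a, b = -thr, -b, -a
    above = x >= thr
    if not above.any():
        return np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, x.size]
    refractory = config.refractory_ms * 1e-3
    out: list[float] = []
    last = -np.inf
    for s, e in zip(starts, ends):
        k = s + int(np.argmax(x[s:e]))
        amp = x[k]
        if not (a <= amp <= b):
            continue
        t = trace.t_start + k / trace.sampling_rate
        if t - last < refractory:
            continue
        out.append(t)
        last = t
    return np.asarray(out)


def score_detection(
    detected: np.ndarray, truth: np.ndarray, tolerance_ms: float = 1.0
) -> dict:
    """Recall and precision of detected spike times against ground truth.

    Greedy one-to-one matching in time order within ``tolerance_ms``.
    Conventions: with no true spikes recall is 1; with no detections
    precision is reported as 1 and the result is flagged
    ``no_detections`` (an empty detection list makes no false claims).
    """
    if tolerance_ms <= 0:
        raise ValueError("tolerance_ms must be positive")
    det = np.sort(np.asarray(detected, dtype=float))
    tru = np.sort(np.asarray(truth, dtype=float))
    tol = tolerance_ms * 1e-3
    i = j = matched = 0
    while i < det.size and j < tru.size:
        d = det[i] - tru[j]
        if abs(d) <= tol:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    flags = []
    if det.size == 0 and tru.size > 0:
        flags.append("no_detections")
    recall = matched / tru.size if tru.size else 1.0
    precision = matched / det.size if det.size else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_matched": matched,
        "n_detected": int(det.size),
        "n_true": int(tru.size),
        "flags": flags,
    }
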