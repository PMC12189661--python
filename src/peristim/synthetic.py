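"""Synthetic cohort generator with known ground truth.

Each simulated neuron fires as a piecewise-homogeneous point process over the
BE / TT / PE windows: a tonic baseline rate ``r_be`` drawn uniformly from the
cohort's baseline range, a tetanization-window rate ``r_tt`` and a post-event
rate ``r_pe`` obtained by applying the neuron's response-type fold changes to
the baseline.  Depressions divide the baseline by the fold, potentiations
multiply by it, so the configured magnitude ratios M_BE/M_TT and M_BE/M_PE
are exact in the generating rates.  The default process is Poisson; a
dispersion knob (squared coefficient of variation of the inter-spike
interval) switches to a gamma renewal process when over- or
under-dispersion is wanted.

Optionally, a raw extracellular voltage trace can be synthesised from a
spike train by placing a template waveform at every spike time and adding
Gaussian noise, providing a substrate for the amplitude-discrimination
detector with scoreable ground truth.

Randomness is fully determined by ``(spec.seed, neuron index)``, so cohorts
are reproducible neuron-by-neuron regardless of generation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .peth import WindowDef
from .trains import SpikeTrain

__all__ = [
    "TYPE_ORDER",
    "StimulationProtocol",
    "CohortSpec",
    "NeuronGroundTruth",
    "RawTrace",
    "allocate_types",
    "sample_neuron_params",
    "generate_spike_train",
    "default_spike_template",
    "generate_raw_trace",
    "generate_cohort",
]

#: Canonical order of the four tetanic/post-tetanic response types.
TYPE_ORDER: tuple[str, ...] = ("TD-PTD", "TD-PTP", "TP-PTP", "TP-PTD")


@dataclass(frozen=True)
class StimulationProtocol:
    """High-frequency stimulation train parameters.

    Defaults describe a 100 Hz, 1 s train of 0.05 ms rectangular pulses
    (amplitude 0.12-0.18 mV, 0.32 mA) delivered at ``onset_time``, which
    defines t = 0 for all alignment.
    """

    pulse_frequency: float = 100.0  # Hz
    train_duration: float = 1.0  # s
    pulse_width: float = 0.05  # ms
    pulse_amplitude: float = 0.15  # mV
    current: float = 0.32  # mA
    onset_time: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.pulse_frequency <= 0 or self.train_duration <= 0:
            raise ValueError("pulse_frequency and train_duration must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one synthetic cohort.

    ``type_mix`` maps response types to proportions (summing to 1); the
    realised counts follow a largest-remainder quota so the mixture is exact.
    ``fold_tt`` / ``fold_pe`` are magnitude fold changes (>= 1) applied to
    the baseline rate according to each type's depression/potentiation
    halves.  ``dispersion`` is the squared ISI coefficient of variation
    (1 = Poisson).
    """

    group: str
    region: str
    n_neurons: int
    type_mix: Mapping[str, float]
    baseline_rate_range: tuple[float, float] = (8.0, 12.0)
    fold_tt: Mapping[str, float] = field(default_factory=dict)
    fold_pe: Mapping[str, float] = field(default_factory=dict)
    windows: WindowDef = field(default_factory=WindowDef)
    seed: int = 20250528
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not self.type_mix:
            raise ValueError("type_mix must not be empty")
        for t in self.type_mix:
            if t not in TYPE_ORDER:
                raise ValueError(f"unknown response type {t!r} in type_mix")
        if any(p < 0 for p in self.type_mix.values()):
            raise ValueError("type_mix proportions must be >= 0")
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_mix proportions must sum to 1 (got {total!r})")
        lo, hi = self.baseline_rate_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_rate_range must satisfy 0 < low <= high")
        for name, folds in (("fold_tt", self.fold_tt), ("fold_pe", self.fold_pe)):
            for t in self.type_mix:
                if self.type_mix[t] > 0 and t not in folds:
                    raise ValueError(f"{name} missing an entry for type {t!r}")
            if any(f < 1 for f in folds.values()):
                raise ValueError(f"{name} folds must be >= 1 (magnitude convention)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class NeuronGroundTruth:
    """True generating rates of one synthetic neuron."""

    neuron_id: int
    true_type: str
    r_be: float
    r_tt: float
    r_pe: float


@dataclass(frozen=True)
class RawTrace:
    """Synthetic extracellular voltage trace with known spike times.

    ``samples`` are in mV at ``sampling_rate`` Hz, starting at ``t_start``
    seconds on the aligned clock.
    """

    samples: np.ndarray
    sampling_rate: float
    t_start: float
    noise_sd: float
    true_spike_times: np.ndarray
    template: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) / self.sampling_rate


def allocate_types(type_mix: Mapping[str, float], n: int) -> list[str]:
    """Quota allocation of ``n`` neurons over response types.

    Largest-remainder (Hamilton) method: each type receives
    ``floor(p * n)`` neurons, the remaining seats go to the largest
    fractional remainders, ties broken by canonical type order.  The result
    lists the type of each neuron index, grouped in canonical order.
    """
    if not type_mix:
        raise ValueError("type_mix must not be empty")
    types = [t for t in TYPE_ORDER if t in type_mix]
    quotas = np.array([type_mix[t] * n for t in types])
    base = np.floor(quotas + 1e-9).astype(int)
    remainder = quotas - base
    short = n - int(base.sum())
    if short > 0:
        # stable sort: ties resolved by canonical order
        order = np.argsort(-remainder, kind="stable")
        for k in order[:short]:
            base[k] += 1
    out: list[str] = []
    for t, c in zip(types, base):
        out.extend([t] * int(c))
    return out


def _derived_rates(true_type: str, r_be: float, fold_tt: float, fold_pe: float) -> tuple[float, float]:
    peri, post = true_type.split("-")
    r_tt = r_be / fold_tt if peri == "TD" else r_be * fold_tt
    r_pe = r_be / fold_pe if post == "PTD" else r_be * fold_pe
    return r_tt, r_pe


def _param_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 0, index])


def _train_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1, index])


def sample_neuron_params(spec: CohortSpec, index: int) -> NeuronGroundTruth:
    """Ground-truth parameters of neuron ``index`` under ``spec``.

    The response type comes from the deterministic quota allocation of the
    type mixture, so realised counts match the mixture exactly; the baseline
    rate is drawn uniformly from the cohort's range using a stream seeded by
    ``(spec.seed, index)``.
    """
    if not 0 <= index < spec.n_neurons:
        raise ValueError(f"index {index} out of range for n_neurons={spec.n_neurons}")
    true_type = allocate_types(spec.type_mix, spec.n_neurons)[index]
    rng = _param_rng(spec, index)
    r_be = float(rng.uniform(*spec.baseline_rate_range))
    r_tt, r_pe = _derived_rates(
        true_type, r_be, spec.fold_tt[true_type], spec.fold_pe[true_type]
    )
    return NeuronGroundTruth(index, true_type, r_be, r_tt, r_pe)


def _window_spikes(
    rate: float, lo: float, hi: float, rng: np.random.Generator, dispersion: float
) -> np.ndarray:
    if rate < 0:
        raise ValueError("firing rate must be non-negative")
    if rate == 0:
        return np.empty(0)
    if dispersion == 1.0:
        n = rng.poisson(rate * (hi - lo))
        return np.sort(rng.uniform(lo, hi, n))
    # Gamma renewal: ISI ~ Gamma(shape=1/dispersion, mean=1/rate).
    shape = 1.0 / dispersion
    scale = dispersion / rate
    out = []
    t = lo + rng.gamma(shape, scale)
    while t < hi:
        out.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(out)


def generate_spike_train(
    gt: NeuronGroundTruth,
    windows: WindowDef,
    rng: np.random.Generator,
    dispersion: float = 1.0,
) -> SpikeTrain:
    """Simulate one neuron's spike train over the BE/TT/PE windows.

    Piecewise-homogeneous process with rates ``(r_be, r_tt, r_pe)``; under
    the default Poisson process the count in each window is Poisson with
    mean rate x duration.  Spike times are strictly increasing and fully
    determined by ``rng``.
    """
    w = windows
    parts = [
        _window_spikes(gt.r_be, *w.be, rng, dispersion),
        _window_spikes(gt.r_tt, *w.tt, rng, dispersion),
        _window_spikes(gt.r_pe, *w.pe, rng, dispersion),
    ]
    t = np.sort(np.concatenate(parts))
    # Resolve (vanishingly rare) exact ties so times are strictly increasing.
    for i in np.flatnonzero(np.diff(t) <= 0):
        t[i + 1] = np.nextafter(t[i], np.inf)
    return SpikeTrain(neuron_id=gt.neuron_id, times=t)


def default_spike_template(
    sampling_rate: float, width_ms: float = 1.0, amplitude_mv: float = 0.15
) -> np.ndarray:
    """Biphasic extracellular spike waveform sampled at ``sampling_rate``.

    A positive Gaussian lobe (peak ``amplitude_mv``) followed by a shallower
    negative after-wave, ~``width_ms`` wide overall; amplitude defaults to
    the middle of the recorded 0.12-0.18 mV range.
    """
    n = int(round(width_ms * 1e-3 * sampling_rate))
    if n < 4:
        raise ValueError("sampling_rate too low to represent the spike template")
    t = np.linspace(-0.5, 0.5, n)
    main = np.exp(-((t + 0.15) ** 2) / (2 * 0.08**2))
    after = -0.35 * np.exp(-((t - 0.2) ** 2) / (2 * 0.14**2))
    wave = main + after
    return amplitude_mv * wave / wave.max()  # peak equals amplitude_mv exactly


def generate_raw_trace(
    train: SpikeTrain,
    template: np.ndarray | None = None,
    noise_sd: float = 0.01,
    sampling_rate: float = 20000.0,
    span: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> RawTrace:
    """Synthesise a raw voltage trace: template at each spike time plus noise.

    The template's peak sample is aligned to each spike time (rounded to the
    sample grid); ``true_spike_times`` are retained for detection scoring.
    """
    if sampling_rate < 10000:
        raise ValueError("sampling_rate must be >= 10 kHz to resolve spike waveforms")
    if template is None:
        template = default_spike_template(sampling_rate)
    template = np.asarray(template, dtype=float)
    if template.size < 4:
        raise ValueError("sampling_rate too low to represent the spike template")
    if template.max() <= 0:
        raise ValueError("template peak amplitude must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if span is None:
        if train.n_spikes:
            span = (float(train.times[0]) - 0.05, float(train.times[-1]) + 0.05)
        else:
            span = (0.0, 1.0)
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span must have positive duration")
    n = int(round((t1 - t0) * sampling_rate))
    samples = np.zeros(n)
    peak_off = int(np.argmax(template))
    for ts in train.times:
        center = int(round((ts - t0) * sampling_rate))
        a = center - peak_off
        b = a + template.size
        ta, tb = max(a, 0), min(b, n)
        if ta < tb:
            samples[ta:tb] += template[ta - a : tb - a]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        samples = samples + rng.normal(0.0, noise_sd, n)
    return RawTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        t_start=t0,
        noise_sd=noise_sd,
        true_spike_times=train.times.copy(),
        template=template,
    )


def _spec_dict(spec: CohortSpec) -> dict:
    return {
        "group": spec.group,
        "region": spec.region,
        "n_neurons": spec.n_neurons,
        "type_mix": dict(spec.type_mix),
        "baseline_rate_range": list(spec.baseline_rate_range),
        "fold_tt": dict(spec.fold_tt),
        "fold_pe": dict(spec.fold_pe),
        "windows": {"be": list(spec.windows.be), "tt": list(spec.windows.tt), "pe": list(spec.windows.pe)},
        "seed": spec.seed,
        "dispersion": spec.dispersion,
    }


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[SpikeTrain], list[NeuronGroundTruth], dict]:
    """Generate a full cohort: spike trains, ground truth and a manifest.

    When ``out_dir`` is given, writes ``spikes.csv`` (neuron_id, group,
    region, t), ``ground_truth.csv`` and ``manifest.json`` there.  The
    manifest echoes the spec, the seed and a SHA-256 checksum of the spike
    table, so byte-identical reruns are verifiable.
    """
    from . import io as _io  # deferred: io is a leaf module

    truths: list[NeuronGroundTruth] = []
    trains: list[SpikeTrain] = []
    for i in range(spec.n_neurons):
        gt = sample_neuron_params(spec, i)
        train = generate_spike_train(gt, spec.windows, _train_rng(spec, i), spec.dispersion)
        truths.append(gt)
        trains.append(
            SpikeTrain(train.neuron_id, train.times, group=spec.group, region=spec.region)
        )
    table_text = _io.spike_table_text(trains)
    manifest = {
        "spec": _spec_dict(spec),
        "seed": spec.seed,
        "n_neurons": spec.n_neurons,
        "spike_table_sha256": hashlib.sha256(table_text.encode()).hexdigest(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            (out / "spikes.csv").write_text(table_text)
            _io.write_ground_truth(truths, out / "ground_truth.csv")
            _io.write_json(manifest, out / "manifest.json")
        except OSError as e:
            raise OSError(f"failed writing cohort outputs under {out}: {e}") from e
        manifest["files"] = {
            "spikes": str(out / "spikes.csv"),
            "ground_truth": str(out / "ground_truth.csv"),
            "manifest": str(out / "manifest.json"),
        }
    return trains, truths, manifest
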