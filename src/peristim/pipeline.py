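"""End-to-end run: simulate (or ingest), rate, classify, summarize, compare.

A :class:`RunConfig` names the cohorts (by preset) and the analysis
parameters; :func:`run_pipeline` executes every stage and returns a report
dictionary mirroring the published table structure, optionally writing
JSON/CSV artifacts.  Reports carry no timestamps, so identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .classification import classify_neuron, labels_frame, summarize_group
from .peth import WindowDef, build_peth, window_rates
from .presets import PRESET_NAMES, preset_spec
from .stats import cohens_d, proportion_test, students_t
from .synthetic import TYPE_ORDER, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "render_tables"]

log = logging.getLogger("peristim")

_ALLOWED_KEYS = {
    "presets",
    "n_neurons",
    "windows",
    "bin_width",
    "epsilon",
    "seed",
    "out_dir",
    "dispersion",
    "baseline_rate_range",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    presets: tuple[str, ...] = PRESET_NAMES
    n_neurons: int | None = None  # None = published cohort sizes
    windows: WindowDef = field(default_factory=WindowDef)
    bin_width: float = 1.0
    epsilon: float = 0.05
    seed: int = 20250528
    out_dir: str | None = None
    dispersion: float = 1.0
    baseline_rate_range: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self) -> None:
        for p in self.presets:
            if p not in PRESET_NAMES:
                raise ValueError(f"unknown preset {p!r}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        unknown = set(data) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(data)
        if "windows" in kw:
            w = kw["windows"]
            kw["windows"] = WindowDef(tuple(w["be"]), tuple(w["tt"]), tuple(w["pe"]))
        if "presets" in kw:
            kw["presets"] = tuple(kw["presets"])
        if "baseline_rate_range" in kw:
            kw["baseline_rate_range"] = tuple(kw["baseline_rate_range"])
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return {
            "presets": list(self.presets),
            "n_neurons": self.n_neurons,
            "windows": {
                "be": list(self.windows.be),
                "tt": list(self.windows.tt),
                "pe": list(self.windows.pe),
            },
            "bin_width": self.bin_width,
            "epsilon": self.epsilon,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "dispersion": self.dispersion,
            "baseline_rate_range": list(self.baseline_rate_range),
        }


def _preset_seed(seed: int, k: int) -> int:
    # distinct deterministic stream per cohort, kept below 2**31
    return (seed + 7919 * (k + 1)) % 2**31


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> rate -> classify -> summarize -> compare.

    Returns the report dictionary; when ``config.out_dir`` is set, also
    writes per-cohort spike tables, label tables and PETH CSVs plus
    ``report.json`` and rendered proportion/ratio tables.
    """
    log.info(
        "pipeline run: seed=%d epsilon=%.3g bin_width=%.3g windows=%s presets=%s",
        config.seed,
        config.epsilon,
        config.bin_width,
        config.windows,
        ",".join(config.presets),
    )
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summaries: dict[str, dict] = {}
    per_neuron: dict[str, dict] = {}
    for k, preset in enumerate(config.presets):
        try:
            spec = preset_spec(
                preset,
                n_neurons=config.n_neurons,
                seed=_preset_seed(config.seed, k),
                baseline_rate_range=config.baseline_rate_range,
                windows=config.windows,
            )
            cohort_dir = out / preset if out is not None else None
            trains, truths, manifest = generate_cohort(spec, cohort_dir)
            rates = [window_rates(tr, config.windows) for tr in trains]
            labels = [classify_neuron(r, config.epsilon) for r in rates]
            summary = summarize_group(labels, rates, spec.group, spec.region)
            peth = build_peth(trains, config.bin_width, config.windows)
            summaries[preset] = summary.to_dict()
            per_neuron[preset] = {
                "rates": rates,
                "labels": labels,
                "ids": [tr.neuron_id for tr in trains],
            }
            if cohort_dir is not None:
                labels_frame(per_neuron[preset]["ids"], rates, labels).to_csv(
                    cohort_dir / "labels.csv", index=False
                )
                pd.DataFrame(
                    {
                        "bin_start": peth.bin_edges[:-1],
                        "bin_end": peth.bin_edges[1:],
                        "summed_count": peth.summed_counts,
                        "averaged_rate": peth.averaged_rate,
                        "difference": peth.difference_curve,
                    }
                ).to_csv(cohort_dir / "peth.csv", index=False)
        except Exception as e:
            raise RuntimeError(f"pipeline stage failed for cohort {preset!r}: {e}") from e

    report = {
        "config": config.to_dict(),
        "summaries": summaries,
        "comparisons": _comparisons(summaries, per_neuron),
    }
    if out is not None:
        _io.write_json(report, out / "report.json")
        props, ratios = render_tables(report)
        props.to_csv(out / "table_proportions.csv")
        ratios.to_csv(out / "table_ratios.csv")
    return report


def _prop_tests(sa: dict, sb: dict) -> dict:
    res = {}
    for t in TYPE_ORDER:
        r = proportion_test(
            sa["counts"][t], sa["n_classified"], sb["counts"][t], sb["n_classified"]
        )
        res[t] = r.to_dict()
    return res


def _pe_rate_test(pa: dict, pb: dict) -> dict:
    xa = [r.m_pe for r in pa["rates"]]
    xb = [r.m_pe for r in pb["rates"]]
    r = students_t(xa, xb)
    d = r.to_dict()
    d["note"] = "per-neuron post-event rates"
    return d


def _comparisons(summaries: dict, per_neuron: dict) -> dict:
    """Proportion tests per type (rotenone vs BM, SNc vs SNr) and rate t-tests.

    Effect sizes on rates use per-neuron post-event window rates; which
    sample the published effect sizes were computed on is not stated, so
    this choice is labelled in the output.
    """
    comp: dict = {"rotenone_vs_bm": {}, "snc_vs_snr": {}, "bm_vs_control": {}}
    for region in ("SNc", "SNr"):
        a, b = f"rotenone-{region}", f"bm-{region}"
        if a in summaries and b in summaries:
            comp["rotenone_vs_bm"][region] = _prop_tests(summaries[a], summaries[b])
        c = f"control-{region}"
        if c in summaries and b in summaries:
            comp["bm_vs_control"][region] = {
                "proportions": _prop_tests(summaries[c], summaries[b]),
                "post_event_rate": _pe_rate_test(per_neuron[c], per_neuron[b]),
            }
    for grp, label in (("control", "control"), ("rotenone", "rotenone"), ("bm", "rotenone_bm")):
        a, b = f"{grp}-SNc", f"{grp}-SNr"
        if a in summaries and b in summaries:
            comp["snc_vs_snr"][label] = {
                "proportions": _prop_tests(summaries[a], summaries[b]),
                "post_event_rate": _pe_rate_test(per_neuron[a], per_neuron[b]),
            }
    return comp


def render_tables(report: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the report as a proportions table and a fold-change ratio table.

    The proportions table has one row per response type (integer percent of
    classified neurons) and one column per cohort; the ratio table has a
    (type, ratio) row pair — M_BE/M_TT and M_BE/M_PE — per type.  Missing
    cohorts yield NaN columns with a warning.
    """
    summaries = report.get("summaries") or {}
    if not summaries:
        raise ValueError("report contains no cohort summaries")
    cols = [p for p in PRESET_NAMES if p in summaries] + [
        p for p in summaries if p not in PRESET_NAMES
    ]
    missing = [p for p in PRESET_NAMES if p not in summaries]
    if missing:
        warnings.warn(f"rendering partial tables; missing cohorts: {missing}")
    props = pd.DataFrame(
        {p: [summaries[p]["proportions_int"][t] for t in TYPE_ORDER] for p in cols},
        index=list(TYPE_ORDER),
    )
    idx = pd.MultiIndex.from_product(
        [TYPE_ORDER, ["M_BE/M_TT", "M_BE/M_PE"]], names=["type", "ratio"]
    )
    ratios = pd.DataFrame(
        {
            p: np.array(
                [
                    [summaries[p]["ratio_tt"][t], summaries[p]["ratio_pe"][t]]
                    for t in TYPE_ORDER
                ]
            ).ravel()
            for p in cols
        },
        index=idx,
    )
    return props, ratios
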