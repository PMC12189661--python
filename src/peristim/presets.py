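"""Cohort presets for the six group x region conditions.

Each preset bundles the observed mixture of the four response types, the
per-type fold changes (baseline vs. tetanization window and baseline vs.
post-event window, magnitude convention, >= 1) and the recorded cohort size
for one experimental condition: control, rotenone-lesioned, or
rotenone + bacterial-melanin (BM) animals, in SNc or SNr.  The presets let
the synthetic generator reproduce any condition's published structure so the
analysis pipeline can be tested by parameter recovery.
"""

from __future__ import annotations

from .peth import WindowDef
from .synthetic import TYPE_ORDER, CohortSpec

__all__ = [
    "TYPE_ORDER",
    "PRESET_NAMES",
    "group_region",
    "preset_spec",
    "single_type_spec",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20250528

# preset name -> (group, region)
_PRESETS: dict[str, tuple[str, str]] = {
    "control-SNc": ("control", "SNc"),
    "rotenone-SNc": ("rotenone", "SNc"),
    "bm-SNc": ("rotenone_bm", "SNc"),
    "control-SNr": ("control", "SNr"),
    "rotenone-SNr": ("rotenone", "SNr"),
    "bm-SNr": ("rotenone_bm", "SNr"),
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)

# Published cohort sizes per condition.
_GROUP_N: dict[str, int] = {
    "control-SNc": 107,
    "rotenone-SNc": 105,
    "bm-SNc": 95,
    "control-SNr": 135,
    "rotenone-SNr": 184,
    "bm-SNr": 141,
}

# Observed proportions of the four response types (fractions summing to 1).
_TYPE_MIX: dict[str, dict[str, float]] = {
    "control-SNc": {"TD-PTD": 0.09, "TD-PTP": 0.36, "TP-PTP": 0.27, "TP-PTD": 0.28},
    "rotenone-SNc": {"TD-PTD": 0.27, "TD-PTP": 0.20, "TP-PTP": 0.11, "TP-PTD": 0.42},
    "bm-SNc": {"TD-PTD": 0.12, "TD-PTP": 0.36, "TP-PTP": 0.25, "TP-PTD": 0.27},
    "control-SNr": {"TD-PTD": 0.13, "TD-PTP": 0.31, "TP-PTP": 0.24, "TP-PTD": 0.32},
    "rotenone-SNr": {"TD-PTD": 0.32, "TD-PTP": 0.17, "TP-PTP": 0.15, "TP-PTD": 0.36},
    "bm-SNr": {"TD-PTD": 0.16, "TD-PTP": 0.39, "TP-PTP": 0.28, "TP-PTD": 0.17},
}

# Fold changes M_BE/M_TT per type (magnitude convention, >= 1).
_FOLD_TT: dict[str, dict[str, float]] = {
    "control-SNc": {"TD-PTD": 5.36, "TD-PTP": 4.24, "TP-PTP": 3.21, "TP-PTD": 2.18},
    "rotenone-SNc": {"TD-PTD": 2.06, "TD-PTP": 2.68, "TP-PTP": 2.39, "TP-PTD": 5.81},
    "bm-SNc": {"TD-PTD": 4.76, "TD-PTP": 4.41, "TP-PTP": 2.87, "TP-PTD": 2.08},
    "control-SNr": {"TD-PTD": 6.04, "TD-PTP": 4.84, "TP-PTP": 3.86, "TP-PTD": 2.79},
    "rotenone-SNr": {"TD-PTD": 2.66, "TD-PTP": 3.96, "TP-PTP": 2.46, "TP-PTD": 6.22},
    "bm-SNr": {"TD-PTD": 5.35, "TD-PTP": 5.22, "TP-PTP": 3.72, "TP-PTD": 2.78},
}

# Fold changes M_BE/M_PE per type (magnitude convention, >= 1).
_FOLD_PE: dict[str, dict[str, float]] = {
    "control-SNc": {"TD-PTD": 2.88, "TD-PTP": 2.20, "TP-PTP": 1.75, "TP-PTD": 1.28},
    "rotenone-SNc": {"TD-PTD": 1.74, "TD-PTP": 2.33, "TP-PTP": 1.48, "TP-PTD": 4.24},
    "bm-SNc": {"TD-PTD": 1.92, "TD-PTP": 1.98, "TP-PTP": 1.80, "TP-PTD": 1.12},
    "control-SNr": {"TD-PTD": 3.23, "TD-PTP": 2.62, "TP-PTP": 1.92, "TP-PTD": 1.50},
    "rotenone-SNr": {"TD-PTD": 1.86, "TD-PTP": 3.14, "TP-PTP": 2.16, "TP-PTD": 4.97},
    "bm-SNr": {"TD-PTD": 2.07, "TD-PTP": 2.58, "TP-PTP": 2.23, "TP-PTD": 1.42},
}


def group_region(preset: str) -> tuple[str, str]:
    """Map a preset name to its (group, region) pair."""
    try:
        return _PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; choose one of {', '.join(PRESET_NAMES)}"
        ) from None


def preset_spec(
    preset: str,
    n_neurons: int | None = None,
    seed: int = DEFAULT_SEED,
    baseline_rate_range: tuple[float, float] = (8.0, 12.0),
    windows: WindowDef | None = None,
) -> CohortSpec:
    """Cohort specification for one published condition.

    ``n_neurons`` defaults to the condition's recorded cohort size.
    """
    group, region = group_region(preset)
    return CohortSpec(
        group=group,
        region=region,
        n_neurons=_GROUP_N[preset] if n_neurons is None else n_neurons,
        type_mix=dict(_TYPE_MIX[preset]),
        baseline_rate_range=baseline_rate_range,
        fold_tt=dict(_FOLD_TT[preset]),
        fold_pe=dict(_FOLD_PE[preset]),
        windows=windows or WindowDef(),
        seed=seed,
    )


def single_type_spec(
    preset: str,
    response_type: str,
    n_neurons: int,
    seed: int = DEFAULT_SEED,
    baseline_rate_range: tuple[float, float] = (8.0, 12.0),
    windows: WindowDef | None = None,
) -> CohortSpec:
    """Cohort of a single response type with one condition's fold changes.

    Used for fold-change recovery runs: every neuron carries the preset's
    ``response_type`` folds applied to its own baseline rate.
    """
    if response_type not in TYPE_ORDER:
        raise ValueError(f"unknown response type {response_type!r}")
    group, region = group_region(preset)
    return CohortSpec(
        group=group,
        region=region,
        n_neurons=n_neurons,
        type_mix={response_type: 1.0},
        baseline_rate_range=baseline_rate_range,
        fold_tt={response_type: _FOLD_TT[preset][response_type]},
        fold_pe={response_type: _FOLD_PE[preset][response_type]},
        windows=windows or WindowDef(),
        seed=seed,
    )
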