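import numpy as np
import pytest

from peristim import (
    CohortSpec,
    WindowDef,
    classify_neuron,
    generate_cohort,
    preset_spec,
    summarize_group,
    window_rates,
)
from peristim.presets import DEFAULT_SEED


@pytest.fixture(scope="session")
def windows() -> WindowDef:
    return WindowDef()


def flat_cohort_spec(n_neurons: int, seed: int, rate: tuple[float, float] = (8.0, 12.0)) -> CohortSpec:
    """Cohort with no stimulation effect (all folds = 1): stationary firing."""
    return CohortSpec(
        group="null",
        region="SNc",
        n_neurons=n_neurons,
        type_mix={"TD-PTD": 1.0},
        baseline_rate_range=rate,
        fold_tt={"TD-PTD": 1.0},
        fold_pe={"TD-PTD": 1.0},
        seed=seed,
    )


def recovered_summary(preset: str, n: int, seed: int = DEFAULT_SEED, epsilon: float = 0.05):
    """Generate a preset cohort and run it through rate -> classify -> summarize."""
    spec = preset_spec(preset, n_neurons=n, seed=seed)
    trains, truths, _ = generate_cohort(spec)
    rates = [window_rates(tr, spec.windows) for tr in trains]
    labels = [classify_neuron(r, epsilon) for r in rates]
    return summarize_group(labels, rates, spec.group, spec.region), truths, labels
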