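"""Generator: quota allocation, rate derivation, Poisson structure, determinism."""

import numpy as np
import pytest

from peristim import (
    CohortSpec,
    NeuronGroundTruth,
    WindowDef,
    allocate_types,
    generate_cohort,
    generate_raw_trace,
    generate_spike_train,
    default_spike_template,
    preset_spec,
    sample_neuron_params,
    single_type_spec,
    window_rates,
)
from peristim.presets import DEFAULT_SEED

from conftest import flat_cohort_spec


class TestAllocation:
    def test_control_snc_mix_allocates_exact_counts_at_n100(self):
        spec = preset_spec("control-SNc", n_neurons=100)
        types = [sample_neuron_params(spec, i).true_type for i in range(100)]
        assert types.count("TD-PTD") == 9
        assert types.count("TD-PTP") == 36
        assert types.count("TP-PTP") == 27
        assert types.count("TP-PTD") == 28

    @pytest.mark.parametrize("preset", ["control-SNc", "rotenone-SNr", "bm-SNc"])
    @pytest.mark.parametrize("n", [7, 50, 107])
    def test_largest_remainder_counts_match_hand_allocation(self, preset, n):
        spec = preset_spec(preset, n_neurons=n)
        types = allocate_types(spec.type_mix, n)
        assert len(types) == n
        # independent largest-remainder computation
        items = sorted(spec.type_mix.items(), key=lambda kv: list(spec.type_mix).index(kv[0]))
        base = {t: int(np.floor(p * n + 1e-9)) for t, p in items}
        rem = {t: p * n - base[t] for t, p in items}
        for t in sorted(rem, key=lambda t: -rem[t])[: n - sum(base.values())]:
            base[t] += 1
        for t, c in base.items():
            assert types.count(t) == c

    def test_empty_mix_rejected(self):
        with pytest.raises(ValueError, match="type_mix"):
            CohortSpec(group="g", region="SNc", n_neurons=5, type_mix={})

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(
                group="g", region="SNc", n_neurons=5,
                type_mix={"TD-PTD": 0.5, "TP-PTP": 0.4},
                fold_tt={"TD-PTD": 2, "TP-PTP": 2},
                fold_pe={"TD-PTD": 2, "TP-PTP": 2},
            )


class TestGroundTruth:
    def test_identity_folds_leave_rates_unchanged(self):
        spec = flat_cohort_spec(20, seed=1)
        for i in range(20):
            gt = sample_neuron_params(spec, i)
            assert gt.r_tt == gt.r_be
            assert gt.r_pe == gt.r_be

    def test_depression_fold_divides_baseline(self):
        # hand value: 10 / 5.36 = 1.8657
        spec = CohortSpec(
            group="g", region="SNc", n_neurons=1,
            type_mix={"TD-PTD": 1.0},
            baseline_rate_range=(10.0, 10.0),
            fold_tt={"TD-PTD": 5.36}, fold_pe={"TD-PTD": 2.88},
        )
        gt = sample_neuron_params(spec, 0)
        assert gt.r_be == 10.0
        assert gt.r_tt == pytest.approx(1.8657, abs=1e-3)
        assert gt.r_pe == pytest.approx(10.0 / 2.88, rel=1e-12)

    def test_potentiation_fold_multiplies_baseline(self):
        spec = CohortSpec(
            group="g", region="SNc", n_neurons=1,
            type_mix={"TP-PTP": 1.0},
            baseline_rate_range=(10.0, 10.0),
            fold_tt={"TP-PTP": 3.21}, fold_pe={"TP-PTP": 1.75},
        )
        gt = sample_neuron_params(spec, 0)
        assert gt.r_tt == pytest.approx(32.1)
        assert gt.r_pe == pytest.approx(17.5)

    def test_baseline_rates_stay_in_range(self):
        spec = preset_spec("rotenone-SNc", n_neurons=200, seed=3)
        for i in range(200):
            gt = sample_neuron_params(spec, i)
            assert 8.0 <= gt.r_be <= 12.0

    def test_folds_below_one_rejected(self):
        with pytest.raises(ValueError, match="magnitude"):
            CohortSpec(
                group="g", region="SNc", n_neurons=1,
                type_mix={"TD-PTD": 1.0},
                fold_tt={"TD-PTD": 0.5}, fold_pe={"TD-PTD": 2.0},
            )


class TestSpikeTrains:
    def test_poisson_window_count_mean_matches_rate_times_duration(self, windows):
        # BE at 10 Hz for 20 s: mean count 200; CLT bound over 2000 replicates
        gt = NeuronGroundTruth(0, "TD-PTD", 10.0, 10.0, 10.0)
        rng = np.random.default_rng(7)
        reps = 2000
        counts = np.empty(reps)
        for k in range(reps):
            tr = generate_spike_train(gt, windows, rng)
            counts[k] = window_rates(tr, windows).counts[0]
        se = np.sqrt(200 / reps)
        assert abs(counts.mean() - 200) < 4 * se

    def test_zero_rate_window_is_silent(self, windows):
        gt = NeuronGroundTruth(0, "TD-PTD", 10.0, 0.0, 5.0)
        tr = generate_spike_train(gt, windows, np.random.default_rng(0))
        assert window_rates(tr, windows).counts[1] == 0

    def test_negative_rate_rejected(self, windows):
        gt = NeuronGroundTruth(0, "TD-PTD", -1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="non-negative"):
            generate_spike_train(gt, windows, np.random.default_rng(0))

    def test_times_strictly_increasing(self, windows):
        gt = NeuronGroundTruth(0, "TD-PTD", 40.0, 80.0, 40.0)
        tr = generate_spike_train(gt, windows, np.random.default_rng(5))
        assert np.all(np.diff(tr.times) > 0)

    def test_long_window_empirical_rate_recovers_truth_within_2pct(self):
        w = WindowDef(be=(-2000.0, 0.0), tt=(0.0, 1.0), pe=(1.0, 2001.0))
        gt = NeuronGroundTruth(0, "TD-PTD", 10.0, 1.866, 5.2)
        tr = generate_spike_train(gt, w, np.random.default_rng(11))
        r = window_rates(tr, w)
        assert r.m_be == pytest.approx(10.0, rel=0.02)
        assert r.m_pe == pytest.approx(5.2, rel=0.02)

    def test_dispersion_knob_thins_variance(self, windows):
        # gamma renewal with dispersion < 1 is more regular than Poisson
        gt = NeuronGroundTruth(0, "TD-PTD", 10.0, 10.0, 10.0)
        rng = np.random.default_rng(13)
        var_reg = np.var(
            [window_rates(generate_spike_train(gt, windows, rng, dispersion=0.2), windows).counts[0] for _ in range(300)]
        )
        var_poi = np.var(
            [window_rates(generate_spike_train(gt, windows, rng), windows).counts[0] for _ in range(300)]
        )
        assert var_reg < var_poi


class TestCohort:
    def test_published_cohort_size_in_manifest(self):
        spec = preset_spec("control-SNc")
        trains, truths, manifest = generate_cohort(spec)
        assert manifest["n_neurons"] == 107
        assert len(trains) == len(truths) == 107

    def test_zero_neurons_rejected(self):
        with pytest.raises(ValueError, match="n_neurons"):
            preset_spec("control-SNc", n_neurons=0)

    def test_same_seed_gives_byte_identical_spike_tables(self, tmp_path):
        for d in ("a", "b"):
            generate_cohort(single_type_spec("control-SNc", "TD-PTD", 20, seed=9), tmp_path / d)
        assert (tmp_path / "a" / "spikes.csv").read_bytes() == (
            tmp_path / "b" / "spikes.csv"
        ).read_bytes()

    def test_different_seeds_differ(self):
        _, _, m1 = generate_cohort(single_type_spec("control-SNc", "TD-PTD", 10, seed=1))
        _, _, m2 = generate_cohort(single_type_spec("control-SNc", "TD-PTD", 10, seed=2))
        assert m1["spike_table_sha256"] != m2["spike_table_sha256"]


class TestRawTraces:
    def test_noiseless_single_spike_peak_equals_template_peak(self):
        from peristim.trains import SpikeTrain

        tr = SpikeTrain(0, np.array([0.1]))
        fs = 20000.0
        trace = generate_raw_trace(tr, noise_sd=0.0, sampling_rate=fs, span=(0.0, 0.2))
        tpl = default_spike_template(fs)
        assert trace.samples.max() == pytest.approx(tpl.max())
        peak_t = trace.t_start + np.argmax(trace.samples) / fs
        assert abs(peak_t - 0.1) <= 1.0 / fs

    def test_empty_train_noiseless_trace_is_zero(self):
        from peristim.trains import SpikeTrain

        trace = generate_raw_trace(SpikeTrain(0, np.empty(0)), noise_sd=0.0, span=(0.0, 0.5))
        assert np.all(trace.samples == 0)

    def test_snr_by_amplitude(self):
        # peak 0.15 mV over noise SD 0.01 mV -> SNR 15
        tpl = default_spike_template(20000.0)
        assert tpl.max() / 0.01 == pytest.approx(15.0, rel=1e-6)

    def test_low_sampling_rate_rejected(self):
        from peristim.trains import SpikeTrain

        with pytest.raises(ValueError, match="10 kHz"):
            generate_raw_trace(SpikeTrain(0, np.array([0.1])), sampling_rate=5000.0)
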