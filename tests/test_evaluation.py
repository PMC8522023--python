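"""Tests for splits, metrics, leakage rules and the experiment grid."""

import numpy as np
import pytest
from dataclasses import replace

from memsctrnn import evaluation as ev
from memsctrnn import preprocess as pp
from memsctrnn import synthetic as synth
from memsctrnn import training as tr


def toy_dataset(b=100, o=2, l=6, seed=0):
    rng = np.random.default_rng(seed)
    labels = (rng.random(b) < 0.3).astype(int)
    return pp.WindowedDataset(
        windows=rng.normal(size=(b, o, l)), labels=labels,
        fractions=labels.astype(float), subjects=np.zeros(b, dtype=int),
        activities=labels.copy(), origins=np.array(["original"] * b, dtype=object),
    )


class TestSplitDataset:
    def test_seventy_thirty_sizes(self):
        train, test = ev.split_dataset(toy_dataset(100), 0.7, seed=0)
        assert len(train) == 70 and len(test) == 30
        assert train.role == "train" and test.role == "test"

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = toy_dataset(57)
        # tag windows through the subjects field to track identity
        ds.subjects[:] = np.arange(57)
        train, test = ev.split_dataset(ds, 0.7, seed=3)
        ids = np.concatenate([train.subjects, test.subjects])
        assert sorted(ids.tolist()) == list(range(57))

    def test_same_seed_same_partition(self):
        ds = toy_dataset(80)
        ds.subjects[:] = np.arange(80)
        a_train, _ = ev.split_dataset(ds, 0.7, seed=5)
        b_train, _ = ev.split_dataset(ds, 0.7, seed=5)
        assert np.array_equal(a_train.subjects, b_train.subjects)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            ev.split_dataset(toy_dataset(2), 0.05, seed=0)


class TestMetrics:
    def test_accuracy_extremes_and_fraction(self):
        assert ev.accuracy([1, 1, 0], [1, 1, 0]) == 1.0
        assert ev.accuracy([1, 1, 1], [0, 0, 0]) == 0.0
        assert ev.accuracy([1, 0, 1, 1], [1, 1, 1, 1]) == 0.75

    def test_accuracy_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.accuracy([1, 0], [1])

    def test_average_accuracy_of_identical_entries(self):
        assert ev.average_accuracy([81.3, 81.3, 81.3]) == 81.3

    def test_average_accuracy_two_decimal_rounding(self):
        assert ev.average_accuracy([76.5, 77.6, 78.9, 78.7, 78.0]) == 77.94

    def test_average_accuracy_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.average_accuracy([])


class TestGrid:
    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ev.ExperimentGrid(P_values=(0.7,))

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ev.ExperimentGrid(hidden_sizes=())

    def test_tau_scaling_delegated_to_closed_form(self):
        cells = list(ev.ExperimentGrid(P_values=(0.25, 1, 4)).cells())
        assert [c["P"] for c in cells] == [0.25, 1, 4]

    def test_single_cell_grid_runs_and_logs(self):
        grid = ev.ExperimentGrid(seeds=(0,))
        cfg = tr.TrainConfig(epochs=1, batch_size=64)
        sc = replace(synth.SynthConfig(), duration=40.0)
        frame = ev.run_grid(grid, sc, train_config=cfg, n_subjects=1, window_len=32, stride=32)
        assert len(frame) == 1
        row = frame.iloc[0]
        assert row["error"] == ""
        assert 0.0 <= row["test_accuracy"] <= 1.0
        assert row["tau"] == pytest.approx(0.0017)

    def test_tau_sweep_rows_scale_tau_by_p(self):
        grid = ev.ExperimentGrid(P_values=(0.25, 4), seeds=(0,))
        cfg = tr.TrainConfig(epochs=0)
        sc = replace(synth.SynthConfig(), duration=40.0)
        frame = ev.run_grid(grid, sc, train_config=cfg, n_subjects=1, window_len=32, stride=32)
        taus = dict(zip(frame["P"], frame["tau"]))
        assert taus[0.25] == pytest.approx(0.0068)
        assert taus[4] == pytest.approx(0.000425)

    def test_summarize_grid_reports_mean_and_sd_across_seeds(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "kind": ["mems"] * 4, "n_hidden": [6] * 4, "quantize": [False] * 4,
                "channels": ["xyz"] * 4, "threshold": [0.75] * 4, "P": [1] * 4,
                "activity": [1] * 4, "seed": [0, 1, 2, 3],
                "test_accuracy": [0.90, 0.94, 0.92, 0.96],
            }
        )
        agg = ev.summarize_grid(frame)
        assert len(agg) == 1
        assert agg["mean"].iloc[0] == pytest.approx(0.93)
        assert agg["std"].iloc[0] == pytest.approx(np.std([0.9, 0.94, 0.92, 0.96], ddof=1))
        assert agg["count"].iloc[0] == 4

    def test_zero_separability_accuracy_collapses_to_class_prior(self):
        # templates off: window content is pure noise, so the detector
        # trained on the (unbalanced) benchmark can do no better than the
        # majority class (or chance, if larger)
        sc = replace(synth.SynthConfig(), separability=0.0, duration=60.0)
        cfg = tr.TrainConfig(epochs=6, batch_size=32)
        res = ev.run_cell(sc, seed=0, n_subjects=1, window_len=32, stride=32,
                          train_config=cfg, augment=False)
        test_prior = 1.0 - (res["tp"] + res["fn"]) / res["n_test"]
        expected = max(test_prior, 0.5)
        assert abs(res["test_accuracy"] - expected) <= 0.15

    def test_failures_are_recorded_not_raised(self):
        grid = ev.ExperimentGrid(seeds=(0,))
        cfg = tr.TrainConfig(epochs=1)
        # window longer than the whole recording: windowing must fail
        sc = replace(synth.SynthConfig(), duration=4.0)
        frame = ev.run_grid(grid, sc, train_config=cfg, n_subjects=1, window_len=512, stride=16)
        assert frame.iloc[0]["error"] != ""
        assert np.isnan(frame.iloc[0]["test_accuracy"])


class TestNoLeakage:
    def test_epsilon_and_standardization_come_from_train_only(self):
        ds = toy_dataset(60, seed=2)
        train, test = ev.split_dataset(ds, 0.7, seed=0)
        stats = pp.fit_channel_stats(train)
        # perturbing the test split must not change the fitted statistics
        test_perturbed = replace(test, windows=test.windows + 100.0)
        assert np.array_equal(pp.fit_channel_stats(train).epsilon, stats.epsilon)
        out = pp.apply_channel_stats(test_perturbed, stats, mode="standardize")
        assert out.windows.mean() > 10  # the shift visibly survives frozen stats

    def test_augmentation_rejected_on_test_split(self):
        from memsctrnn.augmentation import AugmentConfig, augment_dataset

        _, test = ev.split_dataset(toy_dataset(40), 0.7, seed=0)
        with pytest.raises(ValueError):
            augment_dataset(test, AugmentConfig(K=1))
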