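"""Experimental protocols: splits, metrics, sweeps and the run grid.

Implements the evaluation conventions used throughout the package: a
seeded 70/30 window-level split, one-vs-null window accuracy, per-activity
averaging, and a grid runner over model kind, hidden size, quantization,
channel subset, labeling threshold and time-constant multiplier P.  The
leakage rules are enforced structurally: quantization thresholds and
standardization moments are fitted on the training split only, and
augmentation is applied after the split, to the training windows only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import augmentation as aug
from . import preprocess as pp
from . import synthetic as synth
from . import training as tr
from .mems import MEMSParams, scaled_time_constant

__all__ = [
    "ExperimentGrid",
    "split_dataset",
    "accuracy",
    "average_accuracy",
    "run_cell",
    "run_grid",
    "plot_accuracy_vs_hidden",
    "plot_accuracy_vs_tau",
]

# Time-constant multipliers: fractions followed by integers (tau -> tau / P)
P_SET = (1 / 5, 1 / 4, 1 / 3, 1 / 2, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)

CHANNEL_SETS = {
    "xyz": (0, 1, 2),
    "xy": (0, 1),
    "xz": (0, 2),
    "yz": (1, 2),
    "6ch": (0, 1, 2, 3, 4, 5),
}


def split_dataset(dataset: pp.WindowedDataset, train_frac: float = 0.7, seed: int = 0):
    """Disjoint, exhaustive, seeded random partition at the window level.

    Returns ``(train, test)`` tagged with their roles so that downstream
    augmentation of the test split is rejected.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split is degenerate for this dataset size")
    train = dataset.subset(perm[:n_train]).with_role("train")
    test = dataset.subset(perm[n_train:]).with_role("test")
    return train, test


def accuracy(predictions, labels) -> float:
    """Fraction of exact matches, in [0, 1]."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    return float(np.mean(predictions == labels))


def average_accuracy(per_activity) -> float:
    """Arithmetic mean of per-activity accuracy percentages, to 2 decimals."""
    values = list(per_activity)
    if not values:
        raise ValueError("need at least one per-activity accuracy")
    return round(float(np.mean(values)), 2)


@dataclass(frozen=True)
class ExperimentGrid:
    """Axes of a sweep over models, architectures and protocols."""

    model_kinds: tuple = ("mems",)
    hidden_sizes: tuple = (6,)
    quantize: tuple = (False,)
    channel_sets: tuple = ("xyz",)
    thresholds: tuple = (0.75,)
    P_values: tuple = (1,)
    activities: tuple = (synth.WALK,)
    seeds: tuple = (0,)

    def __post_init__(self) -> None:
        for name in ("model_kinds", "hidden_sizes", "quantize", "channel_sets",
                     "thresholds", "P_values", "activities", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"grid axis {name} is empty")
        for p in self.P_values:
            if not any(np.isclose(p, q) for q in P_SET):
                raise ValueError(f"P = {p} is not in the admissible multiplier set")

    def cells(self):
        for kind in self.model_kinds:
            for hidden in self.hidden_sizes:
                for quant in self.quantize:
                    for channels in self.channel_sets:
                        for thr in self.thresholds:
                            for P in self.P_values:
                                for act in self.activities:
                                    yield {
                                        "kind": kind, "n_hidden": hidden,
                                        "quantize": quant, "channels": channels,
                                        "threshold": thr, "P": P, "activity": act,
                                    }


def _select_channels(dataset: pp.WindowedDataset, channels) -> pp.WindowedDataset:
    idx = CHANNEL_SETS[channels] if isinstance(channels, str) else tuple(channels)
    return replace(dataset, windows=dataset.windows[:, list(idx), :])


def run_cell(
    synth_config: synth.SynthConfig,
    kind: str = "mems",
    n_hidden: int = 6,
    quantize: bool = False,
    channels="xyz",
    threshold: float = 0.75,
    P: float = 1.0,
    activity: int = synth.WALK,
    seed: int = 0,
    train_config: tr.TrainConfig | None = None,
    mems_params: MEMSParams | None = None,
    n_subjects: int = 3,
    window_len: int = 64,
    stride: int = 32,
    augment: bool = True,
    shuffle_labels: bool = False,
) -> dict:
    """Run one full train/evaluate protocol on the synthetic benchmark.

    Pipeline: generate recordings -> cut raw windows and label them at
    ``threshold`` -> 70/30 seeded split -> fit per-channel statistics on
    the training split -> quantize (or standardize) both splits with the
    frozen statistics -> augment the training split -> train -> report
    hard-step train/test accuracy.  ``P`` scales the natural frequency, so
    the node time constant becomes ``tau / P``.  ``shuffle_labels`` replaces
    every label with a fair coin flip before the split -- a random-label
    null whose chance accuracy is 0.5 regardless of the class prior.
    """
    base_params = mems_params if mems_params is not None else MEMSParams()
    params = base_params.with_tau_scaled(P)
    tau = scaled_time_constant(base_params.tau, P)
    config = train_config if train_config is not None else tr.TrainConfig()
    config = replace(config, seed=seed)

    ds = synth.generate_benchmark(
        replace(synth_config, seed=synth_config.seed + seed),
        n_subjects=n_subjects, target_activity=activity,
        window_len=window_len, stride=stride, threshold=threshold,
        for_quantization=quantize,
    )
    ds = _select_channels(ds, channels)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1)
        ds = replace(ds, labels=rng.integers(0, 2, size=len(ds)))
    train_ds, test_ds = split_dataset(ds, 0.7, seed=seed)

    stats = pp.fit_channel_stats(train_ds)
    mode = "quantize" if quantize else "standardize"
    train_ds = pp.apply_channel_stats(train_ds, stats, mode=mode)
    test_ds = pp.apply_channel_stats(test_ds, stats, mode=mode)
    if augment:
        train_ds = aug.augment_dataset(train_ds, aug.AugmentConfig(seed=seed))

    weights, history = tr.train(train_ds, config, params, kind=kind, n_hidden=n_hidden)
    train_pred = tr.predict(train_ds.windows, weights, params, config, kind=kind, tau=tau)
    test_pred = tr.predict(test_ds.windows, weights, params, config, kind=kind, tau=tau)
    test_pos = test_ds.labels == 1
    confusion = {
        "tp": int(np.sum((test_pred == 1) & test_pos)),
        "fp": int(np.sum((test_pred == 1) & ~test_pos)),
        "fn": int(np.sum((test_pred == 0) & test_pos)),
        "tn": int(np.sum((test_pred == 0) & ~test_pos)),
    }
    cell = {
        "kind": kind, "n_hidden": n_hidden, "quantize": quantize,
        "channels": channels if isinstance(channels, str) else str(channels),
        "threshold": threshold, "P": P, "tau": tau, "activity": activity, "seed": seed,
    }
    cell_hash = hashlib.sha1(json.dumps(cell, sort_keys=True).encode()).hexdigest()[:10]
    return {
        **cell,
        "train_accuracy": accuracy(train_pred, train_ds.labels),
        "test_accuracy": accuracy(test_pred, test_ds.labels),
        "final_loss": float(history["loss"].iloc[-1]) if len(history) else float("nan"),
        "n_train": len(train_ds), "n_test": len(test_ds),
        "positive_fraction_train": train_ds.positive_fraction,
        **confusion,
        "config_hash": cell_hash,
        "weights": weights,
        "history": history,
    }


def run_grid(
    grid: ExperimentGrid,
    synth_config: synth.SynthConfig | None = None,
    train_config: tr.TrainConfig | None = None,
    mems_params: MEMSParams | None = None,
    **cell_kwargs,
) -> pd.DataFrame:
    """One row per grid cell per seed; per-cell failures are recorded, not raised."""
    synth_config = synth_config if synth_config is not None else synth.SynthConfig()
    rows = []
    for cell in grid.cells():
        for seed in grid.seeds:
            try:
                result = run_cell(
                    synth_config, seed=seed, train_config=train_config,
                    mems_params=mems_params, **cell, **cell_kwargs,
                )
                result.pop("weights")
                result.pop("history")
                result["error"] = ""
            except Exception as exc:  # keep sweeping the remaining cells
                result = {**cell, "seed": seed, "test_accuracy": np.nan,
                          "train_accuracy": np.nan, "error": str(exc)}
            rows.append(result)
    frame = pd.DataFrame(rows)
    return frame


def summarize_grid(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of test accuracy per cell across seeds."""
    keys = ["kind", "n_hidden", "quantize", "channels", "threshold", "P", "activity"]
    return (
        frame.groupby(keys, dropna=False)["test_accuracy"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def plot_accuracy_vs_hidden(frame: pd.DataFrame, path) -> None:
    """Accuracy as a function of hidden-layer size, one line per model kind."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for kind, sub in frame.groupby("kind"):
        agg = sub.groupby("n_hidden")["test_accuracy"].mean()
        ax.plot(agg.index, 100 * agg.values, marker="o", label=kind)
    ax.set_xlabel("hidden-layer neurons")
    ax.set_ylabel("test accuracy (%)")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_accuracy_vs_tau(frame: pd.DataFrame, path) -> None:
    """Accuracy as a function of the node time constant tau = tau_base / P."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    agg = frame.groupby("tau")["test_accuracy"].mean().sort_index()
    ax.semilogx(agg.index, 100 * agg.values, marker="o")
    ax.set_xlabel("time constant tau (s)")
    ax.set_ylabel("test accuracy (%)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
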