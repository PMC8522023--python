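"""Signal pre-processing: ternary quantization, windowing, labeling.

Raw multi-channel inertial signals are optionally quantized to a
three-symbol alphabet that encodes the local trend of the signal
(rise / fall / no-change) relative to a per-channel threshold ``epsilon``,
then cut into fixed-length sliding windows.  A window is labeled positive
for the activity of interest when at least a configurable fraction of its
samples carries that activity's annotation (inclusive ``>=`` comparison,
default threshold 0.75).

The quantization rule compares consecutive samples:

    symbol_t = +1  if a_t > a_{t+1} + eps
              -1  if a_t < a_{t+1} - eps
               0  if |a_{t+1} - a_t| <= eps

Note the +1 branch triggers when the *current* sample exceeds the next one;
the symbol names are configurable because the conventional reading of
"rise" is the opposite comparison.  The recommended threshold is
``eps = mean(channel) + std(channel) / 2``.

Quantized sequences are one sample shorter than their raw source (pairwise
comparisons), so a pipeline that quantizes after windowing should cut raw
windows of length ``l + 1`` to obtain quantized windows of length ``l``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "QuantizerConfig",
    "WindowedDataset",
    "ChannelStats",
    "select_epsilon",
    "quantize",
    "quantize_matrix",
    "make_windows",
    "label_window",
    "relabel",
    "concat_datasets",
    "fit_channel_stats",
    "apply_channel_stats",
]


@dataclass(frozen=True)
class QuantizerConfig:
    """Per-channel thresholds and the three-level symbol alphabet."""

    epsilon: np.ndarray
    symbols: tuple[int, int, int] = (1, -1, 0)  # (a_t > a_{t+1}+eps, a_t < a_{t+1}-eps, no change)
    symbol_names: tuple[str, str, str] = ("rise", "fall", "no-change")

    def __post_init__(self) -> None:
        eps = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if np.any(eps < 0):
            raise ValueError("epsilon must be nonnegative")
        object.__setattr__(self, "epsilon", eps)


def select_epsilon(channel: np.ndarray) -> float:
    """Quantization threshold ``mean + std/2`` for one channel.

    A constant sequence (zero spread) yields ``eps = mean``, which maps
    every transition of that channel to the no-change symbol.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size < 2:
        raise ValueError("need at least two samples to select epsilon")
    return float(np.mean(channel) + np.std(channel) / 2.0)


def quantize(channel: np.ndarray, epsilon: float, symbols=(1, -1, 0)) -> np.ndarray:
    """Ternary-quantize one channel; output has length ``n - 1``."""
    a = np.asarray(channel, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two samples to quantize")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    cur, nxt = a[:-1], a[1:]
    out = np.full(a.size - 1, symbols[2], dtype=float)
    out[cur > nxt + epsilon] = symbols[0]
    out[cur < nxt - epsilon] = symbols[1]
    return out


def quantize_matrix(series: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """Quantize each row of an ``O x T`` matrix with its own threshold."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), (series.shape[0],))
    return np.stack([quantize(row, e) for row, e in zip(series, eps)])


def label_window(fraction: float, threshold: float = 0.75) -> int:
    """Binary window label: 1 iff ``fraction >= threshold`` (inclusive)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return int(fraction >= threshold)


@dataclass
class WindowedDataset:
    """Fixed-length multi-channel windows with binary labels and provenance.

    ``windows`` is a ``(B, O, l)`` array; ``fractions`` holds the
    per-window fraction of samples annotated with the target activity, from
    which ``labels`` derive via :func:`label_window`.  ``origins`` records
    whether a window is an original cut or a mutated (augmented) copy, and
    ``role`` tags the train/test split so augmentation of test data can be
    rejected.
    """

    windows: np.ndarray
    labels: np.ndarray
    fractions: np.ndarray
    subjects: np.ndarray
    activities: np.ndarray
    origins: np.ndarray
    target_activity: int | None = None
    threshold: float = 0.75
    role: str | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be a (B, O, l) array")
        b = len(self.windows)
        self.labels = np.asarray(self.labels, dtype=int)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.subjects = np.asarray(self.subjects, dtype=int)
        self.activities = np.asarray(self.activities, dtype=int)
        self.origins = np.asarray(self.origins, dtype=object)
        for name in ("labels", "fractions", "subjects", "activities", "origins"):
            if len(getattr(self, name)) != b:
                raise ValueError(f"{name} length does not match number of windows")
        if not np.all((self.labels == 0) | (self.labels == 1)):
            raise ValueError("labels must be binary")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_length(self) -> int:
        return self.windows.shape[2]

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.labels)) if len(self) else 0.0

    def subset(self, index: np.ndarray) -> "WindowedDataset":
        index = np.asarray(index)
        return WindowedDataset(
            windows=self.windows[index], labels=self.labels[index],
            fractions=self.fractions[index], subjects=self.subjects[index],
            activities=self.activities[index], origins=self.origins[index],
            target_activity=self.target_activity, threshold=self.threshold,
            role=self.role,
        )

    def with_role(self, role: str | None) -> "WindowedDataset":
        return replace(self, role=role)


def make_windows(
    series: np.ndarray,
    annotations: np.ndarray,
    l: int,
    stride: int,
    target_activity: int | None = None,
    threshold: float = 0.75,
    subject: int = 0,
) -> WindowedDataset:
    """Cut an ``O x T`` series into sliding windows with activity fractions.

    Emits ``floor((T - l) / stride) + 1`` windows.  For each window the
    majority activity id among its per-sample annotations is recorded; the
    fraction-of-activity refers to ``target_activity`` when given (and
    drives the binary label), otherwise to the majority activity.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    annotations = np.asarray(annotations, dtype=int)
    n_channels, T = series.shape
    if annotations.shape != (T,):
        raise ValueError("annotations must align with samples")
    if l < 1 or stride < 1:
        raise ValueError("l and stride must be >= 1")
    if l > T:
        raise ValueError(f"window length {l} exceeds series length {T}")
    starts = range(0, T - l + 1, stride)
    windows, labels, fractions, acts = [], [], [], []
    for s in starts:
        win_ann = annotations[s:s + l]
        ids, counts = np.unique(win_ann, return_counts=True)
        majority = int(ids[np.argmax(counts)])
        if target_activity is None:
            frac = float(np.mean(win_ann == majority))
        else:
            frac = float(np.mean(win_ann == target_activity))
        windows.append(series[:, s:s + l])
        fractions.append(frac)
        labels.append(label_window(frac, threshold))
        acts.append(majority)
    b = len(windows)
    return WindowedDataset(
        windows=np.stack(windows) if b else np.zeros((0, n_channels, l)),
        labels=np.array(labels, dtype=int),
        fractions=np.array(fractions),
        subjects=np.full(b, subject, dtype=int),
        activities=np.array(acts, dtype=int),
        origins=np.array(["original"] * b, dtype=object),
        target_activity=target_activity,
        threshold=threshold,
    )


def relabel(dataset: WindowedDataset, threshold: float) -> WindowedDataset:
    """Re-apply :func:`label_window` at a new threshold (fractions kept)."""
    labels = np.array([label_window(f, threshold) for f in dataset.fractions], dtype=int)
    return replace(dataset, labels=labels, threshold=threshold)


def concat_datasets(datasets) -> WindowedDataset:
    datasets = list(datasets)
    if not datasets:
        raise ValueError("nothing to concatenate")
    first = datasets[0]
    return WindowedDataset(
        windows=np.concatenate([d.windows for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        fractions=np.concatenate([d.fractions for d in datasets]),
        subjects=np.concatenate([d.subjects for d in datasets]),
        activities=np.concatenate([d.activities for d in datasets]),
        origins=np.concatenate([d.origins for d in datasets]),
        target_activity=first.target_activity,
        threshold=first.threshold,
        role=first.role,
    )


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel statistics fitted on training data only.

    Freezing the quantization thresholds and standardization moments on the
    training split prevents information from the test split leaking into
    the input representation.
    """

    mean: np.ndarray
    std: np.ndarray
    epsilon: np.ndarray


def fit_channel_stats(dataset: WindowedDataset) -> ChannelStats:
    """Fit mean/std/epsilon per channel from a (training) window set."""
    flat = dataset.windows.transpose(1, 0, 2).reshape(dataset.n_channels, -1)
    mean = flat.mean(axis=1)
    std = flat.std(axis=1)
    return ChannelStats(mean=mean, std=std, epsilon=mean + std / 2.0)


def apply_channel_stats(
    dataset: WindowedDataset, stats: ChannelStats, mode: str = "quantize"
) -> WindowedDataset:
    """Transform windows with frozen stats.

    ``mode="quantize"``: ternary-quantize each channel (window length
    shrinks by one).  ``mode="standardize"``: subtract the training mean and
    divide by the training std (degenerate std of 0 maps to a unit scale).
    """
    if mode == "quantize":
        new = np.stack([quantize_matrix(w, stats.epsilon) for w in dataset.windows]) \
            if len(dataset) else dataset.windows[:, :, :-1]
        return replace(dataset, windows=new)
    if mode == "standardize":
        std = np.where(stats.std > 0, stats.std, 1.0)
        new = (dataset.windows - stats.mean[None, :, None]) / std[None, :, None]
        return replace(dataset, windows=new)
    raise ValueError(f"unknown mode {mode!r}")
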