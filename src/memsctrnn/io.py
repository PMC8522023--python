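"""Readers and writers for recordings, window datasets and weights.

Raw recordings use the public smartphone-HAR raw-data layout: one
whitespace-separated tri-axial text file per (experiment, user) pair named
``acc_expNN_userNN.txt`` (optionally ``gyro_expNN_userNN.txt``) plus a
``labels.txt`` index whose rows are ``experiment_id user_id activity_id
start end``.  Sample indexing is 0-based and annotation intervals are
half-open ``[start, end)``.

Window datasets are a directory of CSV files plus a JSON manifest; network
weights are CSV matrices plus a JSON parameter file.  All readers are pure
(inputs are never mutated).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mems import MEMSParams, NetworkWeights
from .preprocess import WindowedDataset

__all__ = [
    "Recording",
    "read_raw_recordings",
    "write_recordings",
    "save_dataset",
    "load_dataset",
    "save_weights",
    "load_weights",
    "save_params",
    "load_params",
]

DATASET_FORMAT_VERSION = 1


@dataclass
class Recording:
    """A continuous multi-channel recording with activity annotations."""

    signals: np.ndarray
    sample_rate: float
    annotations: list  # (activity_id, start, end) with half-open [start, end)
    subject_id: int = 0
    experiment_id: int = 0

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        T = self.signals.shape[1]
        for act, start, end in self.annotations:
            if not (0 <= start <= end <= T):
                raise ValueError(f"annotation [{start}, {end}) outside [0, {T})")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def annotation_array(self) -> np.ndarray:
        """Per-sample activity ids (0 = null class)."""
        ann = np.zeros(self.n_samples, dtype=int)
        for act, start, end in self.annotations:
            ann[start:end] = act
        return ann


def _read_signal_file(path: Path) -> np.ndarray:
    try:
        frame = pd.read_csv(path, sep=r"\s+", header=None, dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric line in {path}: {exc}") from exc
    return frame.to_numpy().T  # (channels, samples)


def read_raw_recordings(directory) -> list[Recording]:
    """Best-effort reader for a raw smartphone-HAR style directory.

    One :class:`Recording` is returned per (experiment, user) accelerometer
    file, with gyroscope channels appended when the matching file exists
    and annotations merged in from ``labels.txt``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    labels: dict[tuple[int, int], list] = {}
    labels_path = directory / "labels.txt"
    if labels_path.exists():
        for lineno, line in enumerate(labels_path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                exp, user, act, start, end = (int(float(tok)) for tok in line.split())
            except ValueError as exc:
                raise ValueError(f"malformed labels line {labels_path}:{lineno}: {line!r}") from exc
            labels.setdefault((exp, user), []).append((act, start, end))

    pattern = re.compile(r"acc_exp(\d+)_user(\d+)\.txt$")
    recordings = []
    for acc_path in sorted(directory.glob("acc_exp*_user*.txt")):
        match = pattern.search(acc_path.name)
        if not match:
            continue
        exp, user = int(match.group(1)), int(match.group(2))
        signals = _read_signal_file(acc_path)
        gyro_path = directory / f"gyro_exp{match.group(1)}_user{match.group(2)}.txt"
        if gyro_path.exists():
            gyro = _read_signal_file(gyro_path)
            if gyro.shape[1] != signals.shape[1]:
                raise ValueError(f"{gyro_path} sample count differs from {acc_path}")
            signals = np.vstack([signals, gyro])
        recordings.append(
            Recording(
                signals=signals,
                sample_rate=50.0,
                annotations=sorted(labels.get((exp, user), []), key=lambda a: a[1]),
                subject_id=user,
                experiment_id=exp,
            )
        )
    return recordings


def write_recordings(recordings, directory) -> None:
    """Write recordings in the same raw-text layout `read_raw_recordings` consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label_rows = []
    for rec in recordings:
        stem = f"exp{rec.experiment_id:02d}_user{rec.subject_id:02d}"
        acc = rec.signals[:3]
        np.savetxt(directory / f"acc_{stem}.txt", acc.T, fmt="%.9g")
        if rec.signals.shape[0] > 3:
            np.savetxt(directory / f"gyro_{stem}.txt", rec.signals[3:6].T, fmt="%.9g")
        for act, start, end in rec.annotations:
            label_rows.append(f"{rec.experiment_id} {rec.subject_id} {act} {start} {end}")
    (directory / "labels.txt").write_text("\n".join(label_rows) + ("\n" if label_rows else ""))


def save_dataset(dataset: WindowedDataset, directory) -> None:
    """Lossless round-trip serialization: CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    b, o, l = dataset.windows.shape
    flat = dataset.windows.reshape(b * o, l) if b else np.zeros((0, l))
    index = pd.MultiIndex.from_product([range(b), range(o)], names=["window", "channel"])
    pd.DataFrame(flat, index=index).to_csv(directory / "windows.csv")
    meta = pd.DataFrame(
        {
            "label": dataset.labels,
            "fraction": dataset.fractions,
            "subject": dataset.subjects,
            "activity": dataset.activities,
            "origin": dataset.origins,
        }
    )
    meta.to_csv(directory / "meta.csv", index_label="window")
    manifest = {
        "format_version": DATASET_FORMAT_VERSION,
        "n_windows": b,
        "n_channels": o,
        "window_length": l,
        "target_activity": dataset.target_activity,
        "threshold": dataset.threshold,
        "role": dataset.role,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(directory) -> WindowedDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != DATASET_FORMAT_VERSION:
        raise ValueError(
            f"dataset format version {manifest.get('format_version')} "
            f"not supported (expected {DATASET_FORMAT_VERSION})"
        )
    b, o, l = manifest["n_windows"], manifest["n_channels"], manifest["window_length"]
    if b:
        flat = pd.read_csv(directory / "windows.csv", index_col=[0, 1]).to_numpy()
        windows = flat.reshape(b, o, l)
        meta = pd.read_csv(directory / "meta.csv", index_col=0)
        labels = meta["label"].to_numpy()
        fractions = meta["fraction"].to_numpy()
        subjects = meta["subject"].to_numpy()
        activities = meta["activity"].to_numpy()
        origins = meta["origin"].to_numpy(dtype=object)
    else:
        windows = np.zeros((0, o, l))
        labels = np.zeros(0, dtype=int)
        fractions = np.zeros(0)
        subjects = np.zeros(0, dtype=int)
        activities = np.zeros(0, dtype=int)
        origins = np.array([], dtype=object)
    return WindowedDataset(
        windows=windows, labels=labels, fractions=fractions, subjects=subjects,
        activities=activities, origins=origins,
        target_activity=manifest["target_activity"], threshold=manifest["threshold"],
        role=manifest["role"],
    )


def save_weights(weights: NetworkWeights, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "w_rec.csv", weights.w_rec, delimiter=",")
    np.savetxt(directory / "w_in.csv", np.atleast_2d(weights.w_in), delimiter=",")
    np.savetxt(directory / "theta.csv", weights.theta, delimiter=",")
    np.savetxt(directory / "w_out.csv", weights.w_out, delimiter=",")
    np.savetxt(directory / "b_out.csv", weights.b_out, delimiter=",")
    shapes = {
        "n_nodes": int(weights.n_nodes),
        "n_inputs": int(weights.n_inputs),
        "n_outputs": int(weights.w_out.shape[0]),
    }
    (directory / "shapes.json").write_text(json.dumps(shapes, indent=2))


def load_weights(directory) -> NetworkWeights:
    directory = Path(directory)
    shapes = json.loads((directory / "shapes.json").read_text())
    n, o, q = shapes["n_nodes"], shapes["n_inputs"], shapes["n_outputs"]
    read = lambda name: np.loadtxt(directory / name, delimiter=",")
    return NetworkWeights(
        w_rec=read("w_rec.csv").reshape(n, n),
        w_in=read("w_in.csv").reshape(n, o),
        theta=read("theta.csv").reshape(n),
        w_out=read("w_out.csv").reshape(q, n),
        b_out=read("b_out.csv").reshape(q),
    )


def save_params(params: MEMSParams, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(params), indent=2))


def load_params(path) -> MEMSParams:
    return MEMSParams(**json.loads(Path(path).read_text()))
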