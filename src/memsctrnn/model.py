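"""Model/Results objects over the training machinery.

``MEMSDetector`` and ``CTRNNDetector`` wrap a labeled window dataset the
way statistical modelling packages wrap a design matrix: the model object
holds the data and configuration, ``fit()`` runs backpropagation-through-
time and returns a :class:`DetectorResults` carrying the trained weights,
the loss/accuracy history, diagnostics and a ``summary()`` table.
Simulation of single windows and persistence hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from . import training as tr
from .ctrnn import from_network_weights, simulate_ctrnn
from .mems import MEMSParams, NetworkWeights, simulate_network
from .preprocess import WindowedDataset

__all__ = ["ActivityDetector", "MEMSDetector", "CTRNNDetector", "DetectorResults"]


class ActivityDetector:
    """Binary one-vs-null activity detector fitted to windowed data.

    Parameters
    ----------
    dataset : WindowedDataset
        Labeled training windows (both classes must be present to fit).
    n_hidden : int
        Hidden-layer size; the input layer gets one node per channel.
    params : MEMSParams, optional
        Physical node parameters (MEMS detector only).
    config : TrainConfig, optional
        Discretization/optimizer settings.
    """

    kind = "mems"

    def __init__(
        self,
        dataset: WindowedDataset,
        n_hidden: int = 6,
        params: MEMSParams | None = None,
        config: tr.TrainConfig | None = None,
    ):
        self.dataset = dataset
        self.n_hidden = n_hidden
        self.params = params if params is not None else MEMSParams()
        self.config = config if config is not None else tr.TrainConfig()

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, n_channels: int, window_length: int, **kwargs
    ) -> "ActivityDetector":
        """Build from a tidy frame with columns ``window, channel, s0..s{l-1}, label``."""
        labels = frame.groupby("window")["label"].first().to_numpy(dtype=int)
        cols = [c for c in frame.columns if c.startswith("s")]
        values = frame.sort_values(["window", "channel"])[cols].to_numpy()
        windows = values.reshape(-1, n_channels, window_length)
        b = len(windows)
        ds = WindowedDataset(
            windows=windows, labels=labels, fractions=labels.astype(float),
            subjects=np.zeros(b, dtype=int), activities=labels,
            origins=np.array(["original"] * b, dtype=object),
        )
        return cls(ds, **kwargs)

    def fit(self) -> "DetectorResults":
        weights, history = tr.train(
            self.dataset, self.config, self.params, kind=self.kind, n_hidden=self.n_hidden
        )
        return DetectorResults(model=self, weights=weights, history=history)


class MEMSDetector(ActivityDetector):
    """Activity detector built from electrostatic MEMS neurons."""

    kind = "mems"


class CTRNNDetector(ActivityDetector):
    """Reference software-CTRNN activity detector (same harness)."""

    kind = "ctrnn"


@dataclass
class DetectorResults:
    """Trained weights plus training diagnostics.

    ``history`` has one row per epoch (smooth-pass loss, hard-step training
    accuracy); all predictions made through this object use the hard-step
    physical simulator.
    """

    model: ActivityDetector
    weights: NetworkWeights
    history: pd.DataFrame = field(repr=False)

    @property
    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1]) if len(self.history) else float("nan")

    @property
    def train_accuracy(self) -> float:
        if len(self.history):
            return float(self.history["train_accuracy"].iloc[-1])
        preds = self.predict(self.model.dataset.windows)
        return float(np.mean(preds == self.model.dataset.labels))

    def predict(self, windows) -> np.ndarray:
        """Hard-step 0/1 predictions for an array of windows or a dataset."""
        X = windows.windows if isinstance(windows, WindowedDataset) else np.asarray(windows)
        return tr.predict(
            X, self.weights, self.model.params, self.model.config, kind=self.model.kind
        )

    def accuracy(self, dataset: WindowedDataset) -> float:
        return float(np.mean(self.predict(dataset) == dataset.labels))

    def simulate(self, window: np.ndarray):
        """Full state trajectory plus scores for a single ``(O, L)`` window."""
        if self.model.kind == "mems":
            return simulate_network(
                window, self.model.params, self.weights,
                sample_dt=self.model.config.sample_dt, substeps=self.model.config.substeps,
            )
        params = from_network_weights(self.weights, self.model.params.tau)
        return simulate_ctrnn(
            window, params,
            sample_dt=self.model.config.sample_dt, substeps=self.model.config.substeps,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        n_nodes = self.weights.n_nodes
        lines = [
            "Activity detector fit",
            "=" * 44,
            f"model kind        {m.kind}",
            f"nodes             {n_nodes} ({self.weights.n_inputs} input + "
            f"{n_nodes - self.weights.n_inputs} hidden)",
            f"time constant     {m.params.tau:.6g} s",
            f"epochs            {len(self.history)}",
            f"final loss        {self.final_loss:.4f}",
            f"train accuracy    {self.train_accuracy:.4f}",
            f"windows           {len(m.dataset)} "
            f"(positive fraction {m.dataset.positive_fraction:.3f})",
            "=" * 44,
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        mio.save_weights(self.weights, directory)
        if self.model.kind == "mems":
            mio.save_params(self.model.params, directory / "params.json")
        self.history.to_csv(directory / "history.csv", index=False)
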