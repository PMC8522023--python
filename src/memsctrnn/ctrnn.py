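"""Reference continuous-time recurrent neural network (CTRNN).

Software baseline against which the MEMS network is compared.  Neuron
activations obey the first-order ODE

    dy_i/dt = (1/tau_i) * (-y_i + sum_j w_ij * sigma(y_j) + h_i + I_i)

with logistic ``sigma``.  Integration uses the same explicit-Euler
sub-stepping policy as :mod:`memsctrnn.mems`, so comparisons between the
two isolate the node model rather than the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mems import NetworkWeights, auto_substeps

__all__ = ["CTRNNParams", "CTRNNState", "ctrnn_step", "simulate_ctrnn", "sigmoid", "from_network_weights"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic activation, argument clipped to avoid overflow."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


@dataclass
class CTRNNParams:
    """Time constants, weights and readout of a reference CTRNN."""

    tau: np.ndarray
    w: np.ndarray
    h: np.ndarray
    w_in: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray

    def __post_init__(self) -> None:
        n = len(np.atleast_1d(self.h))
        self.tau = np.broadcast_to(np.asarray(self.tau, dtype=float), (n,)).copy()
        self.w = np.asarray(self.w, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        if np.any(self.tau <= 0):
            raise ValueError("all time constants must be strictly positive")
        for name in ("tau", "w", "h", "w_in", "w_out", "b_out"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")
        if self.w.shape != (n, n) or self.w_in.shape[0] != n or self.w_out.shape[1] != n:
            raise ValueError("shapes inconsistent with number of neurons")

    @property
    def n_nodes(self) -> int:
        return len(self.h)

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1]


@dataclass
class CTRNNState:
    y: np.ndarray
    t: float = 0.0


def from_network_weights(weights: NetworkWeights, tau: float | np.ndarray) -> CTRNNParams:
    """Wrap a trained :class:`NetworkWeights` container as CTRNN parameters."""
    return CTRNNParams(
        tau=tau, w=weights.w_rec, h=weights.theta, w_in=weights.w_in,
        w_out=weights.w_out, b_out=weights.b_out,
    )


def ctrnn_step(state: CTRNNState, params: CTRNNParams, input_t: np.ndarray, dt: float) -> CTRNNState:
    """One explicit-Euler step of the CTRNN ODE (deterministic)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    input_t = np.asarray(input_t, dtype=float)
    drive = params.w @ sigmoid(state.y) + params.h + params.w_in @ input_t
    y_new = state.y + (dt / params.tau) * (-state.y + drive)
    return CTRNNState(y=y_new, t=state.t + dt)


def simulate_ctrnn(
    input_window: np.ndarray,
    params: CTRNNParams,
    sample_dt: float = 0.02,
    substeps: int | None = None,
):
    """Integrate the CTRNN over an ``O x L`` input window.

    Mirrors :func:`memsctrnn.mems.simulate_network`: each sample is held
    constant for ``sample_dt`` and integrated with ``substeps`` Euler
    sub-steps; the readout is applied to the terminal activation summary
    ``sigma(y)``.  Returns a per-sample trajectory and the two class scores.
    """
    X = np.atleast_2d(np.asarray(input_window, dtype=float))
    n_channels, n_samples = X.shape
    if n_samples < 1:
        raise ValueError("input window must contain at least one sample")
    if n_channels != params.n_inputs:
        raise ValueError(f"input has {n_channels} channels but params expect {params.n_inputs}")
    if substeps is None:
        substeps = auto_substeps(float(np.min(params.tau)), sample_dt)
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    dt = sample_dt / substeps

    state = CTRNNState(y=np.zeros(params.n_nodes))
    t_rec = np.zeros(n_samples + 1)
    y_rec = np.zeros((n_samples + 1, params.n_nodes))
    for i in range(n_samples):
        u = X[:, i]
        for _ in range(substeps):
            state = ctrnn_step(state, params, u, dt)
        t_rec[i + 1] = state.t
        y_rec[i + 1] = state.y
    scores = params.w_out @ sigmoid(state.y) + params.b_out
    return {"t": t_rec, "y": y_rec}, scores
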