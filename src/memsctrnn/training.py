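"""Backpropagation-through-time training of the discretized networks.

The MEMS network's unit-step firing function is not differentiable, so
training uses a *smooth* forward pass in which the step is replaced by a
logistic surrogate ``sigma(beta * (z - fire_frac * d))``; as the steepness
``beta`` grows the smooth scores converge to the hard-step simulator's.
Training minimizes the mean cross-entropy of the softmaxed class scores by
mini-batch gradient descent with global gradient-norm clipping; gradients
are computed by a hand-written reverse pass through the Euler recursion,
including the adjoint of the per-step gated voltage solve.  Evaluation and
all reported accuracies always use the hard-step simulator, so they reflect
the physical model rather than its differentiable relaxation.

Network layout convention: the first ``n_inputs`` nodes form the input
layer (their ``w_in`` rows are nonzero, one node per sensor channel), the
remaining nodes are the hidden computing layer, and a dense two-way readout
maps the terminal firing summary to class scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctrnn import sigmoid
from .mems import MEMSParams, NetworkWeights, StabilityError, auto_substeps
from .preprocess import WindowedDataset

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "init_network",
    "forward_smooth",
    "forward_hard",
    "loss_and_grads",
    "train",
    "predict",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Discretization, surrogate and optimizer settings.

    ``sample_dt`` is the input sampling interval (s); ``substeps`` the
    number of Euler sub-steps per sample (``None`` = automatic from the
    stability bound).  ``surrogate_beta`` (1/m) sets the steepness of the
    logistic stand-in for the firing step.  ``theta_bias`` (V) centres the
    initial bias voltages near the sub-pull-in operating point.
    """

    sample_dt: float = 0.02
    substeps: int | None = None
    surrogate_beta: float = 1e6
    lr: float = 0.02
    epochs: int = 30
    batch_size: int = 64
    grad_clip: float = 5.0
    seed: int = 0
    init_scale: float = 0.3
    theta_bias: float = 3.0
    optimizer: str = "adam"
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.sample_dt <= 0 or self.lr <= 0 or self.batch_size < 1:
            raise ValueError("sample_dt, lr and batch_size must be positive")
        if self.epochs < 0 or self.grad_clip <= 0 or self.init_scale <= 0:
            raise ValueError("epochs must be >= 0; grad_clip and init_scale positive")
        if not np.isfinite(self.surrogate_beta) or self.surrogate_beta <= 0:
            raise ValueError("surrogate_beta must be finite and positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


def init_network(
    n_hidden: int,
    n_inputs: int,
    seed: int,
    init_scale: float = 0.3,
    theta_bias: float = 4.0,
) -> NetworkWeights:
    """Reproducible small-random initialization.

    Coupling and readout weights are uniform in ``[-init_scale,
    init_scale]``; the input block is diagonal (one input node per sensor
    channel) with random sign and magnitude in ``[init_scale/2,
    init_scale]`` so every channel is sensed from the start; bias voltages
    sit at ``theta_bias`` plus the uniform jitter, i.e. near (below) the
    static pull-in point so that the electrostatic nonlinearity is
    responsive from the first epoch.
    """
    if n_hidden < 1 or n_inputs < 1:
        raise ValueError("n_hidden and n_inputs must be positive")
    rng = np.random.default_rng(seed)
    n = n_inputs + n_hidden
    u = lambda *shape: rng.uniform(-init_scale, init_scale, size=shape)
    # one input node per sensor channel: diagonal input block, random sign,
    # magnitude bounded away from zero so every channel is sensed at start
    w_in = np.zeros((n, n_inputs))
    mags = rng.uniform(init_scale / 2, init_scale, size=n_inputs)
    signs = rng.choice([-1.0, 1.0], size=n_inputs)
    w_in[np.arange(n_inputs), np.arange(n_inputs)] = mags * signs
    return NetworkWeights(
        w_rec=u(n, n),
        w_in=w_in,
        theta=theta_bias + u(n),
        w_out=u(2, n),
        b_out=np.zeros(2),
    )


def _input_row_mask(weights: NetworkWeights) -> np.ndarray:
    mask = np.any(weights.w_in != 0.0, axis=1)
    if not mask.any():
        mask[: weights.n_inputs] = True
    return mask.astype(float)[:, None]


def _resolve_substeps(config: TrainConfig, tau: float) -> int:
    return config.substeps if config.substeps is not None else auto_substeps(tau, config.sample_dt)


def _batched_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    # A: (B, N, N); b: (N,) or (B, N)
    b = np.broadcast_to(b, A.shape[:2])
    return np.linalg.solve(A, b[..., None])[..., 0]


# ---------------------------------------------------------------------------
# MEMS forward / backward


def _mems_forward_batch(X, weights, params, sample_dt, substeps, beta=None, want_tape=False):
    """Batched integration of the MEMS network over (B, O, L) windows.

    ``beta=None`` runs the hard-step physical model; a finite ``beta`` runs
    the smooth surrogate.  Returns (scores, summary, tape).
    """
    B, O, L = X.shape
    N = weights.n_nodes
    S_sub = substeps
    dt = sample_dt / S_sub
    tau = params.tau
    if dt > 2.0 * tau:
        raise StabilityError(
            f"dt = {dt:g} s exceeds 2*tau = {2 * tau:g} s; increase substeps"
        )
    h = dt / tau
    c1 = params.force_coeff
    d = params.d
    z_stop, z_fire = params.z_stop, params.z_fire
    gin = params.resolved_input_gain / params.omega_n**2
    eye = np.eye(N)

    def firing(z):
        if beta is None:
            return (z >= z_fire).astype(float)
        return sigmoid(beta * (z - z_fire))

    Ts = L * S_sub
    z = np.zeros((B, N))
    s = firing(z)
    if want_tape:
        Z = np.empty((Ts + 1, B, N)); Z[0] = z
        S_arr = np.empty((Ts + 1, B, N)); S_arr[0] = s
        V_arr = np.empty((Ts, B, N))
        M_arr = np.empty((Ts, B, N))
    fins = gin * np.einsum("no,bol->bnl", weights.w_in, X)
    t = 0
    for i in range(L):
        fin = fins[:, :, i]
        for _ in range(S_sub):
            A = eye[None] - weights.w_rec[None] * s[:, None, :]
            V = _batched_solve(A, weights.theta)
            gap = d - z
            F = c1 * V**2 / gap**2 + fin
            zpre = z + h * (F - z)
            mask = ((zpre > 0.0) & (zpre < z_stop)).astype(float)
            z = np.clip(zpre, 0.0, z_stop)
            s = firing(z)
            if want_tape:
                V_arr[t] = V
                M_arr[t] = mask
                Z[t + 1] = z
                S_arr[t + 1] = s
            t += 1
    if not np.all(np.isfinite(z)):
        raise StabilityError("non-finite displacement during batched simulation")
    scores = s @ weights.w_out.T + weights.b_out
    tape = None
    if want_tape:
        tape = {"Z": Z, "S": S_arr, "V": V_arr, "M": M_arr, "h": h, "c1": c1,
                "d": d, "gin": gin, "S_sub": S_sub, "beta": beta}
    return scores, s, tape


def _mems_backward_batch(X, y, weights, tape, scores):
    """Reverse pass through the tape; returns loss gradient dict."""
    B, O, L = X.shape
    N = weights.n_nodes
    Z, S_arr, V_arr, M_arr = tape["Z"], tape["S"], tape["V"], tape["M"]
    h, c1, d, gin, S_sub, beta = (
        tape["h"], tape["c1"], tape["d"], tape["gin"], tape["S_sub"], tape["beta"]
    )
    eye = np.eye(N)
    Ts = L * S_sub

    p = _softmax(scores)
    dscore = (p - _onehot(y)) / B
    gWout = dscore.T @ S_arr[Ts]
    gbout = dscore.sum(axis=0)
    gs = dscore @ weights.w_out  # grad wrt S[Ts]

    gW = np.zeros_like(weights.w_rec)
    gWin = np.zeros_like(weights.w_in)
    gtheta = np.zeros_like(weights.theta)
    gz = np.zeros((B, N))
    w_rec_T_batchless = weights.w_rec
    for t in range(Ts, 0, -1):
        st = S_arr[t]
        gz = gz + gs * beta * st * (1.0 - st)
        gzpre = gz * M_arr[t - 1]
        zprev = Z[t - 1]
        Vt = V_arr[t - 1]
        sprev = S_arr[t - 1]
        gap = d - zprev
        gz = gzpre * (1.0 - h) + gzpre * h * (2.0 * c1 * Vt**2 / gap**3)
        gV = gzpre * h * (2.0 * c1 * Vt / gap**2)
        u = X[:, :, (t - 1) // S_sub]
        gWin += h * gin * gzpre.T @ u
        A_T = (eye[None] - w_rec_T_batchless[None] * sprev[:, None, :]).transpose(0, 2, 1)
        lam = _batched_solve(A_T, gV)
        gtheta += lam.sum(axis=0)
        gW += np.einsum("bj,bk->jk", lam, Vt * sprev)
        gs = Vt * (lam @ w_rec_T_batchless)  # grad wrt S[t-1]
    return {"w_rec": gW, "w_in": gWin, "theta": gtheta, "w_out": gWout, "b_out": gbout}


# ---------------------------------------------------------------------------
# Reference CTRNN forward / backward (same training harness)


def _ctrnn_forward_batch(X, weights, tau, sample_dt, substeps, want_tape=False):
    B, O, L = X.shape
    N = weights.n_nodes
    dt = sample_dt / substeps
    hvec = dt / np.broadcast_to(np.asarray(tau, dtype=float), (N,))
    Ts = L * substeps
    y_state = np.zeros((B, N))
    if want_tape:
        Y = np.empty((Ts + 1, B, N)); Y[0] = y_state
    fins = np.einsum("no,bol->bnl", weights.w_in, X)
    t = 0
    for i in range(L):
        fin = fins[:, :, i]
        for _ in range(substeps):
            drive = sigmoid(y_state) @ weights.w_rec.T + weights.theta + fin
            y_state = y_state + hvec * (drive - y_state)
            if want_tape:
                Y[t + 1] = y_state
            t += 1
    summary = sigmoid(y_state)
    scores = summary @ weights.w_out.T + weights.b_out
    tape = {"Y": Y, "h": hvec, "substeps": substeps} if want_tape else None
    return scores, summary, tape


def _ctrnn_backward_batch(X, y, weights, tape, scores):
    B, O, L = X.shape
    Y, hvec, S_sub = tape["Y"], tape["h"], tape["substeps"]
    Ts = L * S_sub
    p = _softmax(scores)
    dscore = (p - _onehot(y)) / B
    sT = sigmoid(Y[Ts])
    gWout = dscore.T @ sT
    gbout = dscore.sum(axis=0)
    gy = (dscore @ weights.w_out) * sT * (1.0 - sT)

    gW = np.zeros_like(weights.w_rec)
    gWin = np.zeros_like(weights.w_in)
    gtheta = np.zeros_like(weights.theta)
    for t in range(Ts, 0, -1):
        yprev = Y[t - 1]
        sprev = sigmoid(yprev)
        gyh = gy * hvec
        gW += np.einsum("bi,bj->ij", gyh, sprev)
        gtheta += gyh.sum(axis=0)
        u = X[:, :, (t - 1) // S_sub]
        gWin += gyh.T @ u
        gy = gy * (1.0 - hvec) + (gyh @ weights.w_rec) * sprev * (1.0 - sprev)
    return {"w_rec": gW, "w_in": gWin, "theta": gtheta, "w_out": gWout, "b_out": gbout}


# ---------------------------------------------------------------------------
# Public surface


def _softmax(scores):
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _onehot(y):
    out = np.zeros((len(y), 2))
    out[np.arange(len(y)), y] = 1.0
    return out


def cross_entropy(scores, y):
    shifted = scores - scores.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-np.mean(logp[np.arange(len(y)), y]))


def forward_smooth(X, weights, params, config: TrainConfig):
    """Differentiable class scores for a batch of ``(B, O, L)`` windows."""
    X = np.asarray(X, dtype=float)
    substeps = _resolve_substeps(config, params.tau)
    scores, _, _ = _mems_forward_batch(
        X, weights, params, config.sample_dt, substeps, beta=config.surrogate_beta
    )
    return scores


def forward_hard(X, weights, params, sample_dt=0.02, substeps=None, kind="mems", tau=None):
    """Hard-step (physical) class scores for a batch of windows."""
    X = np.asarray(X, dtype=float)
    if kind == "mems":
        if substeps is None:
            substeps = auto_substeps(params.tau, sample_dt)
        scores, _, _ = _mems_forward_batch(X, weights, params, sample_dt, substeps, beta=None)
    else:
        tau = params.tau if tau is None else tau
        if substeps is None:
            substeps = auto_substeps(float(np.min(tau)), sample_dt)
        scores, _, _ = _ctrnn_forward_batch(X, weights, tau, sample_dt, substeps)
    return scores


def loss_and_grads(X, y, weights, params, config: TrainConfig, kind="mems", tau=None):
    """Cross-entropy loss and its exact gradients for one mini-batch."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if kind == "mems":
        substeps = _resolve_substeps(config, params.tau)
        scores, _, tape = _mems_forward_batch(
            X, weights, params, config.sample_dt, substeps,
            beta=config.surrogate_beta, want_tape=True,
        )
        grads = _mems_backward_batch(X, y, weights, tape, scores)
    elif kind == "ctrnn":
        tau = params.tau if tau is None else tau
        substeps = (
            config.substeps
            if config.substeps is not None
            else auto_substeps(float(np.min(np.atleast_1d(tau))), config.sample_dt)
        )
        scores, _, tape = _ctrnn_forward_batch(
            X, weights, tau, config.sample_dt, substeps, want_tape=True
        )
        grads = _ctrnn_backward_batch(X, y, weights, tape, scores)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return cross_entropy(scores, y), grads


def _clip_global(grads, max_norm):
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads


class _Optimizer:
    """Adam or momentum-SGD over the named weight groups."""

    def __init__(self, config: TrainConfig, weights: NetworkWeights):
        self.config = config
        self.t = 0
        groups = ("w_rec", "w_in", "theta", "w_out", "b_out")
        self.m = {k: np.zeros_like(getattr(weights, k)) for k in groups}
        self.v = {k: np.zeros_like(getattr(weights, k)) for k in groups}

    def step(self, weights: NetworkWeights, grads):
        cfg = self.config
        self.t += 1
        for k, g in grads.items():
            if cfg.optimizer == "adam":
                self.m[k] = 0.9 * self.m[k] + 0.1 * g
                self.v[k] = 0.999 * self.v[k] + 0.001 * g**2
                mhat = self.m[k] / (1 - 0.9**self.t)
                vhat = self.v[k] / (1 - 0.999**self.t)
                update = cfg.lr * mhat / (np.sqrt(vhat) + 1e-8)
            else:
                self.m[k] = cfg.momentum * self.m[k] + g
                update = cfg.lr * self.m[k]
            setattr(weights, k, getattr(weights, k) - update)


def train(
    dataset: WindowedDataset,
    config: TrainConfig,
    params: MEMSParams | None = None,
    kind: str = "mems",
    n_hidden: int = 6,
    weights: NetworkWeights | None = None,
    tau: float | None = None,
):
    """Train a binary window classifier; returns (weights, history).

    The history DataFrame has one row per epoch with the mean smooth-pass
    cross-entropy and the hard-step training accuracy.  Fully deterministic
    given ``config.seed``.

    Raises
    ------
    ValueError
        If the dataset does not contain both classes.
    TrainingDivergedError
        If the loss becomes non-finite (with diagnostics).
    """
    params = params if params is not None else MEMSParams()
    X = np.asarray(dataset.windows, dtype=float)
    y = np.asarray(dataset.labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training dataset must contain both classes")
    n_inputs = X.shape[1]
    if weights is None:
        # the sub-pull-in bias operating point is specific to the MEMS node
        theta_bias = config.theta_bias if kind == "mems" else 0.0
        weights = init_network(n_hidden, n_inputs, config.seed, config.init_scale, theta_bias)
    else:
        weights = weights.copy()
    opt = _Optimizer(config, weights)
    in_mask = _input_row_mask(weights)  # keep w_in structurally zero off the input layer
    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = perm[start:start + config.batch_size]
            loss, grads = loss_and_grads(X[idx], y[idx], weights, params, config, kind=kind, tau=tau)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}; "
                    f"max |w_rec| = {np.abs(weights.w_rec).max():.3g}, "
                    f"max |theta| = {np.abs(weights.theta).max():.3g}"
                )
            grads["w_in"] = grads["w_in"] * in_mask
            grads = _clip_global(grads, config.grad_clip)
            opt.step(weights, grads)
            losses.append(loss)
        preds = predict(X, weights, params, config=config, kind=kind, tau=tau)
        acc = float(np.mean(preds == y))
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": acc})
    return weights, pd.DataFrame(history, columns=["epoch", "loss", "train_accuracy"])


def predict(
    X,
    weights: NetworkWeights,
    params: MEMSParams | None = None,
    config: TrainConfig | None = None,
    kind: str = "mems",
    tau: float | None = None,
):
    """Hard-step class predictions (0/1) for a batch of windows."""
    params = params if params is not None else MEMSParams()
    sample_dt = config.sample_dt if config is not None else 0.02
    substeps = config.substeps if config is not None else None
    if kind == "ctrnn" and tau is None:
        tau = params.tau
    scores = forward_hard(X, weights, params, sample_dt, substeps, kind=kind, tau=tau)
    return np.argmax(scores, axis=1)
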