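"""Electrostatic MEMS neuron networks.

Each neuron is a parallel-plate electrostatic actuator reduced to a
first-order (inertia-neglected) spring--damper equation for the proof-mass
displacement ``z``:

    tau * dz/dt + z = eps*A / (2*k*(d - z)^2) * V^2  +  (1/omega_n^2) * sum_k w_in_k u_k(t)

with ``tau = 2*zeta/omega_n`` the mechanical time constant, ``d`` the
electrostatic gap and ``V`` the node voltage.  The electrostatic force is
attractive and diverges as the gap closes, which produces the pull-in
instability: above a critical voltage no static equilibrium exists and the
proof mass snaps toward the electrode.  Contact is modelled by clamping the
displacement at ``contact_frac * d``; a neuron *fires* (drives downstream
voltages) once ``z >= fire_frac * d``.  Because the release voltage of a
pulled-in plate is far below the pull-in voltage, each neuron is a bistable
latch and the network as a whole has hysteretic memory -- the mechanism that
lets a handful of coupled MEMS devices emulate a continuous-time recurrent
neural network.

Node voltages follow a linear superposition gated by firing::

    V_j = sum_k w_jk * V_k * fired_k + theta_j

which is solved as a linear system with the firing pattern held fixed at the
previous integration step (one-step delay; see :func:`node_voltages`).

All quantities are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MEMSParams",
    "NetworkWeights",
    "NetworkState",
    "PowerModel",
    "StabilityError",
    "VoltageDivergenceError",
    "node_voltages",
    "mems_step",
    "static_pullin_voltage",
    "release_voltage",
    "simulate_network",
    "auto_substeps",
    "time_constant",
    "scaled_time_constant",
    "network_power",
]


class StabilityError(RuntimeError):
    """Raised when the explicit-Euler step is too large for the dynamics."""


class VoltageDivergenceError(RuntimeError):
    """Raised when the gated voltage recursion has no finite solution."""


@dataclass(frozen=True)
class MEMSParams:
    """Physical constants of one electrostatic MEMS neuron.

    Parameters
    ----------
    zeta : float
        Damping ratio (dimensionless).  The devices operate in the
        damping-dominated regime, so inertia is neglected.
    omega_n : float
        Natural angular frequency in rad/s.  Together with ``zeta`` it sets
        the time constant ``tau = 2 * zeta / omega_n``.
    A : float
        Overlapping electrode area in m^2.
    k : float
        Linear suspension stiffness in N/m.
    eps_air : float
        Permittivity of the gap medium in F/m (default: air).
    d : float
        Electrostatic gap between proof mass and fixed electrode in m.
    contact_frac : float
        Fraction of ``d`` at which motion stops (mechanical contact /
        stopper).  Must lie in (0, 1); the travel clamp keeps the
        ``(d - z)^2`` denominator away from its singularity.
    fire_frac : float
        Fraction of ``d`` at which the firing indicator switches on.
        ``fire_frac <= contact_frac`` so a pulled-in neuron always fires.
    input_gain : float or None
        Gain that maps (dimensionless, standardized or ternary) input
        samples to a displacement-scale forcing.  ``None`` resolves to
        ``d * omega_n**2`` so that a unit input weight and unit input
        produce a forcing of one gap; see docs/methods.md.

    The default geometry (A = 1 mm^2, k = 0.01 N/m, d = 42 um) places the
    static pull-in voltage near 5 V, the assumed operating voltage of the
    switching-power model.
    """

    zeta: float = 0.85
    omega_n: float = 1000.0
    A: float = 1e-6
    k: float = 0.01
    eps_air: float = 8.854e-12
    d: float = 42e-6
    contact_frac: float = 0.95
    fire_frac: float = 0.90
    input_gain: float | None = None

    def __post_init__(self) -> None:
        for name in ("zeta", "omega_n", "A", "k", "eps_air", "d"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"MEMSParams.{name} must be finite and nonnegative, got {value!r}")
        if self.omega_n <= 0:
            raise ValueError("omega_n must be strictly positive")
        for name in ("A", "k", "eps_air", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.fire_frac <= self.contact_frac < 1.0):
            raise ValueError("need 0 < fire_frac <= contact_frac < 1")
        if not math.isfinite(self.tau) or self.tau <= 0:
            raise ValueError("derived time constant must be finite and positive")

    @property
    def tau(self) -> float:
        """Mechanical time constant ``2 * zeta / omega_n`` in seconds."""
        return 2.0 * self.zeta / self.omega_n

    @property
    def z_stop(self) -> float:
        """Travel limit ``contact_frac * d`` in metres."""
        return self.contact_frac * self.d

    @property
    def z_fire(self) -> float:
        """Firing threshold ``fire_frac * d`` in metres."""
        return self.fire_frac * self.d

    @property
    def force_coeff(self) -> float:
        """Electrostatic force coefficient ``eps * A / (2 * k)`` (m^3 / V^2)."""
        return self.eps_air * self.A / (2.0 * self.k)

    @property
    def resolved_input_gain(self) -> float:
        return self.d * self.omega_n**2 if self.input_gain is None else self.input_gain

    def with_tau_scaled(self, P: float) -> "MEMSParams":
        """Return params with ``omega_n`` multiplied by ``P`` (tau -> tau / P)."""
        if P == 0:
            raise ValueError("P must be nonzero")
        return replace(self, omega_n=self.omega_n * P)


@dataclass
class NetworkWeights:
    """Connection weights of a MEMS (or reference CTRNN) network.

    ``w_rec`` couples all N nodes (input-layer + hidden-layer neurons);
    ``w_in`` has nonzero rows only for the input-layer nodes; ``theta`` is
    the per-node bias voltage; ``w_out``/``b_out`` form the dense two-way
    readout applied to the terminal firing summary.
    """

    w_rec: np.ndarray
    w_in: np.ndarray
    theta: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.w_rec = np.asarray(self.w_rec, dtype=float)
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.b_out is None:
            self.b_out = np.zeros(self.w_out.shape[0])
        self.b_out = np.asarray(self.b_out, dtype=float)
        n = self.n_nodes
        if self.w_rec.shape != (n, n):
            raise ValueError("w_rec must be square")
        if self.w_in.ndim != 2 or self.w_in.shape[0] != n:
            raise ValueError("w_in must be N x O")
        if self.theta.shape != (n,):
            raise ValueError("theta must have length N")
        if self.w_out.shape[1] != n or self.b_out.shape != (self.w_out.shape[0],):
            raise ValueError("readout shapes inconsistent with N")
        for name in ("w_rec", "w_in", "theta", "w_out", "b_out"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.w_rec.shape[0] if self.w_rec.ndim == 2 else len(self.theta)

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.w_rec.copy(), self.w_in.copy(), self.theta.copy(),
            self.w_out.copy(), self.b_out.copy(),
        )


@dataclass
class NetworkState:
    """Instantaneous state of the network: displacements, firing, voltages."""

    z: np.ndarray
    fired: np.ndarray
    V: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, weights: NetworkWeights) -> "NetworkState":
        """Rest state: zero displacement, nothing fired, bias voltages."""
        n = weights.n_nodes
        z = np.zeros(n)
        fired = np.zeros(n)
        V = node_voltages(weights, fired)
        return cls(z=z, fired=fired, V=V, t=0.0)


@dataclass(frozen=True)
class PowerModel:
    """Lumped capacitor-charging model of per-neuron switching power.

    Each switching event charges the device capacitance ``C`` to the
    operating voltage ``V_op``, costing ``C * V_op^2 / 2`` joules; at a
    worst-case switching rate ``f_switch`` the per-neuron power is
    ``C * V_op^2 * f_switch / 2``.
    """

    C: float = 0.5e-12
    V_op: float = 5.0
    f_switch: float = 100.0

    def __post_init__(self) -> None:
        for name in ("C", "V_op", "f_switch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def node_voltages(weights: NetworkWeights, fired_prev: np.ndarray) -> np.ndarray:
    """Solve the gated voltage superposition for all nodes.

    With the firing pattern ``fired_prev`` (from the previous integration
    step) held fixed, ``V_j = sum_k w_jk V_k fired_k + theta_j`` is the
    linear system ``(I - W diag(fired_prev)) V = theta``; its solution is
    returned.  Using the delayed firing pattern breaks the cyclic dependence
    between voltages and displacements in recurrent networks.

    Raises
    ------
    VoltageDivergenceError
        If the gated system is singular or produces a non-finite voltage;
        the message names the worst-offending neuron.
    """
    fired_prev = np.asarray(fired_prev, dtype=float)
    n = weights.n_nodes
    if fired_prev.shape != (n,):
        raise ValueError(f"fired_prev must have length {n}")
    A = np.eye(n) - weights.w_rec * fired_prev[np.newaxis, :]
    try:
        V = np.linalg.solve(A, weights.theta)
    except np.linalg.LinAlgError as exc:
        raise VoltageDivergenceError(
            "gated voltage system is singular (diverging voltage recursion)"
        ) from exc
    if not np.all(np.isfinite(V)):
        bad = int(np.argmax(~np.isfinite(V)))
        raise VoltageDivergenceError(f"non-finite voltage at neuron {bad}")
    return V


def mems_step(
    state: NetworkState,
    params: MEMSParams,
    weights: NetworkWeights,
    input_t: np.ndarray,
    dt: float,
) -> NetworkState:
    """Advance the network by one explicit-Euler step of size ``dt``.

    The displacement ODE is integrated with the node voltages computed from
    the previous step's firing pattern; afterwards displacements are clamped
    to ``[0, contact_frac * d]`` (contact stopper / rigid substrate) and the
    firing indicators recomputed.  Clamping at contact is part of the model:
    once pull-in starts, the electrostatic force diverges and any explicit
    step overshoots the contact plane, which physically means the proof mass
    has landed on the stopper.

    Raises
    ------
    StabilityError
        If ``dt > 2 * tau``, the explicit-Euler stability bound of the
        linear relaxation; use more sub-steps per input sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = params.tau
    if tau > 0 and dt > 2.0 * tau:
        raise StabilityError(
            f"dt = {dt:g} s exceeds the explicit-Euler stability bound 2*tau = "
            f"{2 * tau:g} s; increase the number of sub-steps per input sample"
        )
    input_t = np.asarray(input_t, dtype=float)
    V = node_voltages(weights, state.fired)
    gap = params.d - state.z
    f_es = params.force_coeff * V**2 / gap**2
    f_in = (params.resolved_input_gain / params.omega_n**2) * (weights.w_in @ input_t)
    z_target = f_es + f_in
    z_pre = state.z + (dt / tau) * (z_target - state.z)
    if not np.all(np.isfinite(z_pre)):
        bad = int(np.argmax(~np.isfinite(z_pre)))
        raise StabilityError(f"non-finite displacement at neuron {bad}")
    z_new = np.clip(z_pre, 0.0, params.z_stop)
    fired = (z_new >= params.z_fire).astype(float)
    return NetworkState(z=z_new, fired=fired, V=V, t=state.t + dt)


def static_pullin_voltage(params: MEMSParams) -> float:
    """Static pull-in (loss-of-equilibrium) voltage of one neuron.

    The static force balance ``k z = eps A V^2 / (2 (d - z)^2)`` loses its
    stable root at ``z = d/3``, giving the closed form

        V_PI = sqrt(8 k d^3 / (27 eps A)).
    """
    return math.sqrt(8.0 * params.k * params.d**3 / (27.0 * params.eps_air * params.A))


def release_voltage(params: MEMSParams) -> float:
    """Voltage below which a pulled-in (clamped) neuron detaches.

    At the travel stop ``z_stop = contact_frac * d`` the plate releases when
    the electrostatic force drops below the spring force, i.e. at
    ``V = sqrt(2 k z_stop (d - z_stop)^2 / (eps A))``.  Always below the
    pull-in voltage; the gap between the two is the hysteresis that gives
    the network its memory.
    """
    z = params.z_stop
    return math.sqrt(2.0 * params.k * z * (params.d - z) ** 2 / (params.eps_air * params.A))


def auto_substeps(params_tau: float, sample_dt: float, target_ratio: float = 1.5) -> int:
    """Smallest sub-step count with ``dt <= target_ratio * tau`` (stable Euler)."""
    if params_tau <= 0:
        return 1
    return max(1, math.ceil(sample_dt / (target_ratio * params_tau)))


def simulate_network(
    input_window: np.ndarray,
    params: MEMSParams,
    weights: NetworkWeights,
    sample_dt: float = 0.02,
    substeps: int | None = None,
):
    """Integrate the network over a multi-channel input window.

    Each input sample (column of the ``O x L`` matrix) is held constant for
    its sampling interval ``sample_dt`` and integrated with ``substeps``
    Euler sub-steps (``None``: chosen automatically from the stability
    bound).  Returns a per-sample trajectory and the pair of readout class
    scores ``w_out @ fired_terminal + b_out``.

    Returns
    -------
    trajectory : dict
        Arrays ``t`` (L+1,), ``z``, ``fired``, ``V`` (each (L+1, N)),
        recorded at the end of every sampling interval (index 0 = rest).
    scores : ndarray (2,)
        Class scores from the terminal firing summary.
    """
    X = np.atleast_2d(np.asarray(input_window, dtype=float))
    n_channels, n_samples = X.shape
    if n_samples < 1:
        raise ValueError("input window must contain at least one sample")
    if n_channels != weights.n_inputs:
        raise ValueError(
            f"input has {n_channels} channels but weights expect {weights.n_inputs}"
        )
    if substeps is None:
        substeps = auto_substeps(params.tau, sample_dt)
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    dt = sample_dt / substeps

    state = NetworkState.initial(weights)
    n = weights.n_nodes
    t_rec = np.zeros(n_samples + 1)
    z_rec = np.zeros((n_samples + 1, n))
    f_rec = np.zeros((n_samples + 1, n))
    v_rec = np.zeros((n_samples + 1, n))
    z_rec[0], f_rec[0], v_rec[0] = state.z, state.fired, state.V
    for i in range(n_samples):
        u = X[:, i]
        for _ in range(substeps):
            state = mems_step(state, params, weights, u, dt)
        t_rec[i + 1] = state.t
        z_rec[i + 1], f_rec[i + 1], v_rec[i + 1] = state.z, state.fired, state.V
    scores = weights.w_out @ state.fired + weights.b_out
    trajectory = {"t": t_rec, "z": z_rec, "fired": f_rec, "V": v_rec}
    return trajectory, scores


def time_constant(zeta: float, omega_n: float) -> float:
    """Mechanical time constant ``tau = 2 * zeta / omega_n`` in seconds."""
    if omega_n <= 0:
        raise ValueError("omega_n must be strictly positive")
    return 2.0 * zeta / omega_n


def scaled_time_constant(tau_base: float, P: float) -> float:
    """Time constant after scaling ``omega_n`` by the multiplier ``P``.

    Since ``tau = 2 zeta / omega_n``, multiplying ``omega_n`` by ``P``
    divides the time constant by ``P``.
    """
    if P == 0:
        raise ValueError("P must be nonzero")
    if tau_base <= 0:
        raise ValueError("tau_base must be positive")
    return tau_base / P


def network_power(model: PowerModel, n_neurons: int) -> float:
    """Total switching power in watts of ``n_neurons`` MEMS neurons.

    ``n_neurons * (C * V_op^2 / 2) * f_switch`` -- linear in the neuron
    count and quadratic in the operating voltage.
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be nonnegative")
    return n_neurons * 0.5 * model.C * model.V_op**2 * model.f_switch
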