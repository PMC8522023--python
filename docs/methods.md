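# Methods

## Device model

Each neuron is a parallel-plate electrostatic MEMS actuator reduced to a
first-order ODE for the proof-mass displacement `z` (inertia is negligible
against damping at these scales):

    τ ż + z = εA/(2k(d−z)²) · V²  +  (1/ωn²) Σ_k w_in,k u_k(t),   τ = 2ζ/ωn.

Two printed forms of the first-order coefficient circulate for this family
of models (`2ζωn` and `2ζ/ωn`); we use `2ζ/ωn` throughout so that the
homogeneous decay constant of the ODE equals the device time constant
`τ = 2ζ/ωn` that the rest of the machinery (the `P` multiplier sweep,
τ = 1.7 ms default) is built on. The electrostatic drive uses the *node
voltage* `V_i` solved once per step from the firing-gated superposition

    V_j = Σ_k w_jk V_k U(z_k − d_fire) + θ_j ,

rather than re-expanding the sum inside the force term, which would count
the bias twice. In a recurrent network this relation is cyclic; we break
the cycle by evaluating the gate `U` with the firing pattern of the
*previous* Euler step and then solving the remaining linear system
`(I − W·diag(fired)) V = θ` exactly. A singular system (voltage runaway) is
reported as an error naming the worst-offending neuron.

### Contact, firing and hysteresis

The electrostatic term diverges as the gap closes, so above the static
pull-in voltage `V_PI = √(8kd³/27εA)` the proof mass snaps toward the
electrode. Motion is stopped at `contact_frac·d` (default 0.95) — a
mechanical stopper that also keeps the `(d−z)²` denominator finite — and
the firing indicator switches on at `fire_frac·d` (default 0.9), so a
pulled-in neuron always fires. A latched neuron releases only when its
voltage falls below `√(2k z_stop (d−z_stop)²/εA)` (≈ 0.63 V for the default
device versus `V_PI ≈ 4.98 V`). This pull-in/release hysteresis is the
network's memory mechanism: with τ = 1.7 ms and a 20 ms sampling interval
the displacement dynamics fully relax within each sample, so *all*
cross-sample memory is carried by which neurons have latched.

### Default device constants

| parameter | default | unit | note |
|---|---|---|---|
| ζ | 0.85 | – | damping ratio |
| ωn | 1000 | rad/s | gives τ = 2ζ/ωn = 1.7 ms |
| d | 42 × 10⁻⁶ | m | electrostatic gap |
| A | 1 × 10⁻⁶ | m² | electrode overlap |
| k | 0.01 | N/m | suspension stiffness |
| ε | 8.854 × 10⁻¹² | F/m | permittivity of air |
| contact_frac / fire_frac | 0.95 / 0.90 | – | stopper / firing fractions |

`A` and `k` were chosen so that `V_PI ≈ 5 V`, the operating voltage assumed
by the switching-power model; the remaining values follow the device-scale
conventions above. The input term couples (dimensionless) standardized or
ternary samples to the displacement equation through a gain that defaults
to `d·ωn²`, i.e. a unit input with a unit weight forces a displacement of
one gap; the gain is exposed (`MEMSParams.input_gain`) because it is a
unit-bridging constant, not physics.

### Numerics

Explicit Euler with sub-stepping per 50 Hz input sample. The linear
relaxation imposes the stability bound `dt ≤ 2τ`; the sub-step count
defaults to the smallest value with `dt ≤ 1.5 τ` (8 sub-steps at the
default τ and sample rate) and `mems_step` raises with a "use more
sub-steps" hint when handed a `dt` beyond the bound. Overshoot past the
contact plane during a pull-in collapse is *not* an error: the collapse is
singular and any explicit step overshoots, which physically means the mass
has landed on the stopper — the clamp is the contact model. Displacements
are clamped to `[0, contact_frac·d]` after every step and the invariant
`0 ≤ z ≤ contact_frac·d` holds at all recorded states. Adaptive solvers are
used only as test oracles so that training sees a fixed, differentiable
recursion.

## Training

The firing step is replaced during training by the logistic surrogate
`σ(β(z − fire_frac·d))` with steepness β = 10⁶ 1/m by default (argument
clipped at ±60 to guard overflow); as β → ∞ the smooth scores converge to
the hard-step simulator's. The loss is the mean cross-entropy of the
softmaxed readout scores, minimized by mini-batch gradient descent with
global gradient-norm clipping. Gradients are computed by a hand-written
reverse pass through the Euler recursion, including the adjoint of the
per-step gated voltage solve (`∂L/∂θ = A⁻ᵀ g`, etc.); they match central
finite differences to better than 10⁻⁴ relative error on every weight
group. Because parameter groups live on very different scales (θ in volts
near pull-in, couplings dimensionless, input weights acting through the
`d·ωn²` gain), the default optimizer is Adam; plain momentum-SGD is
available via `TrainConfig.optimizer`.

Initialization places the bias voltages at `theta_bias = 3.0 V`
(≈ 0.6 `V_PI`) plus uniform jitter so neurons are responsive — with biases
near zero the electrostatic force, quadratic in voltage, is so small that
nothing ever approaches pull-in and all gradients vanish; with biases too
close to `V_PI` every neuron latches on any input and the terminal firing
pattern carries no information. The input layer has one node per sensor
channel (diagonal input block, random sign, magnitude in
`[init_scale/2, init_scale]`); a dense random input block would mix
channels and destroy the axis selectivity that the channel-ablation
protocol measures. Training always reports *hard-step* accuracy so that
results reflect the physical model, not its differentiable relaxation.

Known limitation: with a large β the surrogate's gradient is concentrated
in a thin band around the firing threshold that trajectories cross in a
single Euler step, so learning is driven mostly by the readout and by
sub-threshold equilibrium shifts; neurons whose parameters keep them far
from pull-in on every window receive almost no gradient and can stay dead.
The sub-pull-in initialization above is what keeps the network out of that
regime at the start.

## Pre-processing and augmentation

Quantization maps consecutive-sample differences to `{+1, −1, 0}` with a
per-channel threshold `ε = mean + std/2`. The implementation follows the
three-branch rule literally (`+1` when the current sample exceeds the next
by more than ε); the symbol names are configurable since the conventional
reading of "rise" is the opposite comparison. Quantized sequences are one
sample shorter than their source, so pipelines that quantize cut raw
windows of length `l+1`. Thresholds and standardization moments are always
fitted on the training split and frozen for the test split.

Window labeling is inclusive: a window is positive when the fraction of
in-window samples annotated with the target activity is `≥` the threshold
(default 0.75). Augmentation adds, for every positive training window, K
copies each mutated at exactly one uniformly chosen (channel, sample)
position to a different level at most M levels away (ternary windows clip
to the alphabet; continuous windows move on a grid of spacing std/4 by
default). K defaults to the smallest value that brings the positive class
to about half the training split. The alternative reading — one copy with K
mutated positions — is available as `mode="positions"`. Augmenting a
dataset tagged as a test split raises: augmentation belongs to training
only.

## Synthetic benchmark

The generator emulates 50 Hz gravity-removed body-acceleration streams
(zero-mean background: with a +g offset on the vertical channel the
`ε = μ + σ/2` rule would map every vertical transition to "no change").
Defaults, chosen once:

* 3 subjects × 90 s; window 64 samples (1.28 s), stride 32 → ≈ 417 windows;
* walk-like target: 8–12 s sinusoidal bouts at ≈ 2 Hz spanning all three
  axes (amplitudes 2.0/2.5/3.0 m/s², distinct phases) with a 2.5 s
  amplitude build-up and decay at segment edges;
* four postural-transition classes (smooth one-axis bumps, 2–3 s) and an
  oscillatory *distractor* (walk-like on x/y, nearly flat on z, 8 % of
  samples) in the null class;
* class proportions mirroring a strongly imbalanced recording (walk 15.8 %,
  transitions 0.6/0.3/1.0/0.8 %), Gaussian sensor noise (σ = 0.2 m/s²),
  per-subject gain/offset, everything seeded.

Two generator features are deliberate experimental levers. The *distractor*
makes the vertical axis necessary: with only x/y channels it is
indistinguishable from the target, so 2-channel accuracy cannot exceed
3-channel accuracy. The *onset ramp* places windows that contain 50–74 %
of a bout near the noise floor, so a 50 % labeling threshold fills the
positive class with barely-detectable examples while a 75 % threshold keeps
them negative — the physical basis for the threshold comparison. The
default evaluation protocol is non-quantized (standardized) input, the
protocol under which the headline averages are defined; quantization
remains a grid axis, but note that ternary symbols are amplitude-blind
while the latch-based network discriminates mainly by amplitude, so
quantized accuracy on this benchmark is lower.

What passing these tests shows — and does not show. The benchmark
demonstrates that the training framework can shape the latch dynamics into
a working detector under controlled, favorable conditions (high
separability, exact annotations, simple templates). It does not establish
accuracy on real recordings, which contain orientation drift, inter-subject
variability and annotation noise the generator does not model.

## Evaluation protocols

Window-level seeded 70/30 split (a by-subject mode is available since
window-level splitting lets windows of one subject appear on both sides);
accuracy is plain window-level agreement, with confusion counts logged.
Per-activity accuracies average arithmetically (reported to two decimals).
The grid runner sweeps model kind, hidden size {3, 6, 9, 16}, quantization,
channel subsets, labeling thresholds {0.5, 0.75} and the time-constant
multiplier `P ∈ {1/5, 1/4, 1/3, 1/2, 1, 2, …, 10}` (τ → τ/P via ωn → P·ωn),
records one row per cell per seed, and converts per-cell failures into
logged rows rather than aborting. The random-label null replaces every
label with a fair coin flip, making chance level 0.5 regardless of the
class prior (a permutation null would leave the ~85 % majority prior as its
chance level, which is uninformative for a balanced-training detector).

Problem sizes used by the shipped tests — the ~417-window benchmark, four
protocol cells, 30 training epochs — were chosen as the smallest
configuration at which the protocol directions are stable and reproducible
on a single CPU.
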