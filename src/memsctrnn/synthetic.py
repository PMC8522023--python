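"""Seeded generator of wearable-like tri-axial recordings.

Emulates 50 Hz body-acceleration streams containing one oscillatory
("walk"-like) activity and several transient postural transitions embedded
in a dominant null class, with per-subject gain/offset variation and
Gaussian sensor noise.  The background is zero-mean (gravity-removed body
acceleration); the walk template is a multi-axis sinusoid with per-axis
amplitude and phase, and each postural transition is a smooth one-axis
bump.  Templates are deliberately simple -- the generator exists so every
other module can be exercised and tested end-to-end without downloading
data, not to be biomechanically realistic.

Default class proportions mirror a realistic imbalance (walk ~15.8 % of
samples; each transition well below 1 %), which makes the positive class a
small minority of windows for every single-activity detection task and
motivates the mutation-based augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Recording
from .preprocess import WindowedDataset, concat_datasets, make_windows

__all__ = ["ActivityTemplate", "SynthConfig", "generate_recording", "generate_recordings", "generate_benchmark"]

WALK = 1
TRANSITIONS = (2, 3, 4, 5)
DISTRACTOR = 6  # walk-like arm/torso oscillation that barely moves the z axis


@dataclass(frozen=True)
class ActivityTemplate:
    """Generative template for one activity class.

    ``kind="oscillation"``: sinusoid with per-axis ``amplitudes`` (m/s^2),
    common ``frequency`` (Hz) and per-axis ``phases``; segment duration
    drawn uniformly from ``duration_range`` (s).
    ``kind="step"``: smooth raised-cosine bump of height ``delta`` on one
    ``axis`` (a gravity-removed postural transition transient).
    """

    kind: str
    amplitudes: tuple = (2.0, 2.5, 3.0)
    frequency: float = 2.0
    phases: tuple = (0.0, 2.0943951023931953, 4.1887902047863905)  # 0, 2pi/3, 4pi/3
    attack: float = 2.5  # s; amplitude ramp at segment onset/offset (gait builds up)
    axis: int = 0
    delta: float = 3.0
    duration_range: tuple = (4.0, 6.0)

    def __post_init__(self) -> None:
        if self.kind not in ("oscillation", "step"):
            raise ValueError("template kind must be 'oscillation' or 'step'")


def _default_palette() -> dict:
    return {
        WALK: ActivityTemplate(kind="oscillation", duration_range=(8.0, 12.0)),
        2: ActivityTemplate(kind="step", axis=0, delta=3.0, duration_range=(2.0, 3.0)),
        3: ActivityTemplate(kind="step", axis=1, delta=-3.0, duration_range=(2.0, 3.0)),
        4: ActivityTemplate(kind="step", axis=2, delta=3.5, duration_range=(2.0, 3.0)),
        5: ActivityTemplate(kind="step", axis=1, delta=3.0, duration_range=(2.0, 3.0)),
        DISTRACTOR: ActivityTemplate(
            kind="oscillation", amplitudes=(2.0, 2.5, 0.3), frequency=1.6,
            duration_range=(6.0, 9.0),
        ),
    }


def _default_proportions() -> dict:
    # walk and transition shares mirror a strongly imbalanced wearable
    # recording; the distractor is a null-class oscillation that makes the
    # vertical axis necessary for discrimination
    return {WALK: 0.158, 2: 0.006, 3: 0.003, 4: 0.010, 5: 0.008, DISTRACTOR: 0.08}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    ``separability`` scales every template amplitude relative to the noise
    floor (0 turns the templates off entirely, yielding an unlearnable null
    benchmark); ``channels=6`` appends pseudo-gyroscope channels built as
    differentiated, independently noised copies of the acceleration axes.
    """

    sample_rate: float = 50.0
    duration: float = 90.0
    channels: int = 3
    noise_sd: float = 0.2
    separability: float = 1.0
    proportions: dict = field(default_factory=_default_proportions)
    palette: dict = field(default_factory=_default_palette)
    subject_gain: tuple = (0.9, 1.1)
    subject_offset: tuple = (-0.1, 0.1)
    gyro_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        if self.channels not in (3, 6):
            raise ValueError("channels must be 3 or 6")
        props = dict(self.proportions)
        if any(p < 0 for p in props.values()):
            raise ValueError("proportions must be nonnegative")
        if sum(props.values()) > 1.0 + 1e-9:
            raise ValueError("class proportions must sum to at most 1 (remainder is the null class)")


def _place_segments(rng, T, rate, config):
    """Draw non-overlapping (activity, start, end) segments meeting the
    per-class sample budgets as closely as the geometry allows."""
    occupied = np.zeros(T, dtype=bool)
    segments = []
    for act, prop in sorted(config.proportions.items(), key=lambda kv: -kv[1]):
        template = config.palette[act]
        budget = int(round(prop * T))
        if budget == 0:
            continue
        lo, hi = template.duration_range
        mean_len = 0.5 * (lo + hi) * rate
        min_len = max(2, int(round(lo * rate)))
        # whole segments only: at least one per configured class, so short
        # recordings overshoot rare-class proportions; long ones converge
        n_seg = max(1, int(round(budget / mean_len)))
        # segments are capped by the class budget (or the template minimum)
        # and by half of the remaining free space, so short recordings stay
        # feasible and roughly honor the configured proportions
        length_cap = max(budget, min(min_len, T // 8))
        placed_any = False
        for _ in range(n_seg):
            free = T - int(occupied.sum())
            length = min(int(round(rng.uniform(lo, hi) * rate)), length_cap, max(2, free // 2))
            if length < 2 or length > T:
                break
            # rejection-sample a free slot; halve the segment if the free
            # space is too fragmented for the natural duration
            while length >= 2:
                placed_here = False
                for _ in range(200):
                    start = int(rng.integers(0, T - length + 1))
                    if not occupied[start:start + length].any():
                        occupied[start:start + length] = True
                        segments.append((act, start, start + length))
                        placed_any = placed_here = True
                        break
                if placed_here:
                    break
                length //= 2
        if not placed_any:
            raise ValueError(f"could not place any segment for activity {act}; duration too short")
    return sorted(segments, key=lambda s: s[1])


def _render_segment(rng, template, length, rate, gain, separability):
    """Return an (3, length) additive signal for one segment."""
    t = np.arange(length) / rate
    out = np.zeros((3, length))
    scale = gain * separability
    if template.kind == "oscillation":
        freq = template.frequency * rng.uniform(0.9, 1.1)
        # raised amplitude envelope: the oscillation builds up and dies down
        # over `attack` seconds, so segment-edge windows carry a weaker signal
        attack = max(template.attack, 1.0 / rate)
        ramp = np.minimum(1.0, np.minimum(t, t[::-1]) / attack) if length > 1 else np.ones(1)
        for ax in range(3):
            out[ax] = scale * template.amplitudes[ax] * np.sin(2 * np.pi * freq * t + template.phases[ax]) * ramp
    else:
        bump = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(length) / max(length - 1, 1)))
        out[template.axis] = scale * template.delta * bump
    return out


def generate_recording(config: SynthConfig, subject_id: int = 0) -> Recording:
    """One subject's recording: ``(O, T)`` signals plus exact annotations.

    Deterministic for a given ``(config.seed, subject_id)`` pair.  The null
    background is zero-mean Gaussian noise; activity segments are inserted
    at random non-overlapping positions with the per-class templates.
    """
    rng = np.random.default_rng([config.seed, subject_id])
    rate = config.sample_rate
    T = int(round(config.duration * rate))
    gain = rng.uniform(*config.subject_gain)
    offset = rng.uniform(*config.subject_offset, size=3)

    acc = rng.normal(0.0, config.noise_sd, size=(3, T)) + offset[:, None]
    annotations = np.zeros(T, dtype=int)
    segments = _place_segments(rng, T, rate, config)
    for act, start, end in segments:
        acc[:, start:end] += _render_segment(
            rng, config.palette[act], end - start, rate, gain, config.separability
        )
        annotations[start:end] = act

    if config.channels == 6:
        gyro = np.zeros((3, T))
        gyro[:, 1:] = np.diff(acc, axis=1) * rate * config.gyro_scale / (2 * np.pi)
        gyro += rng.normal(0.0, config.noise_sd, size=(3, T))
        signals = np.vstack([acc, gyro])
    else:
        signals = acc

    ann_segments = [(act, start, end) for act, start, end in segments]
    return Recording(
        signals=signals, sample_rate=rate, annotations=ann_segments,
        subject_id=subject_id, experiment_id=subject_id,
    )


def generate_recordings(config: SynthConfig, n_subjects: int = 3) -> list:
    return [generate_recording(config, sid) for sid in range(1, n_subjects + 1)]


def generate_benchmark(
    config: SynthConfig,
    n_subjects: int = 3,
    target_activity: int = WALK,
    window_len: int = 64,
    stride: int = 32,
    threshold: float = 0.75,
    for_quantization: bool = True,
) -> WindowedDataset:
    """Compose recordings over subjects into a labeled window dataset.

    Windows contain raw signal values; when ``for_quantization`` is set the
    raw cut is one sample longer than ``window_len`` so that the ternary
    transform (applied later, with thresholds fitted on the training split
    only) yields windows of exactly ``window_len`` symbols.
    """
    l_raw = window_len + 1 if for_quantization else window_len
    parts = []
    for rec in generate_recordings(config, n_subjects):
        parts.append(
            make_windows(
                rec.signals, rec.annotation_array(), l_raw, stride,
                target_activity=target_activity, threshold=threshold,
                subject=rec.subject_id,
            )
        )
    return concat_datasets(parts)
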