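"""Genetic-mutation training-set augmentation.

Activity-of-interest windows are rare in continuously recorded inertial
data, so the training split is rebalanced by synthesizing extra positive
windows: for every positive window, K mutated copies are added, each
obtained by moving the signal at one randomly chosen (sample, channel)
position to a randomly chosen *different* quantization level at most M
levels away.  Ternary windows mutate on the {-1, 0, +1} alphabet (clipped);
continuous windows mutate on a uniform level grid of configurable spacing.
Mutated copies are labeled positive and tagged with their lineage; negative
windows and the test split are never touched (augmenting test data raises).

An alternative reading -- one mutated copy per positive window with K
mutated positions -- is available via ``mode="positions"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import WindowedDataset, concat_datasets

__all__ = ["AugmentConfig", "mutate_window", "augment_dataset", "is_ternary"]

TERNARY_LEVELS = np.array([-1.0, 0.0, 1.0])


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation settings.

    K : int or None
        Mutated windows generated per positive window.  ``None`` picks the
        smallest K that brings the positive class to roughly half of the
        training split.
    M : int
        Maximum mutation extent in quantization levels (>= 1).
    level_spacing : float or None
        Grid spacing for mutating continuous (non-quantized) windows;
        ``None`` uses a quarter of the per-channel standard deviation of
        the dataset being augmented.
    mode : str
        ``"copies"`` (default): K copies, one mutated position each.
        ``"positions"``: one copy with K mutated positions.
    """

    K: int | None = None
    M: int = 1
    level_spacing: float | None = None
    seed: int = 0
    mode: str = "copies"

    def __post_init__(self) -> None:
        if self.K is not None and self.K < 0:
            raise ValueError("K must be nonnegative")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.level_spacing is not None and self.level_spacing <= 0:
            raise ValueError("level_spacing must be positive")
        if self.mode not in ("copies", "positions"):
            raise ValueError("mode must be 'copies' or 'positions'")


def is_ternary(window: np.ndarray) -> bool:
    return bool(np.all(np.isin(window, TERNARY_LEVELS)))


def _mutate_at(window, idx, ch, M, rng, ternary, spacing):
    """Replace window[ch, idx] by a different level within +/- M levels."""
    orig = window[ch, idx]
    if ternary:
        lo = max(-1.0, orig - M)
        hi = min(1.0, orig + M)
        candidates = TERNARY_LEVELS[(TERNARY_LEVELS >= lo) & (TERNARY_LEVELS <= hi)]
        candidates = candidates[candidates != orig]
        if candidates.size == 0:
            raise ValueError("degenerate single-level alphabet: no neighboring level to mutate to")
        window[ch, idx] = rng.choice(candidates)
    else:
        offsets = np.concatenate([np.arange(-M, 0), np.arange(1, M + 1)])
        window[ch, idx] = orig + int(rng.choice(offsets)) * spacing[ch]


def mutate_window(
    window: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
    level_spacing: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Generate K mutated copies of one ``(O, l)`` window.

    In the default ``copies`` mode every returned copy differs from the
    original at exactly one uniformly chosen (channel, sample) position
    (Hamming distance 1); the original is never modified.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("window is empty")
    n_channels, length = window.shape
    k = config.K if config.K is not None else 0
    ternary = is_ternary(window)
    if level_spacing is None:
        if config.level_spacing is not None:
            spacing = np.full(n_channels, config.level_spacing)
        else:
            std = window.std(axis=1)
            spacing = np.where(std > 0, std / 4.0, 1.0)
    else:
        spacing = np.broadcast_to(np.asarray(level_spacing, dtype=float), (n_channels,))

    copies: list[np.ndarray] = []
    if config.mode == "copies":
        for _ in range(k):
            copy = window.copy()
            ch = int(rng.integers(n_channels))
            idx = int(rng.integers(length))
            _mutate_at(copy, idx, ch, config.M, rng, ternary, spacing)
            copies.append(copy)
    else:  # one copy, k distinct mutated positions
        if k > 0:
            copy = window.copy()
            flat = rng.choice(n_channels * length, size=min(k, n_channels * length), replace=False)
            for pos in flat:
                _mutate_at(copy, int(pos % length), int(pos // length), config.M, rng, ternary, spacing)
            copies.append(copy)
    return copies


def _auto_K(n_pos: int, n_neg: int) -> int:
    # smallest K with (1+K)*n_pos >= n_neg, i.e. positives ~ half the split
    if n_pos == 0:
        return 0
    return max(0, int(np.ceil((n_neg - n_pos) / n_pos)))


def augment_dataset(dataset: WindowedDataset, config: AugmentConfig) -> WindowedDataset:
    """Append K mutated, positively labeled copies of every positive window.

    Deterministic given ``config.seed``; negative windows pass through
    untouched.  Output size = input size + K * (number of positives).

    Raises
    ------
    ValueError
        If the dataset is tagged as a test split -- augmentation belongs to
        training only and never to testing or inference.
    """
    if dataset.role == "test":
        raise ValueError("augmentation must not be applied to the test split")
    n_pos = int(np.sum(dataset.labels == 1))
    n_neg = len(dataset) - n_pos
    k = config.K if config.K is not None else _auto_K(n_pos, n_neg)
    effective = replace(config, K=k)
    if k == 0 or n_pos == 0:
        return dataset

    spacing = None
    if not is_ternary(dataset.windows):
        if config.level_spacing is not None:
            spacing = np.full(dataset.n_channels, config.level_spacing)
        else:
            flat = dataset.windows.transpose(1, 0, 2).reshape(dataset.n_channels, -1)
            std = flat.std(axis=1)
            spacing = np.where(std > 0, std / 4.0, 1.0)

    rng = np.random.default_rng(config.seed)
    new_windows, new_meta = [], []
    for i in np.flatnonzero(dataset.labels == 1):
        for copy in mutate_window(dataset.windows[i], effective, rng, level_spacing=spacing):
            new_windows.append(copy)
            new_meta.append((dataset.fractions[i], dataset.subjects[i], dataset.activities[i]))
    if not new_windows:
        return dataset
    addition = WindowedDataset(
        windows=np.stack(new_windows),
        labels=np.ones(len(new_windows), dtype=int),
        fractions=np.array([m[0] for m in new_meta]),
        subjects=np.array([m[1] for m in new_meta], dtype=int),
        activities=np.array([m[2] for m in new_meta], dtype=int),
        origins=np.array(["mutated"] * len(new_windows), dtype=object),
        target_activity=dataset.target_activity,
        threshold=dataset.threshold,
        role=dataset.role,
    )
    return concat_datasets([dataset, addition])
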