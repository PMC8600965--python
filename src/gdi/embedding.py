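"""Window embedding: from raw series to the paired sample blocks of the
two mutual-information problems behind every directed-information value.

For a source channel j, a target channel k and a conditioning set Z, the
conditional MI is estimated as a difference of two MI terms.  Both share
the same A block (the M past samples of j); the first B block contains the
current value of k followed by the M past samples of k and of every
conditioning channel, the second drops the current value.  Samples are
non-overlapping windows of length M+1, anchored at the start of the
series; within a window the first M values are "past" and the last one is
"current".  Independence surrogates are obtained by permuting the rows of
the A block only, which preserves both marginals exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .timeseries import TimeSeriesSet

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "SamplePairSet",
    "build_mi_problems",
    "embed_windows",
    "permute_block",
]


@dataclass
class EmbeddingConfig:
    """Memory length and channel roles for one directed edge.

    ``M`` past samples per channel; ``source`` and ``target`` are channel
    indices; ``conditioning`` is a collection of further channel indices
    (possibly empty) whose pasts are conditioned on.
    """

    M: int
    target: int
    source: int
    conditioning: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.conditioning = tuple(self.conditioning)
        if self.M < 1:
            raise ValueError("memory M must be >= 1")
        if self.source == self.target:
            raise ValueError("source and target must differ")
        if self.source in self.conditioning or self.target in self.conditioning:
            raise ValueError("conditioning set may not contain source or target")
        if len(set(self.conditioning)) != len(self.conditioning):
            raise ValueError("conditioning set has duplicates")


@dataclass
class SamplePairSet:
    """Paired joint/shuffled sample blocks feeding the ratio classifier.

    ``joint`` holds one row per window drawn from the dependent
    distribution p; ``shuffled`` differs only by a row permutation of the
    A-block columns (``block_index``), simulating the independence
    surrogate q.
    """

    joint: np.ndarray
    shuffled: np.ndarray
    block_index: np.ndarray  # column indices of the A block

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        self.shuffled = np.asarray(self.shuffled, dtype=float)
        self.block_index = np.asarray(self.block_index, dtype=int)
        if self.joint.shape != self.shuffled.shape:
            raise ValueError("joint and shuffled must have identical shape")

    @property
    def n_windows(self) -> int:
        return self.joint.shape[0]

    @property
    def b_index(self) -> np.ndarray:
        """Column indices of the B block (complement of the A block)."""
        mask = np.ones(self.joint.shape[1], dtype=bool)
        mask[self.block_index] = False
        return np.nonzero(mask)[0]


def embed_windows(series: TimeSeriesSet, M: int) -> np.ndarray:
    """Cut the series into non-overlapping windows of length M+1.

    Returns an array of shape ``(n_windows, M+1, R)``; a trailing remainder
    shorter than M+1 samples is discarded.
    """
    T, R = series.values.shape
    n_win = T // (M + 1)
    if n_win < 1:
        raise ValueError(f"series too short for M={M}: T={T}")
    return series.values[: n_win * (M + 1)].reshape(n_win, M + 1, R)


def permute_block(joint: np.ndarray, block_index: np.ndarray, seed) -> np.ndarray:
    """Permute the A-block rows of ``joint`` with a seeded uniform shuffle.

    Columns outside ``block_index`` are untouched, so every column's
    empirical distribution is preserved exactly.  ``seed`` may be an int or
    a :class:`numpy.random.Generator`.
    """
    joint = np.asarray(joint)
    if joint.shape[0] < 2:
        raise ValueError("need at least 2 rows to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(joint.shape[0])
    shuffled = joint.copy()
    shuffled[:, block_index] = joint[perm][:, block_index]
    return shuffled


def build_mi_problems(
    series: TimeSeriesSet, cfg: EmbeddingConfig, seed=0
) -> tuple[SamplePairSet, SamplePairSet]:
    """Assemble the two MI problems whose difference is the conditional DI.

    Both problems share the A block (past of the source).  Problem 1's B
    block is ``[target current, target past, conditioning pasts]``;
    problem 2 drops the target's current value.  The returned shuffled
    blocks use one seeded permutation; estimators re-permute per bootstrap
    iteration via :func:`permute_block`.
    """
    for ch in (cfg.source, cfg.target, *cfg.conditioning):
        if not 0 <= ch < series.n_channels:
            raise ValueError(f"channel index {ch} out of range")
    T = series.n_samples
    if T < 2 * (cfg.M + 1):
        raise ValueError(
            f"insufficient data: T={T} gives fewer than 2 windows of length {cfg.M + 1}"
        )
    wins = embed_windows(series, cfg.M)
    n_win = wins.shape[0]
    if n_win < 50:
        warnings.warn(f"only {n_win} windows available; estimates will be noisy",
                      stacklevel=2)

    a = wins[:, : cfg.M, cfg.source]                      # (n, M)
    cur = wins[:, cfg.M, cfg.target][:, None]             # (n, 1)
    past_cols = [wins[:, : cfg.M, cfg.target]]
    past_cols += [wins[:, : cfg.M, c] for c in cfg.conditioning]
    pasts = np.concatenate(past_cols, axis=1)             # (n, M*(1+|Z|))

    joint1 = np.concatenate([a, cur, pasts], axis=1)
    joint2 = np.concatenate([a, pasts], axis=1)
    a_idx = np.arange(cfg.M)

    rng = np.random.default_rng(seed)
    pair1 = SamplePairSet(joint1, permute_block(joint1, a_idx, rng), a_idx)
    pair2 = SamplePairSet(joint2, permute_block(joint2, a_idx, rng), a_idx)
    return pair1, pair2
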