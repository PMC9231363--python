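"""Block structure and epoched-dataset containers.

A P300 feature vector concatenates the time samples of every channel
(channel-major), so the weight vector of a linear decoder naturally splits
into one contiguous block per channel.  :class:`BlockStructure` records that
partition; :class:`EpochDataset` bundles the stimulus-by-feature matrix with
its binary target/non-target labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BlockStructure:
    """Partition of a flattened weight vector into per-channel blocks.

    Parameters
    ----------
    block_sizes : tuple of int
        Number of coordinates in each block (the number of time points per
        channel; equal for all blocks in the speller application, but the
        container permits ragged blocks).
    """

    block_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.block_sizes)
        if len(sizes) == 0 or any(s <= 0 for s in sizes):
            raise ValueError("block_sizes must be positive integers")
        object.__setattr__(self, "block_sizes", sizes)

    @classmethod
    def uniform(cls, n_blocks: int, block_size: int) -> "BlockStructure":
        return cls((int(block_size),) * int(n_blocks))

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def n_features(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def offsets(self) -> np.ndarray:
        """Start index of each block in the flattened vector."""
        return np.concatenate(([0], np.cumsum(self.block_sizes)[:-1])).astype(int)

    def block_slice(self, b: int) -> slice:
        off = self.offsets
        return slice(int(off[b]), int(off[b] + self.block_sizes[b]))

    def feature_indices(self, blocks) -> np.ndarray:
        """Flat feature indices covered by the given block indices."""
        idx = [np.arange(self.block_slice(b).start, self.block_slice(b).stop)
               for b in blocks]
        if not idx:
            return np.empty(0, dtype=int)
        return np.concatenate(idx)


def _coerce_labels(labels: np.ndarray) -> np.ndarray:
    """Map {1, 0} labels to {+1, -1}; pass {+1, -1} through unchanged."""
    labels = np.asarray(labels, dtype=float).ravel()
    vals = set(np.unique(labels).tolist())
    if vals <= {1.0, -1.0}:
        return labels
    if vals <= {0.0, 1.0}:
        return np.where(labels > 0, 1.0, -1.0)
    raise ValueError(f"labels must be in {{+1,-1}} or {{1,0}}, got values {sorted(vals)}")


@dataclass
class EpochDataset:
    """Labeled feature matrix with explicit per-channel block structure.

    ``features`` has one row per stimulus and ``D = n_channels * n_times``
    columns ordered channel-major (all time points of channel 0, then
    channel 1, ...).  ``labels`` are +1 for target stimuli and -1 otherwise;
    {1, 0} input is coerced.  Optional speller metadata (``codes``,
    ``trial``, ``epoch``) aligns rows with the 6x6 row/column paradigm.
    """

    features: np.ndarray
    labels: np.ndarray
    structure: BlockStructure
    channel_names: list[str]
    sampling_rate: float | None = None
    codes: np.ndarray | None = None
    trial: np.ndarray | None = None
    epoch: np.ndarray | None = None
    true_chars: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n_stimuli, n_features)")
        self.labels = _coerce_labels(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("feature row count must equal label length")
        if self.features.shape[1] != self.structure.n_features:
            raise ValueError(
                f"features have {self.features.shape[1]} columns but the block "
                f"structure covers {self.structure.n_features}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if len(self.channel_names) != self.structure.n_blocks:
            raise ValueError("one channel name required per block")
        for name in ("codes", "trial", "epoch"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=int).ravel()
                if arr.shape[0] != self.features.shape[0]:
                    raise ValueError(f"{name} must align with feature rows")
                setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.structure.n_blocks

    @property
    def n_times(self) -> int:
        return self.structure.block_sizes[0]
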