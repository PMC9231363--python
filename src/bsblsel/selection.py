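"""Turning a fitted BSBL model into channel subsets.

Automatic selection keeps the channels whose final gamma exceeds the shear
threshold; the per-channel importance score is the sum of absolute
posterior-mean weights over the channel's time points.  Fixed-M selection
ranks by importance and, when fewer than M channels survived pruning, backs
fill with the most recently pruned channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockStructure
from .bsbl import EMFitResult

__all__ = ["SelectionResult", "select_auto", "channel_importance",
           "select_top_m", "baseline_auto_threshold"]


@dataclass
class SelectionResult:
    """Selected channels with importances and sparse weights.

    ``weights`` is the full-length (D,) posterior-mean weight vector, zero
    outside the selected channels' coordinates.  ``removal_order`` lists
    channels in the order the EM loop pruned them (earliest first).
    """

    selected: list[int]
    importance: np.ndarray
    weights: np.ndarray
    removal_order: list[int]
    structure: BlockStructure

    def __post_init__(self) -> None:
        if set(self.selected) & set(self.removal_order):
            raise ValueError("a channel cannot be both selected and pruned")
        if len(self.importance) != self.structure.n_blocks:
            raise ValueError("importance must have one entry per channel")

    def restricted(self, channels) -> "SelectionResult":
        """Copy of this result keeping only the given channels selected."""
        channels = sorted(int(c) for c in channels)
        weights = np.zeros_like(self.weights)
        for c in channels:
            s = self.structure.block_slice(c)
            weights[s] = self.weights[s]
        removal = [c for c in self.removal_order if c not in set(channels)]
        return SelectionResult(selected=channels, importance=self.importance,
                               weights=weights, removal_order=removal,
                               structure=self.structure)

    def table(self):
        """Per-channel summary (importance, selected flag, removal rank)."""
        import pandas as pd
        n = self.structure.n_blocks
        rank = {c: i for i, c in enumerate(self.removal_order)}
        return pd.DataFrame({
            "channel": np.arange(n),
            "importance": self.importance,
            "selected": np.isin(np.arange(n), self.selected),
            "removal_rank": [rank.get(c, -1) for c in range(n)],
        })


def channel_importance(weights: np.ndarray,
                       structure: BlockStructure) -> np.ndarray:
    """Per-channel score: sum of |w| over the channel's coordinates."""
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != structure.n_features:
        raise ValueError("weights must cover the full feature vector")
    return np.array([np.sum(np.abs(weights[structure.block_slice(b)]))
                     for b in range(structure.n_blocks)])


def select_auto(result: EMFitResult, tau: float) -> SelectionResult:
    """Channels with final gamma > tau, weighted by the posterior mean."""
    hyper = result.hyper
    structure = result.structure
    selected = [int(b) for b in range(structure.n_blocks)
                if hyper.gamma[b] > tau]
    if not selected:
        raise ValueError(
            "automatic selection is empty; decrease tau (all gamma <= tau)")
    weights = np.zeros(structure.n_features)
    active = list(hyper.active_blocks)
    pos = 0
    for b in active:
        d = structure.block_sizes[b]
        if b in selected:
            weights[structure.block_slice(b)] = result.posterior.mu[pos:pos + d]
        pos += d
    removal = [c for c in result.removal_order if c not in set(selected)]
    return SelectionResult(selected=selected,
                           importance=channel_importance(weights, structure),
                           weights=weights, removal_order=removal,
                           structure=structure)


def select_top_m(result: SelectionResult, m: int) -> list[int]:
    """Top-M channels by importance, with last-pruned-first backfill.

    If at least M channels were selected, the M with the largest importance
    are returned (ties toward the lower channel index).  If only M' < M
    survived, all of them are kept and the most recently pruned M - M'
    channels are added back in reverse pruning order.
    """
    n_ch = result.structure.n_blocks
    if not 1 <= m <= n_ch:
        raise ValueError(f"M must lie in [1, {n_ch}]")
    sel = list(result.selected)
    if len(sel) >= m:
        order = sorted(sel, key=lambda c: (-result.importance[c], c))
        return sorted(order[:m])
    backfill = list(reversed(result.removal_order))[:m - len(sel)]
    if len(sel) + len(backfill) < m:
        raise ValueError("not enough pruned channels to backfill to M")
    return sorted(sel + backfill)


def baseline_auto_threshold(importance: np.ndarray) -> list[int]:
    """Dense-weight baseline rule: keep channels above mean - 0.5 * std.

    Intended for LASSO/SBL-style methods whose weights never become exactly
    block-sparse; the threshold is computed over the importance values
    themselves.
    """
    importance = np.asarray(importance, dtype=float).ravel()
    std = importance.std()
    if std == 0:  # constant scores carry no ranking: keep everything
        return list(range(importance.size))
    thr = importance.mean() - 0.5 * std
    return [int(i) for i in np.flatnonzero(importance > thr)]
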