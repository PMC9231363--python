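"""End-to-end P300 speller processing.

Covers the surrounding machinery of a channel-selection experiment:
band-pass filtering + decimation + epoching of continuous recordings,
row/column evidence accumulation into characters, character recognition
accuracy, cross-validated choice of the shear threshold tau, and the
Wilcoxon signed-rank comparison of per-participant accuracy tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .blocks import BlockStructure, EpochDataset
from .blda import BLDA
from .bsbl import RegionalBSBL
from .regions import RegionMap

__all__ = ["SpellerLayout", "preprocess", "decode_character", "decode_session",
           "accuracy", "crossvalidate_tau", "compare_methods"]

ROW_CODES = tuple(range(1, 7))     # codes 1..6  -> rows 0..5
COL_CODES = tuple(range(7, 13))    # codes 7..12 -> columns 0..5


@dataclass(frozen=True)
class SpellerLayout:
    """6x6 character grid and the stimulus-code convention.

    Codes 1..6 flash rows 0..5 and codes 7..12 flash columns 0..5; every
    character is addressed by exactly one (row, column) pair.
    """

    grid: tuple[str, ...]  # 6 strings of 6 characters

    def __post_init__(self) -> None:
        if len(self.grid) != 6 or any(len(r) != 6 for r in self.grid):
            raise ValueError("layout must be a 6x6 grid")
        flat = "".join(self.grid)
        if len(set(flat)) != 36:
            raise ValueError("grid characters must be unique")

    @classmethod
    def default(cls) -> "SpellerLayout":
        """The classic 26-letter + 10-digit matrix."""
        return cls(("ABCDEF", "GHIJKL", "MNOPQR", "STUVWX", "YZ0123", "456789"))

    def char_at(self, row: int, col: int) -> str:
        return self.grid[row][col]

    def codes_for_char(self, ch: str) -> tuple[int, int]:
        """(row code, column code) addressing the character."""
        for r, line in enumerate(self.grid):
            c = line.find(ch)
            if c >= 0:
                return ROW_CODES[r], COL_CODES[c]
        raise KeyError(f"character {ch!r} not in layout")


def preprocess(raw: np.ndarray, sampling_rate: float, onsets, labels=None,
               codes=None, band=(0.5, 20.0), decim: int = 5,
               window=(0.0, 0.667), channel_names=None) -> EpochDataset:
    """Filter, decimate and epoch a continuous multichannel recording.

    ``raw`` is (n_channels, n_samples); ``onsets`` are stimulus onset sample
    indices at the original rate.  The signal is band-pass filtered with a
    zero-phase 4th-order Butterworth (which also anti-aliases, given the
    upper band edge sits below the post-decimation Nyquist), decimated by an
    integer factor, and windows of ``[window[0], window[1])`` seconds after
    each onset are extracted and flattened channel-major.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw must be (n_channels, n_samples)")
    n_ch, n_samp = raw.shape
    fs_out = sampling_rate / decim
    if band[1] >= fs_out / 2:
        raise ValueError(
            f"band edge {band[1]} Hz is not below the post-decimation "
            f"Nyquist {fs_out / 2} Hz; decrease decim or the band")
    sos = sps.butter(4, band, btype="bandpass", fs=sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, raw, axis=1)
    dec = filtered[:, ::decim]

    n_t = int(round((window[1] - window[0]) * fs_out))
    start_off = int(round(window[0] * fs_out))
    onsets = np.asarray(onsets, dtype=int)
    rows = np.empty((onsets.size, n_ch * n_t))
    for i, onset in enumerate(onsets):
        s = onset // decim + start_off
        if s < 0 or s + n_t > dec.shape[1]:
            raise ValueError(
                f"window for stimulus {i} (samples [{s}, {s + n_t})) exceeds "
                "the record")
        rows[i] = dec[:, s:s + n_t].ravel()
    if labels is None:
        labels = np.full(onsets.size, -1.0)
    if channel_names is None:
        channel_names = [f"ch{i:02d}" for i in range(n_ch)]
    return EpochDataset(features=rows, labels=labels,
                        structure=BlockStructure.uniform(n_ch, n_t),
                        channel_names=list(channel_names),
                        sampling_rate=fs_out,
                        codes=None if codes is None else np.asarray(codes))


def decode_character(scores: np.ndarray, codes: np.ndarray,
                     epochs: np.ndarray, layout: SpellerLayout,
                     n_epochs_used: int | None = None) -> str:
    """Accumulate classifier scores of one trial into a character.

    Scores are summed per stimulus code over the first ``n_epochs_used``
    epochs; the predicted character sits at (argmax row code, argmax column
    code), ties broken toward the lower code index.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    codes = np.asarray(codes, dtype=int).ravel()
    epochs = np.asarray(epochs, dtype=int).ravel()
    use_eps = sorted(set(epochs.tolist()))
    if n_epochs_used is not None:
        use_eps = use_eps[:n_epochs_used]
    totals = {c: 0.0 for c in range(1, 13)}
    for ep in use_eps:
        m = epochs == ep
        seen = codes[m]
        if sorted(seen.tolist()) != list(range(1, 13)):
            raise ValueError(f"epoch {ep} does not contain each of the 12 "
                             "codes exactly once")
        for c, s in zip(seen, scores[m]):
            totals[c] += s
    row_idx = int(np.argmax([totals[c] for c in ROW_CODES]))
    col_idx = int(np.argmax([totals[c] for c in COL_CODES]))
    return layout.char_at(row_idx, col_idx)


def decode_session(scores: np.ndarray, dataset: EpochDataset,
                   layout: SpellerLayout | None = None,
                   n_epochs_used: int | None = None) -> list[str]:
    """Decode every trial of a session dataset carrying codes/trial/epoch."""
    if dataset.codes is None or dataset.trial is None or dataset.epoch is None:
        raise ValueError("dataset lacks speller metadata (codes/trial/epoch)")
    layout = layout or SpellerLayout.default()
    out = []
    for t in sorted(set(dataset.trial.tolist())):
        m = dataset.trial == t
        out.append(decode_character(scores[m], dataset.codes[m],
                                    dataset.epoch[m], layout, n_epochs_used))
    return out


def accuracy(predicted, true) -> float:
    """Character recognition accuracy in percent: 100 * correct / total."""
    predicted, true = list(predicted), list(true)
    if len(predicted) != len(true):
        raise ValueError("sequences must have equal length")
    if not true:
        raise ValueError("empty character sequences")
    correct = sum(p == t for p, t in zip(predicted, true))
    return 100.0 * correct / len(true)


def crossvalidate_tau(data: EpochDataset, regions: RegionMap | None,
                      tau_grid, k: int = 10, seed: int = 0,
                      b_mode: str = "regional", max_iter: int = 200):
    """Pick the shear threshold by stratified k-fold cross-validation.

    For each tau, channel selection is fitted on the training folds, a BLDA
    classifier is trained on the selected channels' features, and validation
    stimuli are scored by target/non-target ROC AUC.  The best tau maximises
    the mean validation score; ties go to the larger tau (fewer channels).
    Returns ``(best_tau, table)`` with the per-fold score table.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    tau_grid = sorted(float(t) for t in tau_grid)
    if any(not 0 < t < 1 for t in tau_grid):
        raise ValueError("tau grid must lie in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    rows = []
    X, y = data.features, data.labels
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError(f"fold {fold} lacks both classes; reduce k")
        for tau in tau_grid:
            sel = RegionalBSBL(n_times=data.n_times, regions=regions, tau=tau,
                               b_mode=b_mode, max_iter=max_iter)
            sel.fit(X[tr], y[tr])
            clf = BLDA().fit(sel.transform(X[tr]), y[tr])
            score = roc_auc_score(y[va], clf.decision_function(
                sel.transform(X[va])))
            rows.append({"fold": fold, "tau": tau, "auc": float(score),
                         "n_selected": len(sel.selected_channels_)})
    table = pd.DataFrame(rows)
    means = table.groupby("tau")["auc"].mean()
    best = max(tau_grid, key=lambda t: (round(means[t], 12), t))
    return best, table


def compare_methods(acc_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank tests between methods.

    ``acc_table`` has one row per participant and one column per method.
    Returns a table of (method_a, method_b, p_value, significant).  With
    fewer than six paired observations the test has little power; a warning
    is emitted.  All-zero differences yield p = 1.
    """
    if acc_table.shape[0] < 6:
        warnings.warn("fewer than 6 paired observations; the signed-rank "
                      "test has very low power", UserWarning, stacklevel=2)
    cols = list(acc_table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            diff = np.asarray(acc_table[a] - acc_table[b], dtype=float)
            if np.allclose(diff, 0):
                warnings.warn(f"all differences between {a!r} and {b!r} are "
                              "zero; p set to 1", UserWarning, stacklevel=2)
                p = 1.0
            else:
                p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
            rows.append({"method_a": a, "method_b": b, "p_value": p,
                         "significant": p < alpha})
    return pd.DataFrame(rows)
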