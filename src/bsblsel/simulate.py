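"""Synthetic fixtures with ground truth.

Two generators:

* :func:`gen_block_sparse` draws regression instances straight from the
  block-sparse prior (active blocks get AR(1)-correlated Gaussian weights),
  giving an exact planted support for recovery tests.

* :func:`gen_p300_session` simulates a 6x6 row/column speller session in the
  oddball paradigm: each epoch flashes the 12 row/column codes once in random
  order; the two codes containing the attended character are targets (1:5
  target ratio) and receive a smooth ERP bump on a planted subset of
  channels, on top of temporally correlated AR(1) channel noise.  Amplitudes
  decay smoothly over the montage from the centroid of the informative set,
  so regional smoothing has real spatial structure to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .blocks import BlockStructure, EpochDataset
from .regions import Montage, standard_montage

__all__ = ["BlockSparseSpec", "P300SimSpec", "gen_block_sparse",
           "gen_p300_session"]

DEFAULT_INFORMATIVE = ("Pz", "P3", "P4", "POz", "PO7", "PO8", "O1", "O2")


@dataclass
class BlockSparseSpec:
    """Parameters of a planted block-sparse regression instance.

    The defaults (40 blocks of 8 points, 8 active, N = 500 at 10 dB SNR)
    give a well-posed but non-trivial recovery problem.  ``sigma2`` may pin
    the noise variance directly; otherwise it is derived from ``snr_db``.
    """

    n_blocks: int = 40
    block_size: int = 8
    n_active_blocks: int = 8
    r_true: float = 0.8
    gamma_scale: float = 1.0
    snr_db: float = 10.0
    sigma2: float | None = None
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_active_blocks <= self.n_blocks:
            raise ValueError("n_active_blocks must lie in [0, n_blocks]")
        if not abs(self.r_true) < 1:
            raise ValueError("|r_true| must be < 1")
        if self.n_samples < 1 or self.block_size < 1:
            raise ValueError("n_samples and block_size must be positive")


def gen_block_sparse(spec: BlockSparseSpec):
    """Draw (dataset, truth) from the block-sparse generative model.

    Active-block weights ~ N(0, gamma_scale * Toeplitz(r_true)); X has iid
    standard-normal entries; y = X w + eps with eps ~ N(0, sigma2 I).
    Returns the :class:`EpochDataset` and a truth dict with ``w_true``,
    ``support`` (sorted active block indices) and ``sigma2``.
    """
    rng = np.random.default_rng(spec.seed)
    structure = BlockStructure.uniform(spec.n_blocks, spec.block_size)
    D = structure.n_features
    support = np.sort(rng.choice(spec.n_blocks, size=spec.n_active_blocks,
                                 replace=False))
    B_true = spec.gamma_scale * toeplitz(spec.r_true ** np.arange(spec.block_size))
    L = np.linalg.cholesky(B_true)
    w = np.zeros(D)
    for b in support:
        w[structure.block_slice(int(b))] = L @ rng.standard_normal(spec.block_size)
    X = rng.standard_normal((spec.n_samples, D))
    signal = X @ w
    if spec.sigma2 is not None:
        sigma2 = float(spec.sigma2)
    elif spec.n_active_blocks == 0:
        sigma2 = 1.0
    else:
        power = float(signal @ signal) / spec.n_samples
        sigma2 = power / 10 ** (spec.snr_db / 10)
    y = signal + (np.sqrt(sigma2) * rng.standard_normal(spec.n_samples)
                  if sigma2 > 0 else 0.0)
    # regression targets stand in for labels here; bypass the +/-1 coercion
    ds = EpochDataset.__new__(EpochDataset)
    ds.features = X
    ds.labels = np.asarray(y, dtype=float)
    ds.structure = structure
    ds.channel_names = [f"blk{b:02d}" for b in range(spec.n_blocks)]
    ds.sampling_rate = None
    ds.codes = ds.trial = ds.epoch = None
    ds.true_chars = None
    ds.meta = {"generator": "block_sparse", "seed": spec.seed}
    truth = {"w_true": w, "support": support.astype(int), "sigma2": sigma2}
    return ds, truth


@dataclass
class P300SimSpec:
    """Parameters of a simulated P300 speller session.

    Defaults emulate a desk-scale lab session: 59-channel cap, 8 informative
    parieto-occipital channels, 18 characters x 8 epochs (1728 stimuli at
    the oddball 1:5 target ratio), 0.625-s epochs at 32 Hz (20 points per
    channel), AR(1) channel noise and a 300-ms Gaussian ERP bump whose peak
    (0.4) sits below the noise floor (0.5) -- single-trial P300s are weaker
    than the background EEG.  ``n_distractors`` turns that many
    uninformative channels into high-noise distractors (noise scaled by
    ``distractor_scale``).
    """

    n_channels: int = 59
    montage: Montage | None = None
    informative_channels: tuple[str, ...] = DEFAULT_INFORMATIVE
    erp_amplitude: float = 0.4
    erp_latency: float = 0.3
    erp_width: float = 0.08
    erp_spatial_floor: float = 0.85
    extra_bumps: tuple[tuple[float, float, float], ...] = ()
    noise_ar: float = 0.3
    noise_sigma: float = 0.5
    n_characters: int = 18
    n_epochs_per_trial: int = 8
    sampling_rate: float = 32.0
    window: float = 0.625
    n_distractors: int = 0
    distractor_scale: float = 3.0
    seed: int = 0
    text: str | None = None

    def __post_init__(self) -> None:
        if self.n_epochs_per_trial < 1:
            raise ValueError("n_epochs_per_trial must be >= 1")
        if not abs(self.noise_ar) < 1:
            raise ValueError("|noise_ar| must be < 1")
        if self.erp_amplitude < 0:
            raise ValueError("erp_amplitude must be >= 0")
        if not 0 < self.erp_spatial_floor <= 1:
            raise ValueError("erp_spatial_floor must lie in (0, 1]")
        if not 0 <= self.erp_latency < self.window:
            raise ValueError("erp_latency must fall inside the epoch window")


def _erp_amplitudes(montage: Montage, informative: list[int], peak: float,
                    floor: float = 0.85) -> np.ndarray:
    """Spatially smooth amplitude map: Gaussian fall-off from the centroid
    of the informative set (the farthest informative channel sits at
    ``floor`` times the peak); exactly zero outside the informative set."""
    amps = np.zeros(montage.n_channels)
    if not informative or peak == 0:
        return amps
    coords = montage.coords[informative]
    centroid = coords.mean(axis=0)
    dists = np.linalg.norm(coords - centroid, axis=1)
    dmax = max(float(dists.max()), 1e-12)
    s = dmax / np.sqrt(-2 * np.log(floor))
    amps[informative] = peak * np.exp(-dists ** 2 / (2 * s ** 2))
    return amps


def _ar1_noise(rng, n_rows, n_ch, n_t, a, sigma):
    """Stationary AR(1) rows with marginal std ``sigma``: x_t = a x_{t-1} + e."""
    e = rng.standard_normal((n_rows, n_ch, n_t))
    out = np.empty_like(e)
    out[..., 0] = e[..., 0]
    for t in range(1, n_t):
        out[..., t] = a * out[..., t - 1] + np.sqrt(1 - a * a) * e[..., t]
    return sigma * out


def gen_p300_session(spec: P300SimSpec, layout=None):
    """Simulate a speller session.

    Returns ``(dataset, truth)`` where the :class:`EpochDataset` carries the
    stimulus codes, trial/epoch indices and the spelled characters, and
    ``truth`` holds the informative channel indices, their ERP amplitudes
    and the distractor indices.
    """
    from .pipeline import SpellerLayout

    layout = layout or SpellerLayout.default()
    rng = np.random.default_rng(spec.seed)
    montage = spec.montage or standard_montage(spec.n_channels)
    if montage.n_channels != spec.n_channels:
        raise ValueError("montage size does not match n_channels")
    informative = [montage.index(n) for n in spec.informative_channels]
    n_t = int(round(spec.window * spec.sampling_rate))
    tgrid = np.arange(n_t) / spec.sampling_rate
    # temporal course: unit-height main bump plus optional extra components
    # (relative amplitude, latency, width); spatial scaling comes from amps
    bumps = [(1.0, spec.erp_latency, spec.erp_width)]
    bumps += [tuple(b) for b in spec.extra_bumps]
    for _, lat, _ in bumps:
        if not 0 <= lat < spec.window:
            raise ValueError(f"bump latency {lat} outside the epoch window")
    course = np.zeros(n_t)
    for rel_amp, lat, width in bumps:
        course += rel_amp * np.exp(-(tgrid - lat) ** 2 / (2 * width ** 2))
    amps = _erp_amplitudes(montage, informative, spec.erp_amplitude,
                           spec.erp_spatial_floor)

    noise_scale = np.ones(montage.n_channels)
    distractors = np.empty(0, dtype=int)
    if spec.n_distractors:
        candidates = np.setdiff1d(np.arange(montage.n_channels), informative)
        distractors = np.sort(rng.choice(candidates, size=spec.n_distractors,
                                         replace=False))
        noise_scale[distractors] = spec.distractor_scale

    chars = list(spec.text) if spec.text else [
        layout.grid[i // 6][i % 6] for i in range(spec.n_characters)]
    if len(chars) != spec.n_characters:
        raise ValueError("text length must equal n_characters")

    n_rows = spec.n_characters * spec.n_epochs_per_trial * 12
    noise = _ar1_noise(rng, n_rows, montage.n_channels, n_t,
                       spec.noise_ar, spec.noise_sigma)
    noise *= noise_scale[None, :, None]

    codes = np.empty(n_rows, dtype=int)
    trial = np.empty(n_rows, dtype=int)
    epoch = np.empty(n_rows, dtype=int)
    labels = np.empty(n_rows, dtype=float)
    features = np.empty((n_rows, montage.n_channels * n_t))
    row = 0
    for ti, ch in enumerate(chars):
        targets = set(layout.codes_for_char(ch))
        for ep in range(spec.n_epochs_per_trial):
            order = rng.permutation(np.arange(1, 13))
            for code in order:
                sig = noise[row]
                if code in targets:
                    sig = sig + amps[:, None] * course[None, :]
                features[row] = sig.ravel()
                codes[row] = code
                trial[row] = ti
                epoch[row] = ep
                labels[row] = 1.0 if code in targets else -1.0
                row += 1

    structure = BlockStructure.uniform(montage.n_channels, n_t)
    ds = EpochDataset(features=features, labels=labels, structure=structure,
                      channel_names=list(montage.channel_names),
                      sampling_rate=spec.sampling_rate, codes=codes,
                      trial=trial, epoch=epoch, true_chars=chars,
                      meta={"generator": "p300_session", "seed": spec.seed})
    truth = {"informative": np.asarray(informative, dtype=int),
             "amplitudes": amps, "distractors": distractors,
             "erp_course": course}
    return ds, truth
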