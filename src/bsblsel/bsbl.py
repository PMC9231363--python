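"""Block-sparse Bayesian learning with regional smoothing (BSBL-EM).

The linear model is ``y = X w + eps`` with ``eps ~ N(0, sigma^2 I)`` and a
zero-mean Gaussian prior on each per-channel block of the weight vector,
``w_b ~ N(0, gamma_b * B_b)``.  ``gamma_b >= 0`` scales the relevance of
channel ``b`` (gamma_b = 0 removes the channel) and ``B_b`` is a positive
definite matrix capturing the temporal correlation of the weights within the
block, constrained to an AR(1) Toeplitz form.  Regional smoothing ties
``B_b`` across all channels of a scalp region, so spatial neighbours share
one temporal-correlation estimate.

Hyperparameters (sigma^2, gamma, B) are estimated by EM; blocks whose gamma
falls below a shear threshold ``tau`` are pruned to exactly zero (at most
``max_prune_per_iter`` per iteration), physically shrinking the model.  The
posterior of the surviving weights is computed by whichever of two
algebraically equivalent routes inverts the smaller matrix: the direct
D x D form, or the Woodbury N x N form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, toeplitz

from .blocks import BlockStructure, EpochDataset
from .regions import RegionMap

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig", "HyperState", "PosteriorState", "EMFitResult",
    "assemble_sigma0", "posterior_direct", "posterior_woodbury",
    "choose_posterior_path", "update_sigma2", "update_gamma", "update_B",
    "toeplitz_constrain", "prune", "em_fit", "RegionalBSBL",
]

B_MODES = ("identity", "shared", "per_block", "regional")


@dataclass
class FitConfig:
    """Knobs of the EM fit.

    tau : shear threshold on gamma below which a block is pruned.
    b_mode : how the intra-block matrix B is tied across blocks --
        ``identity`` (no temporal correlation), ``shared`` (one B for all
        blocks), ``per_block`` (independent B per block, no spatial
        smoothing) or ``regional`` (one B per scalp region; the proposed
        scheme).
    max_prune_per_iter : at most this many blocks are removed per iteration.
    ar_clamp : bound on |r| of the fitted AR(1) coefficient, keeping the
        Toeplitz matrix positive definite.
    """

    tau: float = 1e-3
    max_iter: int = 200
    tol: float = 1e-4
    b_mode: str = "regional"
    max_prune_per_iter: int = 5
    ar_clamp: float = 0.98
    sigma2_floor: float = 1e-10
    center_targets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 < self.ar_clamp < 1:
            raise ValueError("ar_clamp must lie in (0, 1)")
        if self.b_mode not in B_MODES:
            raise ValueError(f"b_mode must be one of {B_MODES}")
        if self.max_iter < 1 or self.max_prune_per_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter, max_prune_per_iter >= 1 and tol > 0")


@dataclass
class HyperState:
    """EM hyperparameters: per-block gamma, per-group B, noise sigma^2.

    ``group_of`` maps each block to the index of the B matrix it shares
    (a region in ``regional`` mode, everything in ``shared`` mode, itself in
    ``per_block``/``identity`` mode).  Pruned blocks have gamma exactly 0
    and ``active_mask`` False.
    """

    gamma: np.ndarray
    B: list[np.ndarray]
    sigma2: float
    active_mask: np.ndarray
    group_of: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        self.group_of = np.asarray(self.group_of, dtype=int)
        if np.any(self.gamma < 0):
            raise ValueError("gamma must be non-negative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if np.any(self.gamma[~self.active_mask] != 0):
            raise ValueError("pruned blocks must have gamma exactly 0")

    @classmethod
    def initial(cls, structure: BlockStructure, groups: np.ndarray,
                sigma2: float) -> "HyperState":
        n_groups = int(groups.max()) + 1
        sizes = structure.block_sizes
        # all blocks in a group share a block size in this application
        B = [np.eye(sizes[int(np.flatnonzero(groups == g)[0])])
             for g in range(n_groups)]
        return cls(gamma=np.ones(structure.n_blocks), B=B, sigma2=float(sigma2),
                   active_mask=np.ones(structure.n_blocks, dtype=bool),
                   group_of=groups)

    @property
    def active_blocks(self) -> np.ndarray:
        return np.flatnonzero(self.active_mask)


@dataclass
class PosteriorState:
    """Posterior mean/covariance of the active weight coordinates."""

    mu: np.ndarray
    Sigma: np.ndarray
    log_evidence: float | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("Sigma must be square and match mu")


def _groups_for_mode(b_mode: str, structure: BlockStructure,
                     regions: RegionMap | None) -> np.ndarray:
    nb = structure.n_blocks
    if b_mode in ("identity", "per_block"):
        return np.arange(nb)
    if b_mode == "shared":
        return np.zeros(nb, dtype=int)
    if regions is None:
        raise ValueError("b_mode='regional' requires a RegionMap")
    if regions.n_channels != nb:
        raise ValueError("region map does not cover the block count")
    return regions.region_of


def _active_offsets(structure: BlockStructure, active: np.ndarray) -> dict[int, slice]:
    """Block -> slice into the compacted (active-only) coordinate vector."""
    out: dict[int, slice] = {}
    pos = 0
    for b in active:
        d = structure.block_sizes[b]
        out[int(b)] = slice(pos, pos + d)
        pos += d
    return out


def assemble_sigma0(hyper: HyperState, structure: BlockStructure) -> np.ndarray:
    """Block-diagonal prior covariance over active coordinates (gamma_b * B_b)."""
    blocks = []
    for b in hyper.active_blocks:
        B = hyper.B[hyper.group_of[b]]
        d = structure.block_sizes[b]
        if B.shape != (d, d):
            raise ValueError(
                f"B for block {b} has shape {B.shape}, expected ({d}, {d})")
        blocks.append(hyper.gamma[b] * B)
    if not blocks:
        return np.zeros((0, 0))
    from scipy.linalg import block_diag
    return block_diag(*blocks)


def choose_posterior_path(n_samples: int, n_active_features: int) -> str:
    """``direct`` when N >= active D, else ``woodbury`` -- the inverted
    matrix is then never larger than min(N, D)."""
    if n_samples <= 0 or n_active_features <= 0:
        raise ValueError("counts must be positive")
    return "direct" if n_samples >= n_active_features else "woodbury"


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in input")


def posterior_direct(X: np.ndarray, y: np.ndarray, Sigma0: np.ndarray,
                     sigma2: float,
                     structure: BlockStructure | None = None) -> PosteriorState:
    """Posterior via the D x D inverse: Sigma_w = (X'X/s2 + Sigma0^-1)^-1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    _check_finite(X, y, Sigma0)
    if X.shape[1] != Sigma0.shape[0]:
        raise ValueError("X columns must match Sigma0 dimension")
    try:
        c0 = cho_factor(Sigma0, lower=True)
        Sigma0_inv = cho_solve(c0, np.eye(Sigma0.shape[0]))
    except np.linalg.LinAlgError as err:
        bad = int(np.argmin(np.diag(Sigma0)))
        blk = "" if structure is None else f" (block {np.searchsorted(structure.offsets, bad, side='right') - 1})"
        raise np.linalg.LinAlgError(
            f"Sigma0 is singular near coordinate {bad}{blk}; "
            "use the Woodbury path when some gamma_b = 0") from err
    A = X.T @ X / sigma2 + Sigma0_inv
    cA = cho_factor(A, lower=True)
    Sigma_w = cho_solve(cA, np.eye(A.shape[0]))
    Sigma_w = 0.5 * (Sigma_w + Sigma_w.T)
    mu = Sigma_w @ (X.T @ y) / sigma2
    return PosteriorState(mu=mu, Sigma=Sigma_w,
                          log_evidence=_logev_direct(X, y, Sigma0, sigma2, A, mu))


def posterior_woodbury(X: np.ndarray, y: np.ndarray, Sigma0: np.ndarray,
                       sigma2: float) -> PosteriorState:
    """Posterior via the N x N inverse; valid even when Sigma0 is singular.

    Sigma_w = Sigma0 - Sigma0 X' (s2 I + X Sigma0 X')^-1 X Sigma0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    _check_finite(X, y, Sigma0)
    n = X.shape[0]
    XS = X @ Sigma0                      # N x D
    H = sigma2 * np.eye(n) + XS @ X.T    # N x N, PD for sigma2 > 0
    cH = cho_factor(H, lower=True)
    mu = XS.T @ cho_solve(cH, y)
    Sigma_w = Sigma0 - XS.T @ cho_solve(cH, XS)
    Sigma_w = 0.5 * (Sigma_w + Sigma_w.T)
    if not np.all(np.isfinite(Sigma_w)):
        raise FloatingPointError("non-finite posterior covariance (Woodbury path)")
    ld = 2.0 * np.sum(np.log(np.diag(cH[0])))
    logev = -0.5 * (n * np.log(2 * np.pi) + ld + float(y @ cho_solve(cH, y)))
    return PosteriorState(mu=mu, Sigma=Sigma_w, log_evidence=logev)


def _logev_direct(X, y, Sigma0, sigma2, A, mu) -> float:
    """log N(y; 0, s2 I + X Sigma0 X') via determinant identities."""
    n, d = X.shape
    sign0, ld0 = np.linalg.slogdet(Sigma0)
    signA, ldA = np.linalg.slogdet(A)
    if sign0 <= 0 or signA <= 0:
        return float("nan")
    # ln|C| = ln|s2 I_N| + ln|Sigma0| + ln|A|  with A = Sigma0^-1 + X'X/s2
    ldC = n * np.log(sigma2) + ld0 + ldA
    quad = float(y @ (y - X @ mu)) / sigma2
    return -0.5 * (n * np.log(2 * np.pi) + ldC + quad)


def update_sigma2(X: np.ndarray, y: np.ndarray, posterior: PosteriorState,
                  Sigma0: np.ndarray, sigma2_old: float,
                  floor: float = 1e-10) -> float:
    """EM update of the noise variance.

    sigma^2 = (||y - X mu||^2 + sigma2_old * [D - Tr(Sigma_w Sigma0^-1)]) / N
    with D the current active feature count.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    d = Sigma0.shape[0]
    resid = y - X @ posterior.mu
    tr = float(np.trace(np.linalg.solve(Sigma0, posterior.Sigma)))
    s2 = (float(resid @ resid) + sigma2_old * (d - tr)) / n
    if s2 < floor:
        logger.warning("sigma2 update hit the floor %g (was %g)", floor, s2)
        s2 = floor
    return s2


def _block_views(posterior: PosteriorState, structure: BlockStructure,
                 active: np.ndarray):
    offs = _active_offsets(structure, active)
    mus = {b: posterior.mu[offs[b]] for b in offs}
    sigs = {b: posterior.Sigma[offs[b], offs[b]] for b in offs}
    return mus, sigs


def update_gamma(posterior: PosteriorState, hyper: HyperState,
                 structure: BlockStructure) -> np.ndarray:
    """EM update gamma_b = Tr[B_b^-1 (Sigma_w^b + mu_b mu_b')] / d_b."""
    gamma = np.zeros_like(hyper.gamma)
    mus, sigs = _block_views(posterior, structure, hyper.active_blocks)
    for b in hyper.active_blocks:
        B = hyper.B[hyper.group_of[b]]
        d = structure.block_sizes[b]
        M = sigs[b] + np.outer(mus[b], mus[b])
        try:
            gamma[b] = float(np.trace(np.linalg.solve(B, M))) / d
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular B in group {hyper.group_of[b]} (block {b})") from err
    return np.maximum(gamma, 0.0)


def update_B(posterior: PosteriorState, hyper: HyperState,
             structure: BlockStructure, gamma_new: np.ndarray,
             b_mode: str) -> list[np.ndarray]:
    """EM update of the raw (unconstrained) B matrix of each group.

    B_group = mean over the group's active blocks of
    (Sigma_w^b + mu_b mu_b') / gamma_b, using the freshly updated gamma.
    A group whose blocks are all pruned (or have zero gamma) keeps its
    previous B.
    """
    if b_mode == "identity":
        return [np.eye(B.shape[0]) for B in hyper.B]
    mus, sigs = _block_views(posterior, structure, hyper.active_blocks)
    out: list[np.ndarray] = []
    for g, B_prev in enumerate(hyper.B):
        members = [b for b in hyper.active_blocks
                   if hyper.group_of[b] == g and gamma_new[b] > 0]
        if not members:
            logger.debug("group %d has no active blocks; keeping previous B", g)
            out.append(B_prev.copy())
            continue
        acc = np.zeros_like(B_prev)
        for b in members:
            acc += (sigs[b] + np.outer(mus[b], mus[b])) / gamma_new[b]
        B_raw = acc / len(members)
        out.append(0.5 * (B_raw + B_raw.T))
    return out


def toeplitz_constrain(B_raw: np.ndarray, ar_clamp: float = 0.98) -> np.ndarray:
    """Project a raw B estimate onto the AR(1) Toeplitz family.

    r = m1/m0 (mean first sub-diagonal over mean main diagonal), clipped to
    [-ar_clamp, ar_clamp]; returns Toeplitz([1, r, r^2, ...]) which is
    symmetric positive definite for |r| < 1.
    """
    B_raw = np.asarray(B_raw, dtype=float)
    d = B_raw.shape[0]
    if B_raw.shape != (d, d):
        raise ValueError("B_raw must be square")
    m0 = float(np.mean(np.diag(B_raw)))
    if m0 <= 0 or not np.isfinite(m0):
        logger.warning("non-positive diagonal mean in B estimate; using identity")
        return np.eye(d)
    if d == 1:
        return np.eye(1)
    m1 = float(np.mean(np.diag(B_raw, k=1)))
    r = float(np.clip(m1 / m0, -ar_clamp, ar_clamp))
    return toeplitz(r ** np.arange(d))


def prune(hyper: HyperState, tau: float,
          max_prune_per_iter: int = 5) -> tuple[HyperState, list[int]]:
    """Zero out up to ``max_prune_per_iter`` active blocks with gamma < tau.

    Candidates are removed smallest-gamma first; ties break toward the lower
    block index.  Returns the updated state and the pruned block indices.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    active = hyper.active_blocks
    cand = [b for b in active if hyper.gamma[b] < tau]
    cand.sort(key=lambda b: (hyper.gamma[b], b))
    pruned = [int(b) for b in cand[:max_prune_per_iter]]
    gamma = hyper.gamma.copy()
    mask = hyper.active_mask.copy()
    gamma[pruned] = 0.0
    mask[pruned] = False
    new = HyperState(gamma=gamma, B=[B.copy() for B in hyper.B],
                     sigma2=hyper.sigma2, active_mask=mask,
                     group_of=hyper.group_of)
    return new, pruned


@dataclass
class EMFitResult:
    """Everything the EM loop produced, plus bookkeeping for selection."""

    hyper: HyperState
    posterior: PosteriorState
    trace: list[dict]
    structure: BlockStructure
    config: FitConfig
    status: str = "converged"
    meta: dict = field(default_factory=dict)

    @property
    def removal_order(self) -> list[int]:
        """Blocks in the order they were pruned during EM."""
        out: list[int] = []
        for rec in self.trace:
            out.extend(rec["pruned"])
        return out

    @property
    def active_blocks(self) -> np.ndarray:
        return self.hyper.active_blocks

    def trace_table(self):
        import pandas as pd
        rows = [{"iteration": r["iteration"], "sigma2": r["sigma2"],
                 "path": r["path"], "n_active": r["n_active"],
                 "pruned": ";".join(map(str, r["pruned"])),
                 "rel_change": r["rel_change"]} for r in self.trace]
        return pd.DataFrame(rows)


def _posterior_blocks(Xa, y, hyper, structure, active, path, gram=None):
    """Posterior mean plus the per-block diagonal of Sigma_w.

    Only the block diagonal of the posterior covariance enters the EM
    updates, so the Woodbury route never materialises the full D x D matrix.
    Returns (mu, mu_blocks, sig_blocks, log_evidence).
    """
    offs = _active_offsets(structure, active)
    n = y.size
    sigma2 = hyper.sigma2
    if path == "direct":
        from scipy.linalg import block_diag
        inv_blocks = []
        for b in active:
            B = hyper.B[hyper.group_of[b]]
            inv_blocks.append(np.linalg.inv(B) / hyper.gamma[b])
        Sigma0_inv = block_diag(*inv_blocks)
        if gram is None:
            gram = Xa.T @ Xa
        A = gram / sigma2 + Sigma0_inv
        cA = cho_factor(A, lower=True)
        Sigma_w = cho_solve(cA, np.eye(A.shape[0]))
        Sigma_w = 0.5 * (Sigma_w + Sigma_w.T)
        mu = Sigma_w @ (Xa.T @ y) / sigma2
        sig_blocks = {b: Sigma_w[offs[b], offs[b]] for b in offs}
        ld0 = float(sum(structure.block_sizes[b] * np.log(hyper.gamma[b])
                        + np.linalg.slogdet(hyper.B[hyper.group_of[b]])[1]
                        for b in active))
        ldA = 2.0 * np.sum(np.log(np.diag(cA[0])))
        quad = float(y @ (y - Xa @ mu)) / sigma2
        logev = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + ld0
                        + ldA + quad)
    else:
        XS = np.empty_like(Xa)
        for b in active:
            s = offs[b]
            XS[:, s] = Xa[:, s] @ (hyper.gamma[b] * hyper.B[hyper.group_of[b]])
        H = sigma2 * np.eye(n) + XS @ Xa.T
        cH = cho_factor(H, lower=True)
        mu = XS.T @ cho_solve(cH, y)
        K = cho_solve(cH, XS)
        sig_blocks = {}
        for b in active:
            s = offs[b]
            Sb = (hyper.gamma[b] * hyper.B[hyper.group_of[b]]
                  - XS[:, s].T @ K[:, s])
            sig_blocks[b] = 0.5 * (Sb + Sb.T)
        ld = 2.0 * np.sum(np.log(np.diag(cH[0])))
        logev = -0.5 * (n * np.log(2 * np.pi) + ld + float(y @ cho_solve(cH, y)))
    mu_blocks = {b: mu[offs[b]] for b in offs}
    return mu, mu_blocks, sig_blocks, float(logev)


def em_fit(data: EpochDataset, regions: RegionMap | None,
           config: FitConfig | None = None) -> EMFitResult:
    """Run the EM fit loop with gamma pruning (the channel-selection engine).

    Each iteration computes the posterior under the current hyperparameters
    (direct route when N >= active D, Woodbury otherwise), then updates
    sigma^2, gamma and the group-wise B (Toeplitz-constrained unless
    b_mode='identity'), and finally prunes up to ``max_prune_per_iter``
    blocks whose gamma fell below tau.  Stops when the active gamma vector
    changes by less than ``tol`` in relative L2 norm with no pruning, or at
    ``max_iter`` (flagged in ``status``, not an exception).
    """
    config = config or FitConfig()
    structure = data.structure
    X, y = data.features, data.labels
    if config.center_targets:
        # the interceptless model cannot represent the class-imbalance
        # offset of +/-1 labels; centering absorbs it
        y = y - y.mean()
    groups = _groups_for_mode(config.b_mode, structure, regions)
    hyper = HyperState.initial(structure, groups,
                               sigma2=max(0.1 * float(np.var(y)),
                                          config.sigma2_floor))
    trace: list[dict] = []
    status = "max_iter"
    gram_cache: tuple[tuple[int, ...], np.ndarray] | None = None

    for it in range(config.max_iter):
        active = hyper.active_blocks
        if active.size == 0:
            raise RuntimeError(
                "degenerate selection: all channels pruned; lower tau or "
                "raise the gamma floor")
        feat_idx = structure.feature_indices(active)
        Xa = X[:, feat_idx]
        path = choose_posterior_path(X.shape[0], feat_idx.size)
        gram = None
        if path == "direct":
            key = tuple(int(b) for b in active)
            if gram_cache is None or gram_cache[0] != key:
                gram_cache = (key, Xa.T @ Xa)
            gram = gram_cache[1]
        mu, mu_b, sig_b, logev = _posterior_blocks(
            Xa, y, hyper, structure, active, path, gram)

        # --- sigma^2 (uses the old Sigma0 and old sigma^2) ---
        resid = y - Xa @ mu
        d_act = feat_idx.size
        tr = 0.0
        Binv = {g: np.linalg.inv(hyper.B[g]) for g in set(hyper.group_of[active])}
        for b in active:
            tr += float(np.trace(Binv[hyper.group_of[b]] @ sig_b[b])) / hyper.gamma[b]
        s2_new = (float(resid @ resid) + hyper.sigma2 * (d_act - tr)) / y.size
        if s2_new < config.sigma2_floor:
            logger.warning("sigma2 hit floor %g at iteration %d",
                           config.sigma2_floor, it)
            s2_new = config.sigma2_floor

        # --- gamma (uses the old B) ---
        gamma_new = hyper.gamma.copy()
        for b in active:
            M = sig_b[b] + np.outer(mu_b[b], mu_b[b])
            gamma_new[b] = max(
                float(np.trace(Binv[hyper.group_of[b]] @ M))
                / structure.block_sizes[b], 0.0)

        # --- B (uses the new gamma), Toeplitz-constrained ---
        B_new = []
        if config.b_mode == "identity":
            B_new = [B.copy() for B in hyper.B]
        else:
            for g, B_prev in enumerate(hyper.B):
                members = [b for b in active
                           if hyper.group_of[b] == g and gamma_new[b] > 0]
                if not members:
                    B_new.append(B_prev.copy())
                    continue
                acc = np.zeros_like(B_prev)
                for b in members:
                    acc += (sig_b[b] + np.outer(mu_b[b], mu_b[b])) / gamma_new[b]
                B_new.append(toeplitz_constrain(acc / len(members),
                                                config.ar_clamp))

        gamma_old_active = hyper.gamma[active]
        hyper = HyperState(gamma=gamma_new, B=B_new, sigma2=s2_new,
                           active_mask=hyper.active_mask.copy(),
                           group_of=hyper.group_of)
        hyper, pruned = prune(hyper, config.tau, config.max_prune_per_iter)

        denom = max(float(np.linalg.norm(gamma_old_active)), 1e-300)
        rel_change = float(
            np.linalg.norm(gamma_new[active] - gamma_old_active)) / denom
        trace.append({
            "iteration": it, "path": path, "sigma2": s2_new,
            "n_active": int(hyper.active_mask.sum()), "pruned": pruned,
            "gamma": hyper.gamma.copy(), "rel_change": rel_change,
            "log_evidence": logev,
        })
        if not pruned and rel_change < config.tol:
            status = "converged"
            break

    # final posterior under the final hyperparameters (Alg. returns mu of
    # the surviving blocks)
    active = hyper.active_blocks
    if active.size == 0:
        raise RuntimeError(
            "degenerate selection: all channels pruned; lower tau or raise "
            "the gamma floor")
    feat_idx = structure.feature_indices(active)
    Xa = X[:, feat_idx]
    Sigma0 = assemble_sigma0(hyper, structure)
    path = choose_posterior_path(X.shape[0], feat_idx.size)
    if path == "direct":
        post = posterior_direct(Xa, y, Sigma0, hyper.sigma2)
    else:
        post = posterior_woodbury(Xa, y, Sigma0, hyper.sigma2)
    if status != "converged":
        logger.warning("EM did not converge within %d iterations", config.max_iter)
    return EMFitResult(hyper=hyper, posterior=post, trace=trace,
                       structure=structure, config=config, status=status)


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402
from sklearn.feature_selection import SelectorMixin  # noqa: E402
from sklearn.utils.validation import check_is_fitted, check_X_y  # noqa: E402


class RegionalBSBL(SelectorMixin, BaseEstimator):
    """Channel selector driven by regionally smoothed BSBL.

    A scikit-learn transformer: ``fit(X, y)`` runs the EM engine on the
    (n_stimuli, n_channels * n_times) feature matrix and binary labels;
    ``transform(X)`` keeps only the feature columns of the selected
    channels.  ``n_select`` switches from automatic (tau-thresholded)
    selection to a fixed number of channels ranked by importance, with
    last-pruned-first backfill when fewer channels survived.

    Parameters
    ----------
    n_times : int
        Time points per channel; defines the block structure
        (n_channels = n_features // n_times).
    regions : RegionMap or None
        Spatial grouping used when ``b_mode='regional'``.  None falls back
        to a single all-channel region.
    tau : float
        Shear threshold on gamma.
    b_mode : {'regional', 'per_block', 'shared', 'identity'}
        Tying of the intra-block correlation matrix.
    n_select : int or None
        If given, return exactly this many channels (fixed-M mode).

    Attributes
    ----------
    gamma_ : ndarray of shape (n_channels,)
        Final relevance scale per channel (0 for pruned channels).
    selected_channels_ : ndarray of int
        Indices of the selected channels, ascending.
    importance_ : ndarray of shape (n_channels,)
        Sum of |posterior-mean weights| per channel.
    coef_ : ndarray of shape (n_features,)
        Sparse posterior-mean weight vector (zeros off the selection).
    removal_order_ : list of int
        Channels in the order the EM loop pruned them.
    """

    def __init__(self, n_times=None, regions=None, tau=1e-3, b_mode="regional",
                 max_iter=200, tol=1e-4, max_prune_per_iter=5, ar_clamp=0.98,
                 sigma2_floor=1e-10, center_targets=True, n_select=None,
                 seed=0):
        self.n_times = n_times
        self.regions = regions
        self.tau = tau
        self.b_mode = b_mode
        self.max_iter = max_iter
        self.tol = tol
        self.max_prune_per_iter = max_prune_per_iter
        self.ar_clamp = ar_clamp
        self.sigma2_floor = sigma2_floor
        self.center_targets = center_targets
        self.n_select = n_select
        self.seed = seed

    def _config(self) -> FitConfig:
        return FitConfig(tau=self.tau, max_iter=self.max_iter, tol=self.tol,
                         b_mode=self.b_mode,
                         max_prune_per_iter=self.max_prune_per_iter,
                         ar_clamp=self.ar_clamp,
                         sigma2_floor=self.sigma2_floor,
                         center_targets=self.center_targets, seed=self.seed)

    def fit(self, X, y, channel_names=None):
        from .selection import select_auto, select_top_m

        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        if self.n_times is None:
            if self.regions is None:
                raise ValueError("n_times (or a RegionMap) is required to "
                                 "define the per-channel blocks")
            n_ch = self.regions.n_channels
            n_times, rem = divmod(X.shape[1], n_ch)
        else:
            n_times = int(self.n_times)
            n_ch, rem = divmod(X.shape[1], n_times)
        if rem:
            raise ValueError("n_features is not a multiple of the block size")
        structure = BlockStructure.uniform(n_ch, n_times)
        if channel_names is None:
            channel_names = [f"ch{i:02d}" for i in range(n_ch)]
        regions = self.regions
        if regions is None and self.b_mode == "regional":
            regions = RegionMap.single(n_ch)
        data = EpochDataset(features=X, labels=y, structure=structure,
                            channel_names=list(channel_names))
        result = em_fit(data, regions, self._config())
        selection = select_auto(result, self.tau)
        if self.n_select is not None:
            chosen = select_top_m(selection, int(self.n_select))
            mask_ch = np.zeros(n_ch, dtype=bool)
            mask_ch[chosen] = True
            selection = selection.restricted(chosen)
        self.structure_ = structure
        self.result_ = result
        self.selection_ = selection
        self.gamma_ = result.hyper.gamma.copy()
        self.sigma2_ = result.hyper.sigma2
        self.selected_channels_ = np.asarray(selection.selected, dtype=int)
        self.importance_ = selection.importance.copy()
        self.coef_ = selection.weights.copy()
        self.removal_order_ = list(result.removal_order)
        self.n_iter_ = len(result.trace)
        self.channel_names_ = list(channel_names)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_channels_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.structure_.feature_indices(self.selected_channels_)] = True
        return mask

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
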