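"""Core engine tests: posterior algebra, EM updates, pruning, fit loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import block_diag, toeplitz

from bsblsel import (BlockStructure, EpochDataset, FitConfig, HyperState,
                     RegionMap, assemble_sigma0, choose_posterior_path,
                     em_fit, gen_block_sparse, posterior_direct,
                     posterior_woodbury, prune, toeplitz_constrain,
                     update_B, update_gamma, update_sigma2)
from bsblsel.simulate import BlockSparseSpec


def _hyper(gamma, Bs, sigma2, group_of=None, mask=None):
    gamma = np.asarray(gamma, float)
    n = gamma.size
    return HyperState(
        gamma=gamma, B=Bs, sigma2=sigma2,
        active_mask=np.ones(n, bool) if mask is None else np.asarray(mask),
        group_of=np.zeros(n, int) if group_of is None else np.asarray(group_of))


class TestAssembleSigma0:
    def test_identity_case(self):
        st2 = BlockStructure.uniform(2, 2)
        h = _hyper([1.0, 1.0], [np.eye(2)], 1.0)
        assert np.array_equal(assemble_sigma0(h, st2), np.eye(4))

    def test_pruned_block_removed(self):
        st2 = BlockStructure.uniform(2, 2)
        h = _hyper([2.0, 0.0], [np.eye(2)], 1.0, mask=[True, False])
        assert np.array_equal(assemble_sigma0(h, st2), 2.0 * np.eye(2))

    def test_single_block_toeplitz(self):
        st1 = BlockStructure.uniform(1, 2)
        h = _hyper([1.0], [toeplitz([1, 0.5])], 1.0)
        assert np.allclose(assemble_sigma0(h, st1),
                           [[1, 0.5], [0.5, 1]])

    def test_dimension_mismatch_raises(self):
        st1 = BlockStructure.uniform(1, 3)
        h = _hyper([1.0], [np.eye(2)], 1.0)
        with pytest.raises(ValueError, match="block 0"):
            assemble_sigma0(h, st1)


class TestPosterior:
    def test_no_data_term(self, rng):
        S0 = np.diag([1.0, 2.0, 3.0])
        X = np.zeros((5, 3))
        y = rng.standard_normal(5)
        for f in (posterior_direct, posterior_woodbury):
            p = f(X, y, S0, 1.0)
            assert np.allclose(p.mu, 0)
            assert np.allclose(p.Sigma, S0)

    def test_identity_closed_form(self):
        n = 4
        y = np.arange(1.0, 5.0)
        p = posterior_direct(np.eye(n), y, np.eye(n), 1.0)
        assert np.allclose(p.Sigma, 0.5 * np.eye(n))
        assert np.allclose(p.mu, 0.5 * y)

    def test_matches_high_precision_solve(self, rng):
        # oracle: direct normal-equations solve at long-double precision
        X = rng.standard_normal((8, 6))
        y = rng.standard_normal(8)
        S0 = np.diag(rng.uniform(0.5, 2.0, 6))
        s2 = 0.7
        Xl = X.astype(np.longdouble)
        A = Xl.T @ Xl / s2 + np.linalg.inv(S0).astype(np.longdouble)
        Sigma = np.linalg.inv(A.astype(float))
        mu = Sigma @ (X.T @ y) / s2
        p = posterior_direct(X, y, S0, s2)
        assert np.allclose(p.mu, mu, rtol=1e-10)
        assert np.allclose(p.Sigma, Sigma, rtol=1e-9)

    def test_woodbury_handles_zero_gamma(self, rng):
        # one block with zero prior variance: its posterior weights pin to 0
        X = rng.standard_normal((6, 4))
        y = rng.standard_normal(6)
        S0 = block_diag(np.eye(2), np.zeros((2, 2)))
        p = posterior_woodbury(X, y, S0, 0.5)
        assert np.allclose(p.mu[2:], 0)
        assert np.allclose(p.Sigma[2:, 2:], 0)

    def test_direct_singular_sigma0_raises(self, rng):
        X = rng.standard_normal((6, 4))
        S0 = block_diag(np.eye(2), np.zeros((2, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            posterior_direct(X, rng.standard_normal(6), S0, 0.5)

    def test_non_finite_input_rejected(self):
        X = np.full((3, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            posterior_direct(X, np.ones(3), np.eye(2), 1.0)

    def test_path_equivalence_many_instances(self):
        # the Woodbury identity must hold to tight relative error on random
        # instances with PD prior covariance
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(5, 41))
            nb = int(rng.integers(2, 11))
            d = int(rng.integers(1, 7))
            X = rng.standard_normal((n, nb * d))
            y = rng.standard_normal(n)
            blocks = [float(rng.uniform(0.1, 3.0))
                      * toeplitz(float(rng.uniform(-0.9, 0.9)) ** np.arange(d))
                      for _ in range(nb)]
            S0 = block_diag(*blocks)
            s2 = float(rng.uniform(0.01, 2.0))
            p1 = posterior_direct(X, y, S0, s2)
            p2 = posterior_woodbury(X, y, S0, s2)
            scale_mu = max(np.max(np.abs(p1.mu)), 1e-30)
            scale_S = max(np.max(np.abs(p1.Sigma)), 1e-30)
            worst = max(worst,
                        np.max(np.abs(p1.mu - p2.mu)) / scale_mu,
                        np.max(np.abs(p1.Sigma - p2.Sigma)) / scale_S)
        assert worst <= 1e-8

    def test_sigma_symmetric_psd(self, rng):
        X = rng.standard_normal((10, 6))
        y = rng.standard_normal(10)
        S0 = np.diag(rng.uniform(0.1, 1, 6))
        for f in (posterior_direct, posterior_woodbury):
            p = f(X, y, S0, 0.3)
            assert np.allclose(p.Sigma, p.Sigma.T)
            assert np.linalg.eigvalsh(p.Sigma).min() > -1e-10


class TestChoosePath:
    @pytest.mark.parametrize("n, d, expected", [
        (7560, 2048, "direct"),    # large competition-scale training set
        (864, 1770, "woodbury"),   # small lab-scale training set
        (100, 100, "direct"),      # boundary: N = D goes direct
    ])
    def test_rule(self, n, d, expected):
        assert choose_posterior_path(n, d) == expected

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            choose_posterior_path(0, 5)


class TestUpdates:
    def test_sigma2_no_data(self, rng):
        # X = 0: mu = 0, Sigma = Sigma0, trace term equals D exactly
        S0 = np.diag([1.0, 2.0])
        X = np.zeros((8, 2))
        y = rng.standard_normal(8)
        p = posterior_woodbury(X, y, S0, 1.0)
        s2 = update_sigma2(X, y, p, S0, 1.0)
        assert np.isclose(s2, y @ y / 8)

    def test_sigma2_matches_straight_line_formula(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        S0 = np.diag(rng.uniform(0.5, 2, 4))
        s2_old = 0.8
        p = posterior_direct(X, y, S0, s2_old)
        expected = ((np.linalg.norm(y - X @ p.mu) ** 2
                     + s2_old * (4 - np.trace(p.Sigma @ np.linalg.inv(S0))))
                    / 10)
        assert np.isclose(update_sigma2(X, y, p, S0, s2_old), expected,
                          rtol=1e-12)

    def test_sigma2_floor(self):
        from bsblsel.bsbl import PosteriorState
        # perfect fit, vanishing posterior: update would go to ~0
        X = np.eye(2)
        y = np.zeros(2)
        p = PosteriorState(mu=np.zeros(2), Sigma=1e-14 * np.eye(2))
        s2 = update_sigma2(X, y, p, np.eye(2), 1e-13, floor=1e-10)
        assert s2 == 1e-10

    def test_gamma_identity_B_zero_mu(self):
        from bsblsel.bsbl import PosteriorState
        st4 = BlockStructure.uniform(1, 4)
        h = _hyper([1.0], [np.eye(4)], 1.0)
        p = PosteriorState(mu=np.zeros(4), Sigma=np.eye(4))
        assert np.isclose(update_gamma(p, h, st4)[0], 1.0)

    def test_gamma_mean_energy(self):
        from bsblsel.bsbl import PosteriorState
        st2 = BlockStructure.uniform(1, 2)
        h = _hyper([1.0], [np.eye(2)], 1.0)
        p = PosteriorState(mu=np.array([2.0, 0.0]), Sigma=np.zeros((2, 2)))
        assert np.isclose(update_gamma(p, h, st2)[0], 2.0)

    def test_gamma_nontrivial_B_oracle(self, rng):
        from bsblsel.bsbl import PosteriorState
        st3 = BlockStructure.uniform(1, 3)
        B = toeplitz([1, 0.4, 0.16])
        h = _hyper([1.0], [B], 1.0)
        mu = rng.standard_normal(3)
        A = rng.standard_normal((3, 3))
        Sigma = A @ A.T
        p = PosteriorState(mu=mu, Sigma=Sigma)
        expected = np.trace(np.linalg.inv(B) @ (Sigma + np.outer(mu, mu))) / 3
        assert np.isclose(update_gamma(p, h, st3)[0], expected, rtol=1e-12)

    def test_B_single_block_is_its_contribution(self, rng):
        from bsblsel.bsbl import PosteriorState
        st3 = BlockStructure.uniform(1, 3)
        A = rng.standard_normal((3, 3))
        C = A @ A.T
        h = _hyper([1.0], [np.eye(3)], 1.0)
        p = PosteriorState(mu=np.zeros(3), Sigma=C)
        out = update_B(p, h, st3, gamma_new=np.array([1.0]), b_mode="shared")
        assert np.allclose(out[0], C)

    def test_B_group_mean_oracle(self, rng):
        from bsblsel.bsbl import PosteriorState
        st3 = BlockStructure.uniform(3, 2)
        h = _hyper([1.0, 1.0, 1.0], [np.eye(2)], 1.0)
        mu = rng.standard_normal(6)
        A = rng.standard_normal((6, 6))
        Sigma = A @ A.T
        p = PosteriorState(mu=mu, Sigma=Sigma)
        gnew = np.array([0.5, 1.5, 2.0])
        out = update_B(p, h, st3, gamma_new=gnew, b_mode="shared")
        acc = np.zeros((2, 2))
        for b in range(3):
            s = st3.block_slice(b)
            acc += (Sigma[s, s] + np.outer(mu[s], mu[s])) / gnew[b]
        assert np.allclose(out[0], acc / 3, rtol=1e-12)

    def test_B_empty_group_keeps_previous(self):
        from bsblsel.bsbl import PosteriorState
        st2 = BlockStructure.uniform(2, 2)
        Bprev = toeplitz([1, 0.3])
        h = _hyper([0.0, 1.0], [Bprev, np.eye(2)], 1.0,
                   group_of=[0, 1], mask=[False, True])
        p = PosteriorState(mu=np.ones(2), Sigma=np.eye(2))
        out = update_B(p, h, st2, gamma_new=np.array([0.0, 1.0]),
                       b_mode="regional")
        assert np.allclose(out[0], Bprev)


class TestToeplitzConstrain:
    def test_identity_passthrough(self):
        assert np.array_equal(toeplitz_constrain(np.eye(4)), np.eye(4))

    def test_half_correlation(self):
        B = np.eye(3) + 0.5 * (np.eye(3, k=1) + np.eye(3, k=-1))
        out = toeplitz_constrain(B)
        assert np.allclose(out, toeplitz([1, 0.5, 0.25]))

    def test_clamp_keeps_pd(self):
        B = np.eye(3) + 1.3 * (np.eye(3, k=1) + np.eye(3, k=-1))
        out = toeplitz_constrain(B, ar_clamp=0.99)
        assert np.isclose(out[0, 1], 0.99)
        assert np.linalg.eigvalsh(out).min() > 0

    def test_nonpositive_diagonal_falls_back_to_identity(self):
        assert np.array_equal(toeplitz_constrain(-np.eye(3)), np.eye(3))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(0, 2 ** 32 - 1))
    def test_always_ar1_toeplitz_symmetric_pd(self, d, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((d, d))
        B_raw = A + A.T
        out = toeplitz_constrain(B_raw, ar_clamp=0.98)
        r = out[0, 1] if d > 1 else 0.0
        assert abs(r) <= 0.98
        assert np.allclose(out, toeplitz(r ** np.arange(d)))
        assert np.allclose(out, out.T)
        assert np.linalg.eigvalsh(out).min() > 0


class TestPrune:
    def test_above_threshold_untouched(self):
        h = _hyper([0.5, 0.3], [np.eye(2)], 1.0)
        new, pruned = prune(h, tau=0.1)
        assert pruned == []
        assert np.array_equal(new.gamma, [0.5, 0.3])

    def test_cap_binds_with_index_tiebreak(self):
        h = _hyper([1e-9] * 7, [np.eye(2)], 1.0,
                   group_of=np.zeros(7, int))
        new, pruned = prune(h, tau=1e-3, max_prune_per_iter=5)
        assert pruned == [0, 1, 2, 3, 4]
        assert new.active_mask.sum() == 2

    def test_threshold_rule_below_cap(self):
        h = _hyper([0.2, 1e-8, 0.3, 1e-9], [np.eye(2)], 1.0,
                   group_of=np.zeros(4, int))
        new, pruned = prune(h, tau=1e-3)
        assert sorted(pruned) == [1, 3]
        # smallest gamma pruned first in the returned order
        assert pruned == [3, 1]

    def test_pruned_gamma_exactly_zero(self):
        h = _hyper([1e-9, 0.5], [np.eye(2)], 1.0,
                   group_of=np.zeros(2, int))
        new, _ = prune(h, tau=1e-3)
        assert new.gamma[0] == 0.0
        assert not new.active_mask[0]


def _straight_line_em_step(X, y, gamma, Bs, group_of, sigma2, structure,
                           tau, ar_clamp=0.98, cap=5):
    """Independent dense transcription of one EM iteration.

    Posterior by the path rule, then the noise, relevance and correlation
    updates with Toeplitz constraining and capped pruning.  Written
    straight-line from the update formulas, no shared code with the engine.
    """
    nb = structure.n_blocks
    S0 = block_diag(*[gamma[b] * Bs[group_of[b]] for b in range(nb)])
    n, d = X.shape
    if n >= d:
        Sw = np.linalg.inv(X.T @ X / sigma2 + np.linalg.inv(S0))
        mu = Sw @ X.T @ y / sigma2
    else:
        Hinv = np.linalg.inv(sigma2 * np.eye(n) + X @ S0 @ X.T)
        Sw = S0 - S0 @ X.T @ Hinv @ X @ S0
        mu = S0 @ X.T @ Hinv @ y
    s2_new = (np.linalg.norm(y - X @ mu) ** 2
              + sigma2 * (d - np.trace(Sw @ np.linalg.inv(S0)))) / n
    gamma_new = np.empty(nb)
    for b in range(nb):
        s = structure.block_slice(b)
        M = Sw[s, s] + np.outer(mu[s], mu[s])
        gamma_new[b] = np.trace(np.linalg.inv(Bs[group_of[b]]) @ M) / \
            structure.block_sizes[b]
    B_new = []
    for g in range(max(group_of) + 1):
        members = [b for b in range(nb) if group_of[b] == g]
        acc = np.zeros_like(Bs[g])
        for b in members:
            s = structure.block_slice(b)
            acc += (Sw[s, s] + np.outer(mu[s], mu[s])) / gamma_new[b]
        raw = acc / len(members)
        m0 = np.mean(np.diag(raw))
        m1 = np.mean(np.diag(raw, 1))
        r = np.clip(m1 / m0, -ar_clamp, ar_clamp)
        B_new.append(toeplitz(r ** np.arange(raw.shape[0])))
    below = sorted([b for b in range(nb) if gamma_new[b] < tau],
                   key=lambda b: (gamma_new[b], b))[:cap]
    gamma_out = gamma_new.copy()
    gamma_out[below] = 0.0
    return mu, Sw, s2_new, gamma_out, B_new, sorted(below)


class TestEMFit:
    def test_single_iteration_matches_straight_line_oracle(self, rng):
        structure = BlockStructure.uniform(3, 4)
        n = 15
        X = rng.standard_normal((n, 12))
        w = np.concatenate([rng.standard_normal(4), np.zeros(8)])
        y = X @ w + 0.2 * rng.standard_normal(n)
        y = y - y.mean()
        regions = RegionMap.single(3)
        cfg = FitConfig(tau=1e-3, max_iter=1, b_mode="regional",
                        center_targets=False)
        ds = EpochDataset(features=X, labels=np.where(y > 0, 1, -1),
                          structure=structure, channel_names=["a", "b", "c"])
        ds.labels = y  # regression targets for the oracle comparison
        res = em_fit(ds, regions, cfg)
        s2_init = max(0.1 * np.var(y), 1e-10)
        _, _, s2_o, gamma_o, B_o, pruned_o = _straight_line_em_step(
            X, y, np.ones(3), [np.eye(4)], [0, 0, 0], s2_init, structure,
            tau=1e-3)
        assert np.allclose(res.hyper.gamma, gamma_o, atol=1e-10)
        assert np.isclose(res.hyper.sigma2, s2_o, rtol=1e-10)
        assert np.allclose(res.hyper.B[0], B_o[0], atol=1e-10)
        assert res.removal_order == pruned_o

    def test_classical_sbl_reduction_scalar_blocks(self, rng):
        # d_b = 1 with identity B: one iteration must give the scalar SBL
        # update gamma_i = Sigma_ii + mu_i^2
        structure = BlockStructure.uniform(5, 1)
        X = rng.standard_normal((12, 5))
        y = rng.standard_normal(12)
        y = y - y.mean()
        ds = EpochDataset(features=X, labels=np.where(y > 0, 1, -1),
                          structure=structure,
                          channel_names=list("abcde"))
        ds.labels = y
        cfg = FitConfig(tau=1e-12, max_iter=1, b_mode="identity",
                        center_targets=False)
        res = em_fit(ds, None, cfg)
        s2 = max(0.1 * np.var(y), 1e-10)
        p = posterior_direct(X, y, np.eye(5), s2)
        expected = np.diag(p.Sigma) + p.mu ** 2
        assert np.allclose(res.hyper.gamma, expected, atol=1e-12)

    def test_recovers_planted_support(self):
        ds, truth = gen_block_sparse(BlockSparseSpec(seed=11))
        res = em_fit(ds, RegionMap.uniform(40, 8), FitConfig(tau=0.05))
        selected = np.flatnonzero(res.hyper.gamma > 0.05)
        assert set(selected) == set(truth["support"])

    def test_tiny_tau_prunes_nothing(self):
        ds, _ = gen_block_sparse(BlockSparseSpec(seed=11))
        res = em_fit(ds, RegionMap.uniform(40, 8),
                     FitConfig(tau=1e-7, max_iter=40))
        assert res.removal_order == []
        assert res.hyper.active_mask.all()

    def test_deterministic_trace(self):
        ds, _ = gen_block_sparse(BlockSparseSpec(seed=5))
        cfg = FitConfig(tau=0.05)
        r1 = em_fit(ds, RegionMap.uniform(40, 8), cfg)
        r2 = em_fit(ds, RegionMap.uniform(40, 8), cfg)
        assert len(r1.trace) == len(r2.trace)
        for a, b in zip(r1.trace, r2.trace):
            assert a["pruned"] == b["pruned"]
            assert a["sigma2"] == b["sigma2"]
            assert np.array_equal(a["gamma"], b["gamma"])

    def test_active_set_monotone_and_pruned_stay_pruned(self):
        ds, _ = gen_block_sparse(BlockSparseSpec(seed=3))
        res = em_fit(ds, RegionMap.uniform(40, 8), FitConfig(tau=0.05))
        prev = ds.structure.n_blocks
        gone: set[int] = set()
        for rec in res.trace:
            assert rec["n_active"] <= prev
            prev = rec["n_active"]
            gone.update(rec["pruned"])
            assert np.all(rec["gamma"][sorted(gone)] == 0)
            assert np.all(rec["gamma"] >= 0)

    def test_all_pruned_raises_degenerate(self, toy_dataset, toy_regions):
        with pytest.raises(RuntimeError, match="degenerate"):
            em_fit(toy_dataset, toy_regions, FitConfig(tau=1e6, max_iter=50))

    def test_nonconvergence_flagged_not_raised(self, toy_dataset, toy_regions):
        res = em_fit(toy_dataset, toy_regions,
                     FitConfig(tau=1e-9, max_iter=2, tol=1e-12))
        assert res.status == "max_iter"

    def test_b_constrained_toeplitz_every_iteration(self):
        ds, _ = gen_block_sparse(BlockSparseSpec(seed=2, n_blocks=10,
                                                 n_samples=120))
        res = em_fit(ds, RegionMap.uniform(10, 2),
                     FitConfig(tau=0.05, max_iter=30))
        for B in res.hyper.B:
            r = B[0, 1]
            assert np.allclose(B, toeplitz(r ** np.arange(B.shape[0])))
            assert np.linalg.eigvalsh(B).min() > 0
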