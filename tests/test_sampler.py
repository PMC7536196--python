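import copy
import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import linregress

from hidalgo import make_gaussian_pair, neighbor_stats, nmi
from hidalgo._gibbs import z_logweights_kernel
from hidalgo.model import (
    ChainState,
    HidalgoConfig,
    log_partition_table,
    log_posterior,
    neighborhood_loglik,
)
from hidalgo.neighbors import NeighborStats
from hidalgo.sampler import (
    UNASSIGNED,
    fit,
    gibbs_sweep,
    init_state,
    run_chain,
    sample_d,
    sample_p,
    z_logweights,
)


def ring_stats(mu: np.ndarray, q: int = 2) -> NeighborStats:
    """NeighborStats with prescribed mu on a ring-graph neighbor structure
    (for tests that control the Pareto ratios directly)."""
    n = len(mu)
    idx = np.stack([(np.arange(n) + j) % n for j in range(1, q + 1)], axis=1)
    in_lists = [[] for _ in range(n)]
    for i in range(n):
        for j in idx[i]:
            in_lists[j].append(i)
    return NeighborStats(
        neighbor_idx=idx.astype(np.int64),
        in_lists=tuple(np.asarray(v, dtype=np.int64) for v in in_lists),
        r1=np.ones(n),
        r2=np.asarray(mu, dtype=np.float64),
        mu=np.asarray(mu, dtype=np.float64),
    )


class TestInitState:
    def test_k1_is_forced(self, gauss30_stats):
        cfg = HidalgoConfig(K=1, n_sweeps=10, n_chains=1)
        state = init_state(gauss30_stats, cfg, np.random.default_rng(0))
        assert np.all(state.z == 0)
        assert state.p.tolist() == [1.0]

    def test_seeding_contract(self, gauss30_stats):
        cfg = HidalgoConfig(K=3, n_sweeps=10, n_chains=1)
        a = init_state(gauss30_stats, cfg, np.random.default_rng(5))
        b = init_state(gauss30_stats, cfg, np.random.default_rng(5))
        c = init_state(gauss30_stats, cfg, np.random.default_rng(6))
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.d, b.d)
        assert not np.array_equal(a.z, c.z) or not np.allclose(a.d, c.d)

    def test_dimensions_positive(self, gauss30_stats):
        cfg = HidalgoConfig(K=4, n_sweeps=10, n_chains=1)
        for seed in range(5):
            state = init_state(gauss30_stats, cfg, np.random.default_rng(seed))
            assert np.all(state.d > 0)


class TestSampleD:
    def test_conditional_matches_gamma_density(self, gauss30_stats):
        # the d_k conditional extracted from the full log-posterior must be
        # proportional to Gamma(a + N_k, b + V_k)
        s = gauss30_stats
        cfg = HidalgoConfig(K=2, n_sweeps=10, n_chains=1)
        state = init_state(s, cfg, np.random.default_rng(2))
        k = 0
        n_k = int(np.sum(state.z == k))
        v_k = float(np.sum(np.log(s.mu[state.z == k])))

        def conditional_logpdf(x):
            st = copy.deepcopy(state)
            st.d[k] = x
            return log_posterior(st, s, cfg)

        shape, rate = 1.0 + n_k, 1.0 + v_k
        for x1, x2 in [(1.0, 2.0), (0.5, 3.7), (2.2, 6.0)]:
            lhs = conditional_logpdf(x2) - conditional_logpdf(x1)
            rhs = (shape - 1) * math.log(x2 / x1) - rate * (x2 - x1)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_conditional_mean_by_numerical_integration(self):
        # a=b=1, N_k=100, V_k=20: mean of the unnormalized conditional
        # integrates to (a+N_k)/(b+V_k) = 101/21
        shape, rate = 101.0, 21.0
        log_norm = shape * math.log(rate) - gammaln(shape)

        def density(x):
            return math.exp(log_norm + (shape - 1) * math.log(x) - rate * x)

        mean, _ = quad(lambda x: x * density(x), 0, 60, limit=200)
        assert mean == pytest.approx(101.0 / 21.0, abs=1e-6)
        assert 101.0 / 21.0 == pytest.approx(4.8095, abs=1e-4)

    def test_empty_component_draws_from_prior(self, gauss30_stats):
        s = gauss30_stats
        cfg = HidalgoConfig(K=2, a=1.0, b=1.0, n_sweeps=10, n_chains=1)
        state = init_state(s, cfg, np.random.default_rng(0))
        state.z[:] = 0  # component 1 empty
        draws = np.array(
            [sample_d(state, s, cfg, np.random.default_rng(i))[1] for i in range(4000)]
        )
        # Gamma(1,1) = Exp(1): mean 1, variance 1
        assert draws.mean() == pytest.approx(1.0, abs=0.06)
        assert draws.var() == pytest.approx(1.0, abs=0.15)

    def test_posterior_concentrates_with_sample_size(self):
        # K=1 with known-mu Pareto data: the d posterior tightens around the
        # truth as N grows
        truth = 3.0
        rng = np.random.default_rng(8)
        prev_sd = None
        for n in (100, 1000, 10_000):
            mu = (1.0 - rng.random(n)) ** (-1.0 / truth)
            s = ring_stats(mu)
            cfg = HidalgoConfig(K=1, q=2, n_sweeps=2000, n_chains=1, seed=1)
            res = fit(s, cfg)
            assert abs(res.d_mean[0] - truth) < 4 * max(res.d_sd[0], 1e-3) + 0.2
            if prev_sd is not None:
                assert res.d_sd[0] < prev_sd
            prev_sd = res.d_sd[0]


class TestSampleP:
    def test_k1_degenerate(self, gauss30_stats):
        cfg = HidalgoConfig(K=1, n_sweeps=10, n_chains=1)
        state = init_state(gauss30_stats, cfg, np.random.default_rng(0))
        assert sample_p(state, cfg, np.random.default_rng(1)).tolist() == [1.0]

    def test_on_simplex(self, gauss30_stats):
        cfg = HidalgoConfig(K=3, n_sweeps=10, n_chains=1)
        state = init_state(gauss30_stats, cfg, np.random.default_rng(0))
        p = sample_p(state, cfg, np.random.default_rng(2))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dirichlet_posterior_mean(self):
        # c=(1,1) with counts (3,1) gives conditional mean (4/6, 2/6)
        mu = np.array([1.5, 2.0, 1.2, 3.0])
        s = ring_stats(mu)
        cfg = HidalgoConfig(K=2, q=2, n_sweeps=10, n_chains=1)
        state = ChainState(
            z=np.array([0, 0, 0, 1]), d=np.array([1.0, 1.0]), p=np.array([0.5, 0.5])
        )
        rng = np.random.default_rng(0)
        draws = np.array([sample_p(state, cfg, rng) for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(axis=0), [4 / 6, 2 / 6], atol=0.01)


class TestZLogweights:
    def test_incremental_equals_full_recompute(self, gauss30_stats):
        # the module's key correctness oracle: for every point and label the
        # incremental weight difference equals the full log-posterior
        # difference
        s = gauss30_stats
        cfg = HidalgoConfig(K=3, q=3, xi=0.8, n_sweeps=10, n_chains=1)
        state = init_state(s, cfg, np.random.default_rng(4))
        lnz = log_partition_table(cfg.xi, s.n_points, cfg.q)
        for i in range(s.n_points):
            w = z_logweights(i, state, s, cfg, lnz)
            full = np.empty(cfg.K)
            for k in range(cfg.K):
                st = copy.deepcopy(state)
                st.z[i] = k
                full[k] = log_posterior(st, s, cfg, lnz)
            np.testing.assert_allclose(w - w[0], full - full[0], atol=1e-9)

    def test_kernel_agrees_with_reference(self, gauss30_stats):
        s = gauss30_stats
        cfg = HidalgoConfig(K=3, q=3, xi=0.8, n_sweeps=10, n_chains=1)
        state = init_state(s, cfg, np.random.default_rng(4))
        lnz = log_partition_table(cfg.xi, s.n_points, cfg.q)
        indptr, indices = s.in_csr()
        logit = math.log(cfg.xi) - math.log1p(-cfg.xi)
        for i in range(s.n_points):
            w = z_logweights(i, state, s, cfg, lnz)
            wk = z_logweights_kernel(
                i, state.z, state.counts(), state.d, state.p, np.log(s.mu),
                s.neighbor_idx, indptr, indices, lnz, logit,
            )
            np.testing.assert_allclose(w - w[0], wk - wk[0], atol=1e-10)

    def test_half_xi_reduces_to_mixture_weights(self, gauss30_stats):
        s = gauss30_stats
        cfg = HidalgoConfig(K=3, xi=0.5, n_sweeps=10, n_chains=1)
        state = init_state(s, cfg, np.random.default_rng(9))
        lnz = log_partition_table(0.5, s.n_points, cfg.q)
        for i in (0, 7, 29):
            w = z_logweights(i, state, s, cfg, lnz)
            expect = (
                np.log(state.p)
                + np.log(state.d)
                - (state.d + 1.0) * math.log(s.mu[i])
            )
            np.testing.assert_allclose(w - w[0], expect - expect[0], atol=1e-10)


def exact_label_posterior(stats, cfg):
    """Enumerate P(z) exactly with d and p marginalized in closed form
    (Gamma and Dirichlet-multinomial integrals) — the oracle for the
    detailed-balance test."""
    n, K = stats.n_points, cfg.K
    lnmu = np.log(stats.mu)
    lnz_tab = log_partition_table(cfg.xi, n, cfg.q)
    lxi, l1m = math.log(cfg.xi), math.log1p(-cfg.xi)
    configs = list(itertools.product(range(K), repeat=n))
    logp = np.empty(len(configs))
    for idx, z in enumerate(configs):
        z = np.asarray(z)
        counts = np.bincount(z, minlength=K)
        v = np.bincount(z, weights=lnmu, minlength=K)
        # integral over d_k of d^(a-1+N_k) e^(-d (b+V_k)); a=b=1
        val = float(
            np.sum(gammaln(1.0 + counts) - (1.0 + counts) * np.log(1.0 + v))
        )
        # Dirichlet-multinomial: c=1
        val += float(np.sum(gammaln(1.0 + counts))) + gammaln(K) - gammaln(K + n)
        val += neighborhood_loglik(stats, z, cfg.xi, cfg.q, counts, lnz_tab)
        logp[idx] = val
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


class TestGibbsSweep:
    def test_k1_sweep_only_updates_d_p(self, gauss30_stats):
        cfg = HidalgoConfig(K=1, n_sweeps=10, n_chains=1)
        state = init_state(gauss30_stats, cfg, np.random.default_rng(0))
        z_before = state.z.copy()
        gibbs_sweep(state, gauss30_stats, cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(state.z, z_before)

    def test_stationary_distribution_matches_enumeration(self):
        # 5-point system, K=2: the chain's joint label frequencies must match
        # the exactly enumerated posterior (d, p marginalized analytically)
        rng = np.random.default_rng(12)
        x = rng.standard_normal((5, 2))
        stats = neighbor_stats(x, q=2)
        cfg = HidalgoConfig(
            K=2, q=2, xi=0.8, n_sweeps=100_000, keep_fraction=0.9, n_chains=1, seed=3
        )
        trace = run_chain(stats, cfg, seed=3, tally_configs=True)
        sampled = trace.config_tally / trace.config_tally.sum()
        exact = exact_label_posterior(stats, cfg)
        tv = 0.5 * np.abs(sampled - exact).sum()
        assert tv < 0.02


class TestRunChain:
    def test_retained_count_arithmetic(self, gauss30_stats):
        cfg = HidalgoConfig(K=2, n_sweeps=1000, keep_fraction=0.1, n_chains=1)
        trace = run_chain(gauss30_stats, cfg, seed=0)
        assert trace.n_retained == 100
        assert trace.log_posterior.shape == (1000,)
        assert trace.z_tally.sum(axis=1).tolist() == [100] * 30

    @pytest.mark.parametrize("backend", ["numba", "python"])
    def test_same_seed_bitwise_identical(self, gauss30_stats, backend):
        cfg = HidalgoConfig(K=2, n_sweeps=200, n_chains=1)
        a = run_chain(gauss30_stats, cfg, seed=7, backend=backend)
        b = run_chain(gauss30_stats, cfg, seed=7, backend=backend)
        np.testing.assert_array_equal(a.log_posterior, b.log_posterior)
        np.testing.assert_array_equal(a.d, b.d)
        np.testing.assert_array_equal(a.z_tally, b.z_tally)

    def test_no_trend_after_convergence(self):
        # K=1 chains are conjugate and converge immediately: the retained
        # log-posterior series should show no drift
        rng = np.random.default_rng(1)
        mu = (1.0 - rng.random(500)) ** (-1.0 / 4.0)
        stats = ring_stats(mu)
        cfg = HidalgoConfig(K=1, q=2, n_sweeps=5000, n_chains=1, seed=3)
        trace = run_chain(stats, cfg, seed=3)
        series = trace.retained_log_posterior
        result = linregress(np.arange(len(series)), series)
        assert result.pvalue > 0.01

    def test_backends_agree_in_distribution(self):
        # same posterior, different random streams: the K=1 posterior mean
        # of d must agree between the compiled kernel and the reference
        rng = np.random.default_rng(3)
        mu = (1.0 - rng.random(200)) ** (-1.0 / 5.0)
        stats = ring_stats(mu)
        cfg = HidalgoConfig(K=1, q=2, n_sweeps=3000, n_chains=1, seed=4)
        t_nb = run_chain(stats, cfg, seed=4, backend="numba")
        t_py = run_chain(stats, cfg, seed=4, backend="python")
        exact = (1.0 + 200) / (1.0 + np.log(mu).sum())
        assert t_nb.d.mean() == pytest.approx(exact, rel=0.05)
        assert t_py.d.mean() == pytest.approx(exact, rel=0.05)


class TestFit:
    def test_recovers_well_separated_manifolds(self):
        # dims 2 and 8, centers far apart: labels and dimensions recovered
        data = make_gaussian_pair(8, 2, n=500, center_offset=10.0, seed=0)
        stats = neighbor_stats(data.data, q=3)
        cfg = HidalgoConfig(K=2, n_sweeps=5000, n_chains=2, seed=1)
        res = fit(stats, cfg)
        assert nmi(res.labels, data.labels) > 0.95
        assert sorted(res.d_mean) == pytest.approx([2, 8], rel=0.2)

    def test_k1_reduces_to_closed_form(self):
        rng = np.random.default_rng(10)
        mu = (1.0 - rng.random(2000)) ** (-1.0 / 3.0)
        stats = ring_stats(mu)
        cfg = HidalgoConfig(K=1, q=2, n_sweeps=4000, n_chains=2, seed=0)
        res = fit(stats, cfg)
        shape, rate = 1.0 + 2000, 1.0 + np.log(mu).sum()
        assert res.d_mean[0] == pytest.approx(shape / rate, rel=0.02)
        assert res.d_sd[0] == pytest.approx(math.sqrt(shape) / rate, rel=0.3)

    def test_membership_contract(self, gauss30_stats):
        cfg = HidalgoConfig(K=3, n_sweeps=400, n_chains=2, seed=0)
        res = fit(gauss30_stats, cfg)
        np.testing.assert_allclose(res.pi.sum(axis=1), 1.0, atol=1e-12)
        assert set(np.unique(res.labels)) <= set(range(cfg.K + 1))
        confident = res.labels != UNASSIGNED
        assert np.all(res.pi.max(axis=1)[confident] > cfg.assignment_threshold)

    def test_best_chain_has_highest_mean_logpost(self, gauss30_stats):
        cfg = HidalgoConfig(K=2, n_sweeps=400, n_chains=3, seed=5)
        res = fit(gauss30_stats, cfg)
        means = res.diagnostics["mean_log_posterior"]
        assert means[res.best_chain] == max(means)
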