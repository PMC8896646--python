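import numpy as np
import pytest
from scipy import stats

from caconet.inference import (
    BanoccHyperparams,
    BanoccPosterior,
    BanoccState,
    _Posterior,
    draw_networks,
    log_posterior,
    posterior_median_network,
    precision_to_correlation,
    prepare_compositional,
    sample_posterior,
)
from caconet.io_otu import OtuTable


def _lognormal_table(rng, n, S, mu):
    X = np.exp(rng.multivariate_normal(mu, S, size=n))
    p = len(mu)
    return OtuTable([f"s{i}" for i in range(n)], [f"t{j}" for j in range(p)], X)


class TestPrecisionToCorrelation:
    def test_identity(self):
        np.testing.assert_allclose(precision_to_correlation(np.eye(3)), np.eye(3))

    def test_hand_example(self):
        # O = [[2,-1],[-1,2]] -> S = (1/3)[[2,1],[1,2]] -> R off-diagonal 0.5
        O = np.array([[2.0, -1.0], [-1.0, 2.0]])
        R = precision_to_correlation(O)
        np.testing.assert_allclose(R, [[1.0, 0.5], [0.5, 1.0]], atol=1e-12)

    def test_entries_bounded_and_unit_diagonal(self, rng):
        for _ in range(10):
            A = rng.standard_normal((5, 5))
            O = A @ A.T + 5 * np.eye(5)
            R = precision_to_correlation(O)
            assert np.all(np.abs(R) <= 1.0)
            np.testing.assert_array_equal(np.diag(R), 1.0)
            np.testing.assert_allclose(R, R.T)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            precision_to_correlation(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, rng):
        logC = np.log(rng.dirichlet(np.ones(4), size=12))
        post = _Posterior(logC, BanoccHyperparams())
        theta = rng.standard_normal(post.dim) * 0.3
        _, grad = post.logp_grad(theta)
        eps = 1e-6
        for i in rng.choice(post.dim, size=15, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (post.logp(tp) - post.logp(tm)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_univariate_closed_form(self):
        # p = 1: composition is identically 1, the latent scale u carries all
        # variation and the model is a univariate normal on u plus priors
        n = 6
        u = np.array([0.3, -0.2, 0.5, 0.0, 0.1, -0.4])
        table = OtuTable([f"s{i}" for i in range(n)], ["t0"], np.ones((n, 1)))
        m, o, lam = 0.2, 1.5, 2.0
        hyper = BanoccHyperparams()
        state = BanoccState(m=np.array([m]), O=np.array([[o]]), lam=lam)
        got = log_posterior(state, table, hyper, log_totals=u)
        s2 = 1.0 / o
        expected = (
            stats.norm.logpdf(u, loc=m, scale=np.sqrt(s2)).sum()
            + stats.norm.logpdf(m, 0.0, np.sqrt(10.0))
            + stats.expon.logpdf(o, scale=2.0 / lam)
            + stats.gamma.logpdf(lam, a=hyper.gamma_a, scale=1.0 / hyper.gamma_b)
            + stats.norm.logpdf(u, 0.0, hyper.scale_prior_sd).sum()
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_non_pd_precision_gives_minus_inf(self, small_table):
        state = BanoccState(
            m=np.zeros(6), O=np.eye(6) - 2 * np.ones((6, 6)) / 6, lam=1.0
        )
        assert log_posterior(state, small_table) == -np.inf

    def test_compositional_invariance_of_density(self, rng):
        X = rng.uniform(1.0, 10.0, size=(8, 3))
        t1 = OtuTable([f"s{i}" for i in range(8)], list("abc"), X)
        X2 = X.copy()
        X2[2] *= 37.5  # rescale one sample's raw abundances
        t2 = OtuTable([f"s{i}" for i in range(8)], list("abc"), X2)
        state = BanoccState(m=np.zeros(3), O=np.eye(3), lam=1.0)
        assert log_posterior(state, t1) == pytest.approx(log_posterior(state, t2))


class TestPrepareCompositional:
    def test_zero_replacement_and_renormalization(self):
        t = OtuTable(["s0"], list("abc"), np.array([[0.0, 1.0, 3.0]]))
        rel = prepare_compositional(t)
        assert np.all(rel > 0)
        assert rel.sum() == pytest.approx(1.0)

    def test_positive_input_untouched(self):
        t = OtuTable(["s0"], list("ab"), np.array([[1.0, 3.0]]))
        np.testing.assert_allclose(prepare_compositional(t), [[0.25, 0.75]])


class TestSampler:
    def test_correlation_recovery(self, rng):
        # two correlated features among ten: posterior median of R12 within
        # +-0.2 of the true 0.7 at n = 500
        p = 10
        S = np.eye(p)
        S[0, 1] = S[1, 0] = 0.7
        table = _lognormal_table(rng, 500, S, rng.normal(1.0, 1.5, p))
        post = sample_posterior(table, chains=2, warmup=400, iters=600, seed=7)
        r12 = float(np.median(post.R[:, 0, 1]))
        assert abs(r12 - 0.7) < 0.2

    def test_independent_features_calibration(self, rng):
        # 95% credible intervals of off-diagonal correlations cover 0
        p = 4
        table = _lognormal_table(rng, 400, np.eye(p), np.array([2.0, 1.0, 0.5, 1.5]))
        post = sample_posterior(table, chains=2, warmup=300, iters=300, seed=3)
        iu = np.triu_indices(p, 1)
        lo = np.quantile(post.R[:, iu[0], iu[1]], 0.025, axis=0)
        hi = np.quantile(post.R[:, iu[0], iu[1]], 0.975, axis=0)
        assert np.all(lo < 0) and np.all(hi > 0)

    def test_fixed_seed_reproducible(self, rng):
        table = _lognormal_table(rng, 60, np.eye(3), np.zeros(3))
        a = sample_posterior(table, chains=2, warmup=50, iters=50, seed=5)
        b = sample_posterior(table, chains=2, warmup=50, iters=50, seed=5)
        np.testing.assert_array_equal(a.R, b.R)
        np.testing.assert_array_equal(a.lam, b.lam)

    def test_posterior_invariant_to_sample_rescaling(self, rng):
        # multiplying one sample's raw abundances by a positive constant
        # leaves the entire posterior bit-identical under a fixed seed
        # (a power-of-two factor keeps the float normalization exact;
        # arbitrary factors agree to rounding error)
        X = rng.uniform(1.0, 50.0, size=(40, 3))
        t1 = OtuTable([f"s{i}" for i in range(40)], list("abc"), X)
        X2 = X.copy()
        X2[7] *= 1024.0
        t2 = OtuTable([f"s{i}" for i in range(40)], list("abc"), X2)
        a = sample_posterior(t1, chains=1, warmup=60, iters=60, seed=2)
        b = sample_posterior(t2, chains=1, warmup=60, iters=60, seed=2)
        np.testing.assert_array_equal(a.R, b.R)

    def test_diagnostics_present(self, rng):
        table = _lognormal_table(rng, 80, np.eye(3), np.zeros(3))
        post = sample_posterior(table, chains=2, warmup=80, iters=80, seed=1)
        assert {"max_rhat", "min_ess", "divergence_rate"} <= set(post.diagnostics)
        assert post.diagnostics["rhat"]["r"].size == 3

    def test_single_taxon_rejected(self):
        t = OtuTable(["s0", "s1"], ["a"], np.ones((2, 1)))
        with pytest.raises(ValueError, match="2 taxa"):
            sample_posterior(t)

    def test_shrinkage_monotonicity(self, rng):
        # a much larger prior shrinkage never increases the number of
        # |median R| > 0.2 edges on one fixed dataset
        p = 6
        S = np.eye(p)
        S[0, 1] = S[1, 0] = 0.6
        table = _lognormal_table(rng, 150, S, np.zeros(p))
        weak = sample_posterior(
            table, hyper=BanoccHyperparams(gamma_a=0.5, gamma_b=0.01),
            chains=1, warmup=200, iters=300, seed=4,
        )
        strong = sample_posterior(
            table, hyper=BanoccHyperparams(gamma_a=2000.0, gamma_b=1.0),
            chains=1, warmup=200, iters=300, seed=4,
        )
        def n_edges(post):
            med = np.abs(np.median(post.R, axis=0) - np.eye(p))
            return int(np.sum(med > 0.2) // 2)
        assert n_edges(strong) <= n_edges(weak)


class TestNetworkDraws:
    def _posterior(self, rng, n_draws=50, p=4):
        R = np.empty((n_draws, p, p))
        O = np.empty_like(R)
        for i in range(n_draws):
            A = rng.standard_normal((p, p)) * 0.3
            Oi = A @ A.T + 3 * np.eye(p)
            O[i] = Oi
            R[i] = precision_to_correlation(Oi)
        return BanoccPosterior(
            m=np.zeros((n_draws, p)), O=O, lam=np.ones(n_draws),
            R=R, taxon_ids=[f"t{j}" for j in range(p)], n_chains=1,
        )

    def test_draw_count_and_labels(self, rng):
        post = self._posterior(rng)
        nets = draw_networks(post, 800, label=1, seed=0)
        assert len(nets) == 800
        assert all(net.label == 1 for net in nets)

    def test_adjacency_symmetric_zero_diagonal(self, rng):
        post = self._posterior(rng)
        for net in draw_networks(post, 10, label=0, seed=1):
            np.testing.assert_allclose(net.adjacency, net.adjacency.T)
            np.testing.assert_array_equal(np.diag(net.adjacency), 0.0)

    def test_draws_vary_across_posterior(self, rng):
        post = self._posterior(rng)
        nets = draw_networks(post, 30, label=0, seed=2)
        stack = np.stack([net.adjacency for net in nets])
        assert stack.var(axis=0).max() > 0

    def test_median_network_thresholds(self, rng):
        post = self._posterior(rng)
        full = posterior_median_network(post, threshold=0.0)
        empty = posterior_median_network(post, threshold=1.0)
        assert np.count_nonzero(empty.adjacency) == 0
        med = np.median(post.R, axis=0)
        iu = np.triu_indices(4, 1)
        np.testing.assert_allclose(full.adjacency[iu], med[iu])

    def test_single_draw_median_is_that_draw(self, rng):
        post = self._posterior(rng, n_draws=1)
        net = posterior_median_network(post, threshold=0.0)
        expected = post.R[0].copy()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(net.adjacency, expected)
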