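"""Compositional-aware Bayesian correlation inference.

Observed relative abundances C (rows sum to 1) only determine the latent
log absolute abundances up to a per-sample additive constant:
log X_ij = log C_ij + u_i, with u_i the unknown log library size.  The
hierarchical model places a log-normal likelihood on the latent basis and
a graphical-LASSO prior on its precision matrix O:

    X_i ~ Log-normal(m, S),  S = O^{-1}
    m ~ N(n, L)
    O_jj ~ Exponential(rate lambda/2)
    O_jk ~ Laplace(location 0, rate lambda),  j != k
    lambda ~ Gamma(a, b)

The per-sample scale u_i is sampled jointly with (m, O), under a weak
normal prior, which makes the likelihood well defined on compositional
input and renders the whole posterior invariant to rescaling any sample's
raw abundances before normalization.

Sampling is Hamiltonian Monte Carlo within Gibbs.  Only the precision
matrix requires gradient-based updates: O is parameterized through its
Cholesky factor (log-transformed diagonal) so the HMC space is
unconstrained, with dual-averaging step-size adaptation and a diagonal
mass matrix estimated from an intermediate warmup window.  The remaining
blocks all have exact conjugate full conditionals drawn between
trajectories:

    lambda | O   ~ Gamma(a + p + p(p-1)/2,  b + tr(O)/2 + sum_{j<k}|O_jk|)
    m | O, u     ~ N( (nO + L^{-1})^{-1} (O sum_i y_i + L^{-1} n),
                      (nO + L^{-1})^{-1} )               with y_i = log C_i + u_i
    u_i | O, m   ~ N( -1'O(log C_i - m) / q,  1/q ),      q = 1'O1 + 1/tau^2

Blocking m, u and lambda out of the HMC state removes the flat
mean/scale ridge and the shrinkage funnel that cripple a joint HMC
update, and makes the leapfrog cost independent of the sample size.  The
correlation matrix of interest is R = D^{-1/2} O^{-1} D^{-1/2} with
D = diag(O^{-1}), computed per draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .graph_dataset import CorrelationNetwork
from .io_otu import OtuTable, to_relative_abundance

logger = logging.getLogger(__name__)


@dataclass
class BanoccHyperparams:
    """Hyperparameters of the hierarchical model.

    prior_mean_n / prior_cov_L: normal hyperprior on the log-basis mean m
    (defaults: zero vector, 10 * identity).
    gamma_a / gamma_b: shape and rate of the Gamma hyperprior on the
    shrinkage parameter lambda (defaults 0.5 and 0.01).
    scale_prior_sd: sd of the weak normal prior on the latent per-sample
    log scales u_i.
    """

    prior_mean_n: np.ndarray | None = None
    prior_cov_L: np.ndarray | None = None
    gamma_a: float = 0.5
    gamma_b: float = 0.01
    scale_prior_sd: float = 20.0

    def resolved(self, p: int) -> "BanoccHyperparams":
        n = np.zeros(p) if self.prior_mean_n is None else np.asarray(self.prior_mean_n, float)
        L = 10.0 * np.eye(p) if self.prior_cov_L is None else np.asarray(self.prior_cov_L, float)
        if n.shape != (p,):
            raise ValueError("prior_mean_n has wrong length")
        if L.shape != (p, p) or not np.allclose(L, L.T):
            raise ValueError("prior_cov_L must be a symmetric p x p matrix")
        if self.gamma_a <= 0 or self.gamma_b <= 0:
            raise ValueError("gamma_a and gamma_b must be positive")
        return BanoccHyperparams(n, L, self.gamma_a, self.gamma_b, self.scale_prior_sd)


@dataclass
class BanoccState:
    """One draw of the model parameters."""

    m: np.ndarray
    O: np.ndarray
    lam: float

    @property
    def S(self) -> np.ndarray:
        return np.linalg.inv(self.O)

    @property
    def R(self) -> np.ndarray:
        return precision_to_correlation(self.O)


@dataclass
class BanoccPosterior:
    """Post-warmup MCMC draws (all chains concatenated) plus diagnostics."""

    m: np.ndarray          # (draws, p)
    O: np.ndarray          # (draws, p, p)
    lam: np.ndarray        # (draws,)
    R: np.ndarray          # (draws, p, p)
    taxon_ids: list[str]
    n_chains: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.lam.size

    def state(self, i: int) -> BanoccState:
        return BanoccState(m=self.m[i], O=self.O[i], lam=float(self.lam[i]))


# --------------------------------------------------------------------------
# Zeros and the compositional input

def prepare_compositional(table: OtuTable, zero_fraction: float = 0.5) -> np.ndarray:
    """Return a strictly positive relative-abundance matrix.

    Zeros are replaced by ``zero_fraction`` times the smallest nonzero
    relative abundance in the table (a pseudo-fraction), then rows are
    renormalized to sum to 1.
    """
    rel = table.abundance if table.is_relative else to_relative_abundance(table).abundance
    rel = np.array(rel, dtype=float)
    if np.any(rel == 0):
        nz = rel[rel > 0]
        if nz.size == 0:
            raise ValueError("table contains no nonzero abundances")
        rel[rel == 0] = zero_fraction * nz.min()
        rel /= rel.sum(axis=1, keepdims=True)
    return rel


# --------------------------------------------------------------------------
# Log posterior and gradient on the unconstrained space
#
# HMC state: theta = [m (p), tril(T) row-major with log-diagonal
# (p(p+1)/2), u (n)] with O = T T', T lower triangular, diag(T) > 0;
# lambda is held fixed within a trajectory and Gibbs-updated between
# trajectories.  The change of variables O -> T -> unconstrained adds the
# log-Jacobian sum_j (p - j + 1) log T_jj (Cholesky, 1-based j) plus
# sum_j log T_jj (log-diagonal).


def _unpack(theta: np.ndarray, p: int, n: int):
    m = theta[:p]
    ntri = p * (p + 1) // 2
    tvec = theta[p : p + ntri]
    u = theta[p + ntri :]
    assert u.size == n
    T = np.zeros((p, p))
    il = np.tril_indices(p)
    T[il] = tvec
    diag = np.exp(np.clip(np.diag(T), -30.0, 30.0))
    T[np.diag_indices(p)] = diag
    return m, T, u


def _pack(m: np.ndarray, T: np.ndarray, u: np.ndarray) -> np.ndarray:
    p = m.size
    Tl = T.copy()
    Tl[np.diag_indices(p)] = np.log(np.diag(T))
    return np.concatenate([m, Tl[np.tril_indices(p)], u])


class _Posterior:
    """Log density and gradient of (m, T, u) given lambda, for fixed data."""

    def __init__(self, logC: np.ndarray, hyper: BanoccHyperparams):
        self.logC = logC
        self.n, self.p = logC.shape
        self.hyper = hyper.resolved(self.p)
        self.Linv = np.linalg.inv(self.hyper.prior_cov_L)
        p = self.p
        # Jacobian exponents for the Cholesky + log-diag transform
        self._jac_exp = (p - np.arange(p)) + 1.0  # (p - j + 1) + 1, 0-based j
        self._tau2 = self.hyper.scale_prior_sd**2
        self.lam = self.hyper.gamma_a / self.hyper.gamma_b

    @property
    def dim(self) -> int:
        return self.p + self.p * (self.p + 1) // 2 + self.n

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore"):
            logp, grad = self._logp_grad_impl(theta)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(theta)
        return logp, grad

    def _logp_grad_impl(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        p, n, lam = self.p, self.n, self.lam
        m, T, u = _unpack(theta, p, n)
        diagT = np.diag(T)

        O = T @ T.T
        Y = self.logC + u[:, None]
        E = Y - m[None, :]
        CE = E.T @ E

        off = ~np.eye(p, dtype=bool)
        abs_off_sum = np.abs(O[off]).sum() / 2.0  # each pair once
        diag_sum = np.trace(O)

        logdetO = 2.0 * np.log(diagT).sum()
        quad = float(np.sum((CE @ T) * T))  # tr(T' CE T) = tr(O CE)
        loglik = 0.5 * n * logdetO - 0.5 * quad

        dm = m - self.hyper.prior_mean_n
        lp_m = -0.5 * float(dm @ self.Linv @ dm)
        # lambda-dependent normalization constants are irrelevant within a
        # fixed-lambda HMC update but harmless to include
        lp_O = -(lam / 2.0) * diag_sum - lam * abs_off_sum
        lp_u = -0.5 * float(u @ u) / self._tau2
        jac = float(self._jac_exp @ np.log(diagT))

        logp = loglik + lp_m + lp_O + lp_u + jac

        # ---- gradients ----
        grad_m = O @ E.sum(axis=0) - self.Linv @ dm
        grad_u = -(E @ O).sum(axis=1) - u / self._tau2

        # dL/dT from likelihood: n * diag(1/T_jj) - CE @ T
        GT = -CE @ T
        GT[np.diag_indices(p)] += n / diagT
        # prior on O: for P = sum_j a_j(O_jj) + sum_{j>k} b_jk(O_jk),
        # dP/dT = M T with M symmetric, M_jj = 2 a'_j, M_jk = b'_jk
        M = -lam * np.sign(O)
        M[np.diag_indices(p)] = -lam
        GT += M @ T
        # Jacobian diagonal, then chain rule for the log-diagonal transform
        GT[np.diag_indices(p)] += self._jac_exp / diagT
        GT[np.diag_indices(p)] *= diagT
        grad_T = GT[np.tril_indices(p)]

        return float(logp), np.concatenate([grad_m, grad_T, grad_u])

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]


def log_posterior(
    state: BanoccState,
    data: OtuTable,
    hyper: BanoccHyperparams | None = None,
    log_totals: np.ndarray | None = None,
) -> float:
    """Joint log density (up to an additive constant) of one state.

    ``log_totals`` holds the latent per-sample log scales u (defaults to
    zeros).  A non-positive-definite precision matrix yields -inf rather
    than raising, matching the support of the prior.
    """
    hyper = (hyper or BanoccHyperparams()).resolved(len(data.taxon_ids))
    logC = np.log(prepare_compositional(data))
    n, p = logC.shape
    if log_totals is None:
        log_totals = np.zeros(n)
    log_totals = np.asarray(log_totals, float)
    if log_totals.shape != (n,):
        raise ValueError("log_totals must have one entry per sample")
    O = np.asarray(state.O, float)
    if not np.allclose(O, O.T, atol=1e-8):
        return -np.inf
    try:
        T = np.linalg.cholesky(O)
    except np.linalg.LinAlgError:
        return -np.inf
    lam = float(state.lam)
    if lam <= 0:
        return -np.inf
    post = _Posterior(logC, hyper)
    post.lam = lam
    theta = _pack(np.asarray(state.m, float), T, log_totals)
    logp, _ = post.logp_grad(theta)
    if not np.isfinite(logp):
        return -np.inf
    # remove the change-of-variable Jacobian (density of the state itself,
    # not of the unconstrained vector), then add the lambda prior and every
    # normalization constant so the result is the fully normalized joint
    from scipy.special import gammaln

    jac = float(post._jac_exp @ np.log(np.diag(T)))
    a, b = hyper.gamma_a, hyper.gamma_b
    npairs = p * (p - 1) // 2
    lp_lam = (
        (p + npairs) * np.log(lam / 2.0)              # Exp + Laplace rates
        + a * np.log(b) - gammaln(a)                  # Gamma(a, b)
        + (a - 1.0) * np.log(lam) - b * lam
    )
    tau2 = hyper.scale_prior_sd**2
    const = (
        -0.5 * n * p * np.log(2 * np.pi)              # likelihood
        - 0.5 * (p * np.log(2 * np.pi) + np.linalg.slogdet(hyper.prior_cov_L)[1])
        - 0.5 * n * np.log(2 * np.pi * tau2)          # latent scales
    )
    return logp - jac + lp_lam + const


# --------------------------------------------------------------------------
# Hamiltonian Monte Carlo within Gibbs

class _PrecisionConditional:
    """Conditional log density / gradient of tril(T) given (m, u, lambda).

    With E = Y - 1 m' fixed, the conditional is
    0.5 n log det O - 0.5 tr(O E'E) - (lam/2) tr(O) - lam sum_{j<k} |O_jk|
    plus the Cholesky/log-diag Jacobian.
    """

    def __init__(self, p: int, n: int):
        self.p, self.n = p, n
        self._jac_exp = (p - np.arange(p)) + 1.0
        self._il = np.tril_indices(p)
        self._dg = np.diag_indices(p)
        self.CE = np.eye(p)
        self.lam = 1.0

    @property
    def dim(self) -> int:
        return self.p * (self.p + 1) // 2

    def unpack(self, tvec: np.ndarray) -> np.ndarray:
        T = np.zeros((self.p, self.p))
        T[self._il] = tvec
        T[self._dg] = np.exp(np.clip(T[self._dg], -30.0, 30.0))
        return T

    def pack(self, T: np.ndarray) -> np.ndarray:
        Tl = T.copy()
        Tl[self._dg] = np.log(T[self._dg])
        return Tl[self._il]

    def logp_grad(self, tvec: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore"):
            logp, grad = self._impl(tvec)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(tvec)
        return logp, grad

    def _impl(self, tvec):
        p, n, lam = self.p, self.n, self.lam
        T = self.unpack(tvec)
        diagT = T[self._dg]
        O = T @ T.T
        off = ~np.eye(p, dtype=bool)
        abs_off_sum = np.abs(O[off]).sum() / 2.0
        logp = (
            0.5 * n * 2.0 * np.log(diagT).sum()
            - 0.5 * float(np.sum((self.CE @ T) * T))
            - (lam / 2.0) * np.trace(O)
            - lam * abs_off_sum
            + float(self._jac_exp @ np.log(diagT))
        )
        GT = -self.CE @ T
        M = -lam * np.sign(O)
        M[self._dg] = -lam
        GT += M @ T
        GT[self._dg] += (n + self._jac_exp) / diagT
        GT[self._dg] *= diagT
        return float(logp), GT[self._il]

    def logp(self, tvec: np.ndarray) -> float:
        return self.logp_grad(tvec)[0]


def _leapfrog(post, theta, r, eps, n_steps, inv_mass):
    logp, grad = post.logp_grad(theta)
    r = r + 0.5 * eps * grad
    for s in range(n_steps):
        theta = theta + eps * inv_mass * r
        logp, grad = post.logp_grad(theta)
        if not np.isfinite(logp):
            return theta, r, -np.inf, grad
        r = r + (eps if s < n_steps - 1 else 0.5 * eps) * grad
    return theta, r, logp, grad


def _find_initial_step(post, theta, rng, inv_mass, eps=1.0):
    """Halve/double the step size until a single leapfrog step changes the
    Hamiltonian by roughly log(2) (cheap Stan-style heuristic)."""
    logp0 = post.logp(theta)
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * float((r0 * inv_mass) @ r0)

    def delta_h(e):
        _, r1, logp1, _ = _leapfrog(post, theta, r0, e, 1, inv_mass)
        if not np.isfinite(logp1):
            return -np.inf
        return (logp1 - 0.5 * float((r1 * inv_mass) @ r1)) - h0

    d = delta_h(eps)
    direction = 1 if d > np.log(0.5) else -1
    for _ in range(50):
        eps_new = eps * (2.0 if direction == 1 else 0.5)
        d = delta_h(eps_new)
        ok = d > np.log(0.5)
        if (direction == 1 and not ok) or (direction == -1 and ok):
            return eps_new if direction == -1 else eps
        eps = eps_new
    return eps


def _gibbs_lambda(O, hyper, rng) -> float:
    p = O.shape[0]
    off = ~np.eye(p, dtype=bool)
    shape = hyper.gamma_a + p + p * (p - 1) / 2.0
    rate = hyper.gamma_b + 0.5 * np.trace(O) + np.abs(O[off]).sum() / 2.0
    return float(rng.gamma(shape, 1.0 / rate))


def _gibbs_mean(O, logC, hyper, Linv, tau2, rng) -> np.ndarray:
    """Exact draw of m | O with the latent scales u marginalized out.

    Marginally log C_i ~ N(m, S + tau^2 11'), whose precision by Woodbury is
    W = O - tau^2 (O1)(O1)' / (1 + tau^2 1'O1); drawing m from this
    u-marginalized conditional (then u | m exactly) is a joint (m, u) block
    update, which sidesteps the slow mean/scale ridge of coordinate-wise
    Gibbs.
    """
    n, p = logC.shape
    Orow = O.sum(axis=0)
    s = float(Orow.sum())
    W = O - (tau2 / (1.0 + tau2 * s)) * np.outer(Orow, Orow)
    P = n * W + Linv
    Lp = np.linalg.cholesky(P)
    b = W @ logC.sum(axis=0) + Linv @ hyper.prior_mean_n
    mean = linalg.cho_solve((Lp, True), b)
    z = rng.standard_normal(p)
    return mean + linalg.solve_triangular(Lp, z, lower=True, trans="T")


def _gibbs_scales(O, m, logC, tau2, rng) -> np.ndarray:
    Orow = O.sum(axis=0)  # O 1
    q = float(Orow.sum()) + 1.0 / tau2  # 1'O1 + 1/tau^2
    d = logC - m[None, :]
    mean = -(d @ Orow) / q
    return mean + rng.standard_normal(logC.shape[0]) / np.sqrt(q)


def _hmc_chain(logC, hyper, theta0, warmup, iters, seed, target_accept=0.8,
               n_leapfrog=(8, 16), adapt_mass=False):
    """One HMC-within-Gibbs chain.

    HMC updates tril(T) given (m, u, lambda); m, u and lambda are then
    refreshed from their exact conjugate conditionals.  Returns arrays of
    post-warmup draws (m, O, lambda) and the divergence count.

    The mass matrix is the identity by default: the Cholesky coordinates
    share units and curvature, and a diagonal metric estimated from a
    pre-convergence warmup window can freeze the weakly identified
    directions of the compositional posterior.
    """
    n, p = logC.shape
    rng = np.random.default_rng(seed)
    cond = _PrecisionConditional(p, n)
    tau2 = hyper.scale_prior_sd**2
    Linv = np.linalg.inv(hyper.prior_cov_L)

    m, T, u = _unpack(theta0, p, n)
    tvec = cond.pack(T)
    O = T @ T.T
    cond.lam = _gibbs_lambda(O, hyper, rng)

    def refresh_CE():
        E = logC + u[:, None] - m[None, :]
        cond.CE = E.T @ E

    refresh_CE()
    inv_mass = np.ones(cond.dim)
    eps = _find_initial_step(cond, tvec, rng, inv_mass)
    mu_da = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    window: list[np.ndarray] = []
    window_start, window_end = warmup // 4, (3 * warmup) // 4
    m_draws = np.empty((iters, p))
    O_draws = np.empty((iters, p, p))
    lam_draws = np.empty(iters)
    divergences = 0

    for it in range(warmup + iters):
        logp = cond.logp(tvec)
        r0 = rng.standard_normal(cond.dim) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(n_leapfrog[0], n_leapfrog[1] + 1))
        h0 = logp - 0.5 * float((r0 * inv_mass) @ r0)
        tvec_new, r_new, logp_new, _ = _leapfrog(cond, tvec, r0, eps, n_steps, inv_mass)
        if np.isfinite(logp_new):
            h1 = logp_new - 0.5 * float((r_new * inv_mass) @ r_new)
            accept_prob = float(np.exp(min(0.0, h1 - h0)))
            diverged = h0 - h1 > 1000.0
        else:
            accept_prob = 0.0
            diverged = True
        if rng.random() < accept_prob:
            tvec = tvec_new
        T = cond.unpack(tvec)
        O = T @ T.T

        # exact conditional updates; (m, u) drawn as one block
        cond.lam = _gibbs_lambda(O, hyper, rng)
        m = _gibbs_mean(O, logC, hyper, Linv, tau2, rng)
        u = _gibbs_scales(O, m, logC, tau2, rng)
        refresh_CE()

        if it < warmup:
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar + (target_accept - accept_prob) / (da_count + t0)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if adapt_mass and window_start <= it < window_end:
                window.append(tvec.copy())
            if adapt_mass and it == window_end - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                inv_mass = np.maximum(var, 1e-8)
                # restart step-size adaptation under the new metric
                eps = _find_initial_step(cond, tvec, rng, inv_mass)
                mu_da = np.log(10 * eps)
                h_bar, log_eps_bar, da_count = 0.0, 0.0, 0
            if it == warmup - 1 and da_count > 0:
                eps = float(np.exp(log_eps_bar))
        else:
            if diverged:
                divergences += 1
            k = it - warmup
            m_draws[k] = m
            O_draws[k] = O
            lam_draws[k] = cond.lam
    return m_draws, O_draws, lam_draws, divergences


def sample_posterior(
    data: OtuTable,
    hyper: BanoccHyperparams | None = None,
    chains: int = 2,
    warmup: int = 300,
    iters: int = 300,
    seed: int = 0,
    max_divergence_rate: float = 0.10,
) -> BanoccPosterior:
    """Sample the posterior over (m, O, lambda, u) by adaptive HMC-within-Gibbs.

    Returns post-warmup draws from all chains with split R-hat and bulk
    effective sample size diagnostics (computed on m, lambda and the
    correlation entries).  Raises if the post-warmup divergence rate
    exceeds ``max_divergence_rate``.
    """
    hyper = (hyper or BanoccHyperparams()).resolved(len(data.taxon_ids))
    logC = np.log(prepare_compositional(data))
    n, p = logC.shape
    if p < 2:
        raise ValueError("need at least 2 taxa for correlation inference")
    if n < p:
        logger.warning("fewer samples (%d) than taxa (%d); posterior may be diffuse", n, p)

    # initialization: center each sample, moment-match m and O
    u0 = -logC.mean(axis=1)
    Y0 = logC + u0[:, None]
    m0 = Y0.mean(axis=0)
    cov = np.cov(Y0, rowvar=False) if n > 1 else np.eye(p)
    cov = np.atleast_2d(cov) + 0.1 * np.eye(p) * max(1.0, float(np.trace(np.atleast_2d(cov))) / p)
    O0 = np.linalg.inv(cov)
    T0 = np.linalg.cholesky(O0)
    theta0 = _pack(m0, T0, u0)

    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(chains)]
    m_d = np.empty((chains, iters, p))
    O_d = np.empty((chains, iters, p, p))
    lam_d = np.empty((chains, iters))
    R_d = np.empty((chains, iters, p, p))
    total_div = 0
    for c in range(chains):
        m_c, O_c, lam_c, div = _hmc_chain(logC, hyper, theta0, warmup, iters, chain_seeds[c])
        m_d[c], O_d[c], lam_d[c] = m_c, O_c, lam_c
        total_div += div
        for i in range(iters):
            R_d[c, i] = precision_to_correlation(O_c[i])
    div_rate = total_div / (chains * iters)
    if div_rate > max_divergence_rate:
        raise RuntimeError(
            f"HMC divergence rate {div_rate:.1%} exceeds {max_divergence_rate:.0%}; "
            "consider longer warmup or a reparameterization"
        )

    diagnostics = _diagnostics(m_d, lam_d, R_d)
    diagnostics["divergence_rate"] = div_rate
    if diagnostics["max_rhat"] > 1.05:
        logger.warning(
            "convergence warning: max split R-hat %.3f > 1.05", diagnostics["max_rhat"]
        )

    def flat(x):
        return x.reshape((chains * iters,) + x.shape[2:])

    return BanoccPosterior(
        m=flat(m_d), O=flat(O_d), lam=flat(lam_d), R=flat(R_d),
        taxon_ids=list(data.taxon_ids), n_chains=chains, diagnostics=diagnostics,
    )


def _diagnostics(m_d, lam_d, R_d) -> dict:
    import arviz as az

    p = m_d.shape[-1]
    iu = np.triu_indices(p, k=1)
    data = {
        "m": m_d,
        "lam": lam_d,
        "r": R_d[:, :, iu[0], iu[1]],
    }
    if m_d.shape[0] < 2:
        # split R-hat and rank-normalized ESS need at least two chains
        nan = {k: np.full(np.shape(v)[2:] or (), np.nan) for k, v in data.items()}
        return {"max_rhat": np.nan, "min_ess": np.nan, "rhat": nan, "ess": nan}
    ds = az.convert_to_dataset(data)
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    max_rhat = max(float(np.nanmax(rhat[k].values)) for k in data)
    min_ess = min(float(np.nanmin(ess[k].values)) for k in data)
    return {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "rhat": {k: np.asarray(rhat[k].values) for k in data},
        "ess": {k: np.asarray(ess[k].values) for k in data},
    }


# --------------------------------------------------------------------------
# Posterior -> correlation networks

def precision_to_correlation(O: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a positive-definite precision matrix:
    R = D^{-1/2} O^{-1} D^{-1/2}, D = diag(O^{-1}); unit diagonal exactly."""
    O = np.asarray(O, float)
    if not np.allclose(O, O.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    try:
        c, lower = linalg.cho_factor(O, lower=True)
    except linalg.LinAlgError:
        raise ValueError("precision matrix must be positive definite")
    S = linalg.cho_solve((c, lower), np.eye(O.shape[0]))
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def draw_networks(
    posterior: BanoccPosterior, n_draws: int, label: int, seed: int = 0
) -> list[CorrelationNetwork]:
    """Sample labeled correlation networks from the stored posterior draws
    (without replacement when possible, with replacement otherwise).
    Adjacency = that draw's R with the diagonal zeroed."""
    if posterior.n_draws == 0:
        raise ValueError("posterior holds no draws")
    rng = np.random.default_rng(seed)
    replace_flag = n_draws > posterior.n_draws
    idx = rng.choice(posterior.n_draws, size=n_draws, replace=replace_flag)
    nets = []
    for i in idx:
        A = posterior.R[i].copy()
        np.fill_diagonal(A, 0.0)
        nets.append(CorrelationNetwork(taxon_ids=posterior.taxon_ids, adjacency=A, label=label))
    return nets


def save_posterior(posterior: BanoccPosterior, prefix) -> None:
    """Serialize draws as a compressed archive plus a JSON diagnostics report."""
    import json

    np.savez_compressed(
        f"{prefix}.npz", m=posterior.m, O=posterior.O, lam=posterior.lam, R=posterior.R
    )
    report = {
        "taxon_ids": posterior.taxon_ids,
        "n_chains": posterior.n_chains,
        "n_draws": posterior.n_draws,
        "max_rhat": posterior.diagnostics.get("max_rhat"),
        "min_ess": posterior.diagnostics.get("min_ess"),
        "divergence_rate": posterior.diagnostics.get("divergence_rate"),
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(report, fh, indent=2)


def load_posterior(prefix) -> BanoccPosterior:
    import json

    arrays = np.load(f"{prefix}.npz")
    with open(f"{prefix}.json") as fh:
        report = json.load(fh)
    diag = {k: report[k] for k in ("max_rhat", "min_ess", "divergence_rate")}
    return BanoccPosterior(
        m=arrays["m"], O=arrays["O"], lam=arrays["lam"], R=arrays["R"],
        taxon_ids=report["taxon_ids"], n_chains=report["n_chains"], diagnostics=diag,
    )


def posterior_median_network(
    posterior: BanoccPosterior, threshold: float = 0.0, label: int | None = None
) -> CorrelationNetwork:
    """Element-wise posterior median correlation network, keeping edges with
    |median| strictly above ``threshold``."""
    if posterior.n_draws == 0:
        raise ValueError("posterior holds no draws")
    med = np.median(posterior.R, axis=0)
    A = np.where(np.abs(med) > threshold, med, 0.0)
    np.fill_diagonal(A, 0.0)
    return CorrelationNetwork(taxon_ids=posterior.taxon_ids, adjacency=A, label=label)
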