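"""Gibbs samplers for Bayesian whole-genome marker-effect regression.

All three methods share the linear model

    y = mu * 1 + X beta + e,        e ~ N(0, sigma2_e I)

with a flat prior on ``mu`` and a scale-invariant ``1/sigma2_e`` prior on
the residual variance, and differ only in the second level of the
hierarchy on the marker effects ``beta_j ~ N(0, v_j)``:

* ``bayes_a``   — v_j ~ scaled-Inv-chi2(v, s2), v and s2 fixed
  hyperparameters; the marginal prior on beta_j is a fixed-tail Student t.
* ``student_t`` — as Bayes-A but v and s2 are estimated: 1/v is uniform on
  (0, 1] and s uniform on (0, A], so the data control the shrinkage.
* ``lasso``     — v_j (tau2_j) ~ Exponential(lambda2/2) with
  lambda2 ~ Gamma(a, b); the marginal prior on beta_j is Laplace, i.e. a
  Bayesian lasso.  The per-marker variance is *not* scaled by sigma2_e,
  so unimodality of the joint posterior is not guaranteed.

One iteration draws, in order: mu; every beta_j by Gauss-Seidel with
residual update (never forming an m x m system); sigma2_e; the per-marker
variance layer; and the method-specific hyperparameters.  Chains are
deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

try:
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

METHODS = ("bayes_a", "student_t", "lasso")

_BETA_FLOOR = 1e-8      # |beta_j| floor before the inverse-Gaussian mean
_SSE_FLOOR = 1e-12      # degenerate zero-residual guard


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ChainConfig:
    """Chain settings and method hyperparameters.

    Defaults follow the reference analysis protocol: a single chain of
    15000 iterations, 5500 burn-in, storing every 30th state.  ``v``/``s2``
    are the Bayes-A scaled-Inv-chi2 hyperparameters (``s2=None`` derives
    the scale from the expected per-marker variance heuristic);
    ``A_upper`` bounds the uniform prior on s in the Student-t model
    (``None`` -> 1000 * sd(y)); ``a``/``b`` are the Gamma prior on
    lambda2 for the lasso.
    """

    method: str = "bayes_a"
    n_iter: int = 15000
    burn_in: int = 5500
    thin: int = 30
    seed: int = 0
    # Bayes-A / Student-t
    v: float = 4.012
    s2: float | None = None
    expected_marker_var: float | None = None
    # Student-t
    A_upper: float | None = None
    metropolis_step: float = 0.05
    # Lasso
    a: float = 0.05
    b: float = 1.0
    # proper-prior surrogates (None = the improper defaults above)
    mu_prior_var: float | None = None
    sigma2_e_prior: tuple[float, float] | None = None  # (nu0, s0_sq)
    # freezing hooks for closed-form validation
    fix_mu: float | None = None
    fix_sigma2_e: float | None = None
    fix_var_beta: float | np.ndarray | None = None
    fix_hyper: bool = False
    permute_order: bool = False
    store_beta: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("lasso Gamma prior parameters must be positive")
        if self.v <= 0 or (self.s2 is not None and self.s2 <= 0):
            raise ValueError("v and s2 must be positive")


@dataclass
class SamplerState:
    """All unknowns of one chain plus the fixed data it conditions on.

    ``e`` is maintained incrementally as ``y - mu - X beta`` by every
    update; ``resync`` recomputes it from scratch to shed rounding drift.
    """

    y: np.ndarray
    X: np.ndarray               # Fortran-ordered n x m codes
    config: ChainConfig
    rng: np.random.Generator
    mu: float
    beta: np.ndarray
    e: np.ndarray
    sigma2_e: float
    var_beta: np.ndarray        # sigma2_beta_j (Bayes-A/t) or tau2_j (lasso)
    v: float
    s2: float
    lambda2: float
    xtx: np.ndarray = field(default=None)  # cached column sums of squares
    accept_v: int = 0
    propose_v: int = 0

    def __post_init__(self) -> None:
        if self.xtx is None:
            self.xtx = np.einsum("ij,ij->j", self.X, self.X)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def resync(self) -> None:
        self.e = self.y - self.mu - self.X @ self.beta

    def residual_error(self) -> float:
        return float(np.max(np.abs(self.e - (self.y - self.mu - self.X @ self.beta))))


@dataclass
class PosteriorSummary:
    """Posterior means over the stored post-burn-in states, plus the
    thinned samples themselves and convergence diagnostics."""

    method: str
    mu_mean: float
    beta_mean: np.ndarray
    var_beta_mean: np.ndarray
    sigma2_e_mean: float
    v_mean: float | None
    s2_mean: float | None
    lambda2_mean: float | None
    samples: dict
    ess: dict
    accept_rate_v: float | None
    n_stored: int


# ---------------------------------------------------------------------------
# Gauss-Seidel marker sweep (step 2)
# ---------------------------------------------------------------------------

def _gs_sweep_py(X, xtx, e, beta, var_beta, sigma2_e, z, order):
    for j in order:
        xj = X[:, j]
        bj = beta[j]
        rhs = (xj @ e + xtx[j] * bj) / sigma2_e
        if xtx[j] > 0.0:
            cj = xtx[j] / sigma2_e + 1.0 / var_beta[j]
            newb = rhs / cj + z[j] / math.sqrt(cj)
        else:
            newb = math.sqrt(var_beta[j]) * z[j]
        if bj != newb:
            e += xj * (bj - newb)
        beta[j] = newb


if _HAVE_NUMBA:

    @njit(cache=False)
    def _gs_sweep_nb(X, xtx, e, beta, var_beta, sigma2_e, z, order):  # pragma: no cover
        n = e.shape[0]
        for t in range(order.shape[0]):
            j = order[t]
            bj = beta[j]
            dot = 0.0
            for i in range(n):
                dot += X[i, j] * e[i]
            rhs = (dot + xtx[j] * bj) / sigma2_e
            if xtx[j] > 0.0:
                cj = xtx[j] / sigma2_e + 1.0 / var_beta[j]
                newb = rhs / cj + z[j] / math.sqrt(cj)
            else:
                newb = math.sqrt(var_beta[j]) * z[j]
            diff = bj - newb
            if diff != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * diff
            beta[j] = newb

    _gs_sweep = _gs_sweep_nb
else:  # pragma: no cover
    _gs_sweep = _gs_sweep_py


def draw_beta_gauss_seidel(state: SamplerState) -> None:
    """One sweep over all markers in fixed (or permuted) order.

    Each beta_j is drawn from its univariate normal full conditional
    N(C_j^-1 r_j, C_j^-1), C_j = x_j'x_j/sigma2_e + 1/var_beta_j, with the
    residual vector updated in place; a zero-variance column falls back to
    its prior.
    """
    m = state.m
    if state.config.permute_order:
        order = state.rng.permutation(m).astype(np.int64)
    else:
        order = np.arange(m, dtype=np.int64)
    z = state.rng.standard_normal(m)
    _gs_sweep(state.X, state.xtx, state.e, state.beta, state.var_beta,
              state.sigma2_e, z, order)


# ---------------------------------------------------------------------------
# Remaining conditional draws (steps 1, 3, 4)
# ---------------------------------------------------------------------------

def draw_mu(state: SamplerState) -> None:
    """Overall mean: flat prior by default, N(0, mu_prior_var) surrogate
    when a proper prior is requested."""
    cfg = state.config
    if cfg.fix_mu is not None:
        return
    e_part = state.e + state.mu
    if cfg.mu_prior_var is None:
        post_var = state.sigma2_e / state.n
        post_mean = float(np.mean(e_part))
    else:
        prec = state.n / state.sigma2_e + 1.0 / cfg.mu_prior_var
        post_var = 1.0 / prec
        post_mean = float(np.sum(e_part)) / state.sigma2_e * post_var
    new_mu = state.rng.normal(post_mean, math.sqrt(post_var))
    state.e = e_part - new_mu
    state.mu = float(new_mu)


def draw_sigma_e(state: SamplerState) -> None:
    """Residual variance: scaled-Inv-chi2(n, e'e/n) under the 1/sigma2_e
    prior, or scaled-Inv-chi2(n+nu0, (e'e+nu0*s0^2)/(n+nu0)) with a proper
    surrogate."""
    cfg = state.config
    if cfg.fix_sigma2_e is not None:
        return
    sse = float(state.e @ state.e)
    if cfg.sigma2_e_prior is None:
        df, scale_sum = state.n, sse
    else:
        nu0, s0_sq = cfg.sigma2_e_prior
        df, scale_sum = state.n + nu0, sse + nu0 * s0_sq
    draw = scale_sum / state.rng.chisquare(df)
    state.sigma2_e = max(float(draw), _SSE_FLOOR)


def draw_snp_variance_invchisq(state: SamplerState, j: int | None = None) -> None:
    """Bayes-A / Student-t per-marker variance layer:
    sigma2_beta_j ~ scaled-Inv-chi2(v+1, (v*s2 + beta_j^2)/(v+1))."""
    if state.config.method not in ("bayes_a", "student_t"):
        raise ValueError("inverse-chi-square layer applies to bayes_a/student_t")
    if state.config.fix_var_beta is not None:
        return
    if j is None:
        num = state.v * state.s2 + state.beta ** 2
        state.var_beta = num / state.rng.chisquare(state.v + 1.0, size=state.m)
    else:
        num = state.v * state.s2 + state.beta[j] ** 2
        state.var_beta[j] = num / state.rng.chisquare(state.v + 1.0)


def _rand_inverse_gaussian(mean: np.ndarray, shape: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Michael-Schucany-Haas inverse-Gaussian sampler."""
    nu2 = rng.standard_normal(size=mean.shape) ** 2
    x = (mean + mean ** 2 * nu2 / (2.0 * shape)
         - mean / (2.0 * shape) * np.sqrt(4.0 * mean * shape * nu2
                                          + (mean * nu2) ** 2))
    u = rng.random(size=mean.shape)
    return np.where(u <= mean / (mean + x), x, mean ** 2 / x)


def draw_lasso_layer(state: SamplerState) -> None:
    """Lasso layer: 1/tau2_j ~ InvGauss(sqrt(lambda2)/|beta_j|, lambda2),
    then lambda2 ~ Gamma(a + m, b + sum(tau2)/2)."""
    cfg = state.config
    if cfg.method != "lasso":
        raise ValueError("lasso layer requested for a non-lasso chain")
    if cfg.fix_var_beta is None:
        absb = np.maximum(np.abs(state.beta), _BETA_FLOOR)
        ig_mean = math.sqrt(state.lambda2) / absb
        inv_tau2 = _rand_inverse_gaussian(ig_mean, state.lambda2, state.rng)
        state.var_beta = 1.0 / np.maximum(inv_tau2, _SSE_FLOOR)
    if not cfg.fix_hyper:
        shape = cfg.a + state.m
        rate = cfg.b + float(np.sum(state.var_beta)) / 2.0
        state.lambda2 = float(state.rng.gamma(shape, 1.0 / rate))


def _loglik_v(v: float, s2: float, sum_log_var: float, sum_inv_var: float,
              m: int) -> float:
    """Log full conditional of the Student-t degrees of freedom (terms in v
    only), for {sigma2_beta_j} ~ scaled-Inv-chi2(v, s2)."""
    half_v = 0.5 * v
    return (m * half_v * math.log(half_v * s2) - m * gammaln(half_v)
            - half_v * sum_log_var - half_v * s2 * sum_inv_var)


def draw_student_t_s2(state: SamplerState) -> None:
    """s2 | v, {sigma2_beta_j}: a Gamma-form full conditional with shape
    m*v/2 + 1/2 (the 1/2 comes from the uniform-on-s prior), truncated at
    A^2, sampled by inverse CDF."""
    cfg = state.config
    sum_inv = float(np.sum(1.0 / state.var_beta))
    A = cfg.A_upper if cfg.A_upper is not None else 1e3 * math.sqrt(
        max(np.var(state.y), _SSE_FLOOR))
    shape = state.m * state.v / 2.0 + 0.5
    rate = state.v * sum_inv / 2.0
    upper = A * A
    cdf_hi = stats.gamma.cdf(upper, shape, scale=1.0 / rate)
    if cdf_hi <= 0.0:
        state.s2 = upper
    else:
        u = state.rng.random() * cdf_hi
        s2 = float(stats.gamma.ppf(u, shape, scale=1.0 / rate))
        state.s2 = min(max(s2, _SSE_FLOOR), upper)


def metropolis_v_step(state: SamplerState) -> None:
    """v | s2, {sigma2_beta_j}: reflecting Gaussian random-walk Metropolis
    on u = 1/v in (0, 1] (the prior is uniform in u, so the target in
    u-space is the likelihood alone).  A rejected proposal keeps v."""
    cfg = state.config
    sum_inv = float(np.sum(1.0 / state.var_beta))
    sum_log = float(np.sum(np.log(state.var_beta)))
    u_cur = 1.0 / state.v
    u_prop = u_cur + cfg.metropolis_step * state.rng.standard_normal()
    for _ in range(64):  # reflect into (0, 1]
        if u_prop <= 0.0:
            u_prop = -u_prop
        elif u_prop > 1.0:
            u_prop = 2.0 - u_prop
        else:
            break
    u_prop = max(u_prop, 1e-12)
    state.propose_v += 1
    ll_cur = _loglik_v(1.0 / u_cur, state.s2, sum_log, sum_inv, state.m)
    ll_prop = _loglik_v(1.0 / u_prop, state.s2, sum_log, sum_inv, state.m)
    if math.log(state.rng.random()) < ll_prop - ll_cur:
        state.v = 1.0 / u_prop
        state.accept_v += 1


def draw_student_t_hyper(state: SamplerState) -> None:
    """Student-t hyperparameter block: the truncated-Gamma s2 draw followed
    by one Metropolis update of v."""
    cfg = state.config
    if cfg.method != "student_t":
        raise ValueError("student-t hyper draw requested for another method")
    if cfg.fix_hyper:
        return
    draw_student_t_s2(state)
    metropolis_v_step(state)


# ---------------------------------------------------------------------------
# Chain assembly
# ---------------------------------------------------------------------------

def _expected_marker_var(y: np.ndarray, X: np.ndarray,
                         cfg: ChainConfig) -> float:
    """Heuristic prior expectation of a single marker's effect variance:
    half the phenotypic variance attributed to markers, divided by
    2*sum(p_j(1-p_j)) computed from the observed codes."""
    if cfg.expected_marker_var is not None:
        return cfg.expected_marker_var
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    vy = float(np.var(y))
    if denom <= 0:
        return max(0.5 * vy / X.shape[1], _SSE_FLOOR)
    return max(0.5 * vy / denom, _SSE_FLOOR)


def initialize_state(y: np.ndarray, X: np.ndarray, config: ChainConfig,
                     rng: np.random.Generator | None = None) -> SamplerState:
    """Neutral starting point: mu = mean(y), beta = 0, sigma2_e = var(y)/2,
    small equal per-marker variances, hyperparameters at their prior
    centres.  Honors the freezing hooks."""
    y = np.asarray(y, dtype=float)
    X = np.asfortranarray(np.asarray(X, dtype=float))
    if X.shape[1] == 0:
        raise ValueError("need at least one marker column")
    if X.shape[0] != len(y):
        raise ValueError("X rows must match phenotype length")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    if np.any(np.isnan(X)):
        raise ValueError("genotype matrix must be complete (no missing codes)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vy = float(np.var(y))
    m = X.shape[1]
    ev = _expected_marker_var(y, X, config)
    s2 = config.s2
    if s2 is None:
        s2 = ev * (config.v - 2.0) / config.v if config.v > 2.0 else ev
    mu = float(np.mean(y)) if config.fix_mu is None else float(config.fix_mu)
    sigma2_e = max(vy / 2.0, _SSE_FLOOR)
    if config.fix_sigma2_e is not None:
        sigma2_e = float(config.fix_sigma2_e)
    var_beta = np.full(m, max(0.01 * vy / m, _SSE_FLOOR))
    if config.fix_var_beta is not None:
        var_beta = np.broadcast_to(
            np.asarray(config.fix_var_beta, dtype=float), (m,)).copy()
    state = SamplerState(
        y=y, X=X, config=config, rng=rng, mu=mu,
        beta=np.zeros(m), e=np.empty(0), sigma2_e=sigma2_e,
        var_beta=var_beta, v=float(config.v), s2=float(s2),
        lambda2=config.a / config.b,
    )
    state.resync()
    return state


def gibbs_scan(state: SamplerState) -> None:
    """One full iteration: steps 1 (mu), 2 (beta sweep), 3 (sigma2_e),
    4 (variance layer and hyperparameters), in that order."""
    draw_mu(state)
    draw_beta_gauss_seidel(state)
    draw_sigma_e(state)
    method = state.config.method
    if method == "lasso":
        draw_lasso_layer(state)
    else:
        draw_snp_variance_invchisq(state)
        if method == "student_t":
            draw_student_t_hyper(state)


def run_chain(y, X, config: ChainConfig) -> PosteriorSummary:
    """Run one Gibbs chain and summarise the stored post-burn-in states.

    ``X`` may be a plain array or a :class:`~gebvpipe.simdata.GenotypeMatrix`
    (which must be complete).  Posterior means are averages of the stored
    thinned samples after burn-in.
    """
    if hasattr(X, "codes"):
        X = X.codes
    state = initialize_state(y, X, config)
    m = state.m
    keep_mu, keep_s2e, keep_hyper1, keep_hyper2 = [], [], [], []
    keep_beta, keep_var = [], []
    for it in range(config.n_iter):
        gibbs_scan(state)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep_mu.append(state.mu)
            keep_s2e.append(state.sigma2_e)
            keep_beta.append(state.beta.copy() if config.store_beta else None)
            keep_var.append(state.var_beta.copy() if config.store_beta else None)
            if config.method == "lasso":
                keep_hyper1.append(state.lambda2)
            elif config.method == "student_t":
                keep_hyper1.append(state.v)
                keep_hyper2.append(state.s2)
        if (it + 1) % 1000 == 0:
            state.resync()  # shed accumulated rounding
    samples = {"mu": np.array(keep_mu), "sigma2_e": np.array(keep_s2e)}
    if config.store_beta:
        samples["beta"] = np.array(keep_beta)
        samples["var_beta"] = np.array(keep_var)
        beta_mean = samples["beta"].mean(axis=0)
        var_mean = samples["var_beta"].mean(axis=0)
    else:
        beta_mean = np.full(m, np.nan)
        var_mean = np.full(m, np.nan)
    v_mean = s2_mean = lambda2_mean = None
    accept = None
    if config.method == "lasso":
        samples["lambda2"] = np.array(keep_hyper1)
        lambda2_mean = float(samples["lambda2"].mean())
    elif config.method == "student_t":
        samples["v"] = np.array(keep_hyper1)
        samples["s2"] = np.array(keep_hyper2)
        v_mean = float(samples["v"].mean())
        s2_mean = float(samples["s2"].mean())
        accept = state.accept_v / max(state.propose_v, 1)
    else:
        v_mean, s2_mean = state.v, state.s2  # fixed hyperparameters
    ess = {"sigma2_e": effective_sample_size(samples["sigma2_e"])}
    for key in ("lambda2", "v", "s2"):
        if key in samples:
            ess[key] = effective_sample_size(samples[key])
    return PosteriorSummary(
        method=config.method, mu_mean=float(samples["mu"].mean()),
        beta_mean=beta_mean, var_beta_mean=var_mean,
        sigma2_e_mean=float(samples["sigma2_e"].mean()),
        v_mean=v_mean, s2_mean=s2_mean, lambda2_mean=lambda2_mean,
        samples=samples, ess=ess, accept_rate_v=accept,
        n_stored=len(keep_mu),
    )


# ---------------------------------------------------------------------------
# Prior simulation (for calibration checks) and diagnostics
# ---------------------------------------------------------------------------

def prior_draw(config: ChainConfig, X: np.ndarray,
               rng: np.random.Generator) -> SamplerState:
    """Draw every unknown from its prior and the data from the likelihood.

    Requires proper surrogates for the improper defaults
    (``mu_prior_var`` and ``sigma2_e_prior`` must be set).  Used for
    prior-predictive / successive-conditional calibration testing.
    """
    if config.mu_prior_var is None or config.sigma2_e_prior is None:
        raise ValueError("prior_draw needs proper mu and sigma2_e priors")
    X = np.asfortranarray(np.asarray(X, dtype=float))
    n, m = X.shape
    mu = rng.normal(0.0, math.sqrt(config.mu_prior_var))
    nu0, s0_sq = config.sigma2_e_prior
    sigma2_e = nu0 * s0_sq / rng.chisquare(nu0)
    v, s2, lambda2 = config.v, config.s2, config.a / config.b
    if config.method == "lasso":
        lambda2 = rng.gamma(config.a, 1.0 / config.b)
        var_beta = rng.exponential(2.0 / lambda2, size=m)
    else:
        if config.method == "student_t":
            v = 1.0 / rng.uniform(1e-6, 1.0)
            A = config.A_upper if config.A_upper is not None else 1.0
            s = rng.uniform(0.0, A)
            s2 = max(s * s, _SSE_FLOOR)
        elif s2 is None:
            raise ValueError("bayes_a prior draw needs an explicit s2")
        var_beta = v * s2 / rng.chisquare(v, size=m)
    beta = rng.normal(0.0, np.sqrt(var_beta))
    y = mu + X @ beta + rng.normal(0.0, math.sqrt(sigma2_e), size=n)
    state = SamplerState(y=y, X=X, config=config, rng=rng, mu=float(mu),
                         beta=beta, e=np.empty(0), sigma2_e=float(sigma2_e),
                         var_beta=var_beta, v=float(v), s2=float(s2),
                         lambda2=float(lambda2))
    state.resync()
    return state


def regenerate_data(state: SamplerState) -> None:
    """Redraw y | parameters (the successive-conditional companion to
    :func:`gibbs_scan`)."""
    n = state.X.shape[0]
    state.y = (state.mu + state.X @ state.beta
               + state.rng.normal(0.0, math.sqrt(state.sigma2_e), size=n))
    state.resync()


def effective_sample_size(samples: np.ndarray) -> float:
    """Initial-positive-sequence (Geyer) ESS of a scalar chain.

    A constant chain is defined to have ESS equal to its length (callers
    can detect the zero-variance case via :func:`is_constant_chain`).
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 stored samples")
    if np.all(x == x[0]):
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # initial positive sequence with the monotone correction: paired
    # autocorrelations are kept while positive and forced non-increasing
    tau = 0.0
    k = 0
    prev = np.inf
    while 2 * k + 1 < n:
        gamma = rho[2 * k] + rho[2 * k + 1]
        if gamma <= 0.0:
            break
        gamma = min(gamma, prev)
        prev = gamma
        tau += gamma
        k += 1
    tau = max(2.0 * tau - 1.0, 1e-3)
    return float(n / tau)


def is_constant_chain(samples: np.ndarray) -> bool:
    x = np.asarray(samples, dtype=float)
    return bool(np.all(x == x[0]))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_effects(summary: PosteriorSummary, markers: list[str], path) -> None:
    pd.DataFrame({"marker": markers, "beta_mean": summary.beta_mean,
                  "var_mean": summary.var_beta_mean}).to_csv(
        path, sep="\t", index=False)


def read_effects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_diagnostics(summary: PosteriorSummary, path) -> None:
    diag = {
        "method": summary.method,
        "n_stored": summary.n_stored,
        "ess": {k: float(v) for k, v in summary.ess.items()},
        "accept_rate_v": summary.accept_rate_v,
        "posterior_means": {
            "mu": summary.mu_mean, "sigma2_e": summary.sigma2_e_mean,
            "v": summary.v_mean, "s2": summary.s2_mean,
            "lambda2": summary.lambda2_mean,
        },
    }
    with open(path, "w") as fh:
        json.dump(diag, fh, indent=2)
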