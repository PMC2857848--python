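"""Gibbs sampler components against analytic conditionals and moment oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from gebvpipe import samplers
from gebvpipe.config import load_chain_config
from gebvpipe.samplers import (ChainConfig, draw_beta_gauss_seidel,
                               draw_lasso_layer, draw_snp_variance_invchisq,
                               draw_student_t_hyper, effective_sample_size,
                               gibbs_scan, initialize_state, is_constant_chain,
                               metropolis_v_step, run_chain)


def make_state(method="bayes_a", n=40, m=8, seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    beta = rng.normal(0, 0.5, m)
    y = 5.0 + X @ beta + rng.normal(0, 1.0, n)
    cfg = ChainConfig(method=method, n_iter=100, burn_in=10, thin=1,
                      seed=seed, **kwargs)
    return initialize_state(y, X, cfg)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(method="bayes_c")
        with pytest.raises(ValueError):
            ChainConfig(burn_in=200, n_iter=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)
        with pytest.raises(ValueError):
            ChainConfig(a=-1.0)
        with pytest.raises(ValueError):
            ChainConfig(v=-2.0)

    def test_lasso_gamma_prior_defaults_round_trip(self):
        # a = 0.05, b = 1.0: a nearly flat prior for lambda over a wide range
        assert (ChainConfig().a, ChainConfig().b) == (0.05, 1.0)
        cfg = load_chain_config(text="method = lasso\na = 0.05\nb = 1.0\n"
                                     "n_iter = 200\nburn_in = 50")
        assert cfg.method == "lasso" and cfg.a == 0.05 and cfg.b == 1.0

    def test_protocol_defaults(self):
        cfg = ChainConfig()
        assert (cfg.n_iter, cfg.burn_in, cfg.thin) == (15000, 5500, 30)


class TestGaussSeidel:
    def test_residual_identity_after_sweeps(self):
        state = make_state(m=12)
        for _ in range(20):
            gibbs_scan(state)
        assert state.residual_error() < 1e-8

    def test_zero_column_falls_back_to_prior(self):
        state = make_state(m=4, fix_var_beta=0.7, fix_sigma2_e=1.0, fix_mu=0.0)
        state.X[:, 2] = 0.0
        state.xtx = np.einsum("ij,ij->j", state.X, state.X)
        state.resync()
        draws = []
        for _ in range(4000):
            draw_beta_gauss_seidel(state)
            draws.append(state.beta[2])
        draws = np.asarray(draws)
        assert abs(draws.mean()) < 3 * math.sqrt(0.7 / len(draws))
        assert abs(draws.var() - 0.7) < 3 * 0.7 * math.sqrt(2 / len(draws))

    def test_single_snp_conditional_moments(self):
        # with everything else frozen the draws are i.i.d. from the
        # analytic univariate conditional
        rng = np.random.default_rng(1)
        n = 50
        x = rng.integers(0, 3, n).astype(float)
        y = 0.8 * x + rng.normal(0, 1, n)
        s2e, s2b = 1.3, 0.6
        cfg = ChainConfig(method="bayes_a", fix_mu=0.0, fix_sigma2_e=s2e,
                          fix_var_beta=s2b, seed=2)
        state = initialize_state(y, x[:, None], cfg)
        N = 10_000
        draws = np.empty(N)
        for i in range(N):
            draw_beta_gauss_seidel(state)
            draws[i] = state.beta[0]
        c = x @ x / s2e + 1.0 / s2b
        mean_expect = (x @ y / s2e) / c
        var_expect = 1.0 / c
        assert abs(draws.mean() - mean_expect) < 3 * math.sqrt(var_expect / N)
        assert abs(draws.var() - var_expect) < 3 * var_expect * math.sqrt(2 / N)


class TestVarianceLayers:
    def test_invchisq_moments_at_beta_zero(self):
        v, s2 = 5.0, 2.0
        state = make_state("bayes_a", m=1, v=v, s2=s2)
        state.beta[:] = 0.0
        N = 100_000
        draws = np.empty(N)
        for i in range(N):
            draw_snp_variance_invchisq(state)
            draws[i] = state.var_beta[0]
        # scaled-Inv-chi2(v+1, v*s2/(v+1)) has mean v*s2/(v-1)
        mean_expect = v * s2 / (v - 1.0)
        se = draws.std() / math.sqrt(N)
        assert abs(draws.mean() - mean_expect) < 3 * se

    def test_invchisq_concentrates_for_large_v(self):
        state = make_state("bayes_a", m=1, v=1e6, s2=2.0)
        state.beta[:] = 0.0
        draws = np.empty(2000)
        for i in range(2000):
            draw_snp_variance_invchisq(state)
            draws[i] = state.var_beta[0]
        assert draws.std() / draws.mean() < 0.01
        assert abs(draws.mean() - 2.0) < 0.01

    def test_inverse_gaussian_sampler_matches_scipy_cdf(self):
        rng = np.random.default_rng(3)
        mean, shape = 1.7, 2.4
        draws = samplers._rand_inverse_gaussian(
            np.full(100_000, mean), shape, rng)
        grid = np.quantile(draws, np.linspace(0.005, 0.995, 200))
        emp = np.searchsorted(np.sort(draws), grid) / len(draws)
        ana = stats.invgauss.cdf(grid, mean / shape, scale=shape)
        assert np.max(np.abs(emp - ana)) < 0.01

    def test_lambda2_gamma_conditional_moments(self):
        tau2 = np.array([0.5, 1.5, 0.2, 0.8])
        cfg = ChainConfig(method="lasso", a=0.05, b=1.0,
                          fix_var_beta=tau2, seed=4)
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, (30, 4)).astype(float)
        state = initialize_state(rng.normal(0, 1, 30), X, cfg)
        N = 100_000
        draws = np.empty(N)
        for i in range(N):
            draw_lasso_layer(state)
            draws[i] = state.lambda2
        shape, rate = 0.05 + 4, 1.0 + tau2.sum() / 2.0
        assert abs(draws.mean() - shape / rate) < 3 * draws.std() / math.sqrt(N)
        var_expect = shape / rate**2
        assert abs(draws.var() - var_expect) < 0.05 * var_expect


class TestStudentT:
    def test_zero_step_proposal_always_accepted(self):
        state = make_state("student_t", metropolis_step=0.0)
        v0 = state.v
        for _ in range(50):
            metropolis_v_step(state)
        assert state.v == v0
        assert state.accept_v == state.propose_v == 50

    def test_hyperparameter_recovery(self):
        # {sigma2_beta_j} simulated from scaled-Inv-chi2(v0=4, s2_0=0.01):
        # posterior means of (v, s2) recover the generating values
        rng = np.random.default_rng(6)
        v0, s20, m = 4.0, 0.01, 2000
        var_beta = v0 * s20 / rng.chisquare(v0, size=m)
        cfg = ChainConfig(method="student_t", A_upper=10.0, seed=7)
        X = rng.integers(0, 3, (20, m)).astype(float)
        state = initialize_state(rng.normal(0, 1, 20), X, cfg)
        state.var_beta = var_beta
        vs, s2s = [], []
        for i in range(4000):
            draw_student_t_hyper(state)
            if i >= 500:
                vs.append(state.v)
                s2s.append(state.s2)
        assert abs(np.mean(vs) - v0) < 0.15 * v0
        assert abs(np.mean(s2s) - s20) < 0.15 * s20

    def test_wrong_method_rejected(self):
        state = make_state("bayes_a")
        with pytest.raises(ValueError):
            draw_student_t_hyper(state)
        with pytest.raises(ValueError):
            draw_lasso_layer(state)


class TestEffectiveSampleSize:
    def test_iid_normal(self):
        x = np.random.default_rng(8).standard_normal(1000)
        assert 800 <= effective_sample_size(x) <= 1200

    def test_ar1_closed_form(self):
        rng = np.random.default_rng(9)
        rho, n = 0.9, 10_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + math.sqrt(1 - rho**2) * rng.standard_normal()
        expect = n * (1 - rho) / (1 + rho)
        assert abs(effective_sample_size(x) - expect) < 0.3 * expect

    def test_constant_chain_flagged(self):
        x = np.full(50, 3.14)
        assert effective_sample_size(x) == 50
        assert is_constant_chain(x)
        assert not is_constant_chain(np.arange(50.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5.0))


class TestRunChain:
    def test_no_signal_flat_phenotype(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, (40, 6)).astype(float)
        y = np.full(40, 3.0) + rng.normal(0, 1e-3, 40)  # essentially constant
        cfg = ChainConfig(n_iter=600, burn_in=100, thin=2, seed=11)
        summ = run_chain(y, X, cfg)
        assert abs(summ.mu_mean - 3.0) < 0.01
        sd = summ.samples["beta"].std(axis=0)
        assert np.all(np.abs(summ.beta_mean) < 3 * sd + 1e-6)

    def test_seed_determinism_and_storage(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 3, (30, 5)).astype(float)
        y = X @ rng.normal(0, 1, 5) + rng.normal(0, 1, 30)
        cfg = ChainConfig(method="lasso", n_iter=300, burn_in=60, thin=6,
                          seed=13)
        a = run_chain(y, X, cfg)
        b = run_chain(y, X, cfg)
        assert np.array_equal(a.beta_mean, b.beta_mean)
        assert a.n_stored == len(range(60, 300, 6))
        c = run_chain(y, X, ChainConfig(method="lasso", n_iter=300,
                                        burn_in=60, thin=6, seed=14))
        assert not np.array_equal(a.beta_mean, c.beta_mean)

    def test_input_validation(self):
        cfg = ChainConfig()
        with pytest.raises(ValueError):
            run_chain(np.array([1.0, np.nan]), np.ones((2, 1)), cfg)
        with pytest.raises(ValueError):
            run_chain(np.ones(2), np.ones((2, 0)), cfg)

    def test_lasso_shrinks_small_qtl_least(self):
        # one large + ten small QTL: the Laplace prior retains more of the
        # small effects than either inverse-chi-square method
        from gebvpipe import simdata

        mean_abs = {m: [] for m in samplers.METHODS}
        for seed in range(10):
            ped = simdata.simulate_pedigree(2, 6, 150, seed=seed)
            mmap = simdata.default_marker_map(40, 2)
            geno = simdata.simulate_genomes(ped, mmap, 0.5, seed=seed + 50)
            rng = np.random.default_rng(seed + 100)
            X = geno.codes[ped.generation > 0]
            qtl = np.arange(0, 33, 3)[:11]
            eff = np.zeros(40)
            eff[qtl[0]] = 2.0
            eff[qtl[1:]] = 0.2 * rng.choice([-1.0, 1.0], 10)
            tbv = X @ eff
            y = tbv + rng.normal(0, tbv.std(), len(tbv))
            for method in samplers.METHODS:
                cfg = ChainConfig(method=method, n_iter=1200, burn_in=400,
                                  thin=4, seed=seed)
                summ = run_chain(y, X, cfg)
                mean_abs[method].append(np.mean(np.abs(summ.beta_mean[qtl[1:]])))
        lasso = np.mean(mean_abs["lasso"])
        assert lasso >= np.mean(mean_abs["bayes_a"])
        assert lasso >= np.mean(mean_abs["student_t"])


def test_effects_and_diagnostics_round_trip(tmp_path):
    rng = np.random.default_rng(15)
    X = rng.integers(0, 3, (25, 4)).astype(float)
    y = X @ np.array([1.0, 0, 0, -1.0]) + rng.normal(0, 1, 25)
    summ = run_chain(y, X, ChainConfig(method="student_t", n_iter=400,
                                       burn_in=100, thin=4, seed=16))
    samplers.write_effects(summ, [f"M{i}" for i in range(4)],
                           tmp_path / "eff.tsv")
    eff = samplers.read_effects(tmp_path / "eff.tsv")
    assert np.allclose(eff["beta_mean"], summ.beta_mean)
    samplers.write_diagnostics(summ, tmp_path / "diag.json")
    import json
    diag = json.loads((tmp_path / "diag.json").read_text())
    assert diag["method"] == "student_t"
    assert 0.0 <= diag["accept_rate_v"] <= 1.0
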