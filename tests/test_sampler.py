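"""DRAM core against analytically tractable targets."""

import math

import numpy as np
import pytest
from scipy import stats

from glucodyn.calibration import effective_sample_size
from glucodyn.sampler import SamplerDivergence, dram_chain, sample_error_precision


class TestErrorPrecision:
    SS, N, N0, S0 = 123.4, 7, 1.0, 15.0

    def draws(self, size=100_000, seed=3):
        rng = np.random.default_rng(seed)
        return np.array([sample_error_precision(self.SS, self.N, self.N0,
                                                self.S0, rng)
                         for _ in range(size)])

    def test_precision_mean(self):
        precision = 1.0 / self.draws()
        shape = (self.N0 + self.N) / 2
        rate = (self.N0 * self.S0 + self.SS) / 2
        mc_se = math.sqrt(shape / rate**2 / precision.size)
        assert abs(precision.mean() - shape / rate) < 3 * mc_se

    def test_precision_quantiles_match_gamma(self):
        precision = 1.0 / self.draws()
        shape = (self.N0 + self.N) / 2
        rate = (self.N0 * self.S0 + self.SS) / 2
        qs = np.linspace(0.05, 0.95, 19)
        empirical = np.quantile(precision, qs)
        theoretical = stats.gamma.ppf(qs, shape, scale=1.0 / rate)
        assert np.max(np.abs(empirical - theoretical) / theoretical) < 0.02

    def test_zero_ss_uses_prior_terms_only(self):
        rng = np.random.default_rng(0)
        draws = 1.0 / np.array([sample_error_precision(0.0, self.N, self.N0,
                                                       self.S0, rng)
                                for _ in range(50_000)])
        expected_mean = (self.N0 + self.N) / (self.N0 * self.S0)
        assert draws.mean() == pytest.approx(expected_mean, rel=0.05)

    def test_degenerate_rate_signalled(self):
        with pytest.raises(ValueError):
            sample_error_precision(0.0, 5, 0.0, 0.0, np.random.default_rng(0))

    @pytest.mark.parametrize("kwargs", [dict(ss=-1.0), dict(n=0), dict(n0=-1.0)])
    def test_invalid_inputs(self, kwargs):
        args = dict(ss=1.0, n=5, n0=1.0, s0=1.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            sample_error_precision(args["ss"], args["n"], args["n0"],
                                   args["s0"], np.random.default_rng(0))


class TestLinearGaussianOracle:
    """On a linear model with fixed noise variance the posterior is the
    closed-form Gaussian N(beta_hat, sigma^2 (X'X)^-1)."""

    @classmethod
    def setup_class(cls):
        rng = np.random.default_rng(42)
        n = 40
        cls.X = np.column_stack([np.ones(n), np.linspace(0.0, 1.0, n)])
        cls.sigma = 0.5
        cls.y = cls.X @ np.array([1.0, -0.5]) + rng.normal(0, cls.sigma, n)
        XtX = cls.X.T @ cls.X
        cls.beta_hat = np.linalg.solve(XtX, cls.X.T @ cls.y)
        cls.post_cov = cls.sigma**2 * np.linalg.inv(XtX)
        ss = lambda th: float(np.sum((cls.y - cls.X @ th) ** 2))
        cls.result = dram_chain(ss, cls.beta_hat, [-10, -10], [10, 10],
                                cls.post_cov, 40_000,
                                np.random.default_rng(1), n_obs=n,
                                sigma2=cls.sigma**2)

    def test_posterior_mean_and_variance(self):
        kept = self.result.chain[5000:]
        for j in range(2):
            values = kept[:, j]
            ess = effective_sample_size(values)
            mean_se = values.std() / math.sqrt(ess)
            var_se = values.var() * math.sqrt(2.0 / ess)
            assert abs(values.mean() - self.beta_hat[j]) < 3 * mean_se
            assert abs(values.var() - self.post_cov[j, j]) < 3 * var_se

    def test_chain_has_requested_length(self):
        assert self.result.chain.shape == (40_000, 2)
        assert self.result.sigma2_chain == pytest.approx(self.sigma**2)


class TestMarginalisedVarianceOracle:
    """With sigma^2 unknown, the theta-marginal posterior of a linear model
    is multivariate Student-t: location beta_hat, scale
    (n0*s0 + SS_min) (X'X)^-1 / (nu - 2) variance with nu = n0 + n - d."""

    def test_chain_matches_t_posterior(self):
        rng = np.random.default_rng(42)
        n, d = 40, 2
        X = np.column_stack([np.ones(n), np.linspace(0.0, 1.0, n)])
        y = X @ np.array([1.0, -0.5]) + rng.normal(0, 0.5, n)
        XtX = X.T @ X
        beta_hat = np.linalg.solve(XtX, X.T @ y)
        ss_min = float(np.sum((y - X @ beta_hat) ** 2))
        n0, s0 = 1.0, ss_min / n
        result = dram_chain(lambda th: float(np.sum((y - X @ th) ** 2)),
                            beta_hat, [-10, -10], [10, 10],
                            0.25 * np.linalg.inv(XtX), 40_000,
                            np.random.default_rng(1), n_obs=n, n0=n0, s0=s0)
        kept = result.chain[5000:]
        nu = n0 + n - d
        var_theory = np.diag((n0 * s0 + ss_min) * np.linalg.inv(XtX)
                             / (nu - 2.0))
        for j in range(d):
            values = kept[:, j]
            ess = effective_sample_size(values)
            assert abs(values.mean() - beta_hat[j]) \
                < 3 * values.std() / math.sqrt(ess)
            assert abs(values.var() - var_theory[j]) \
                < 3 * values.var() * math.sqrt(2.0 / ess) + 0.05 * var_theory[j]


def _quadratic_ss(theta):
    theta = np.atleast_1d(theta)
    return float(np.sum(theta**2))


def test_seeded_chains_are_identical():
    kwargs = dict(theta0=[0.5], lower=[-5], upper=[5], cov0=np.eye(1),
                  n_iter=2000, n_obs=10, n0=1.0, s0=0.5)
    first = dram_chain(_quadratic_ss, rng=np.random.default_rng(9), **kwargs)
    second = dram_chain(_quadratic_ss, rng=np.random.default_rng(9), **kwargs)
    assert np.array_equal(first.chain, second.chain)
    assert np.array_equal(first.sigma2_chain, second.sigma2_chain)


def test_sampled_sigma2_is_positive_and_varies():
    result = dram_chain(_quadratic_ss, [0.5], [-5], [5], np.eye(1), 2000,
                        np.random.default_rng(9), n_obs=10, s0=0.5)
    assert np.all(result.sigma2_chain > 0)
    assert np.unique(result.sigma2_chain).size > 1500


def test_detailed_balance_acceptance_rule():
    """With adaptation and delayed rejection off and a symmetric fixed
    proposal, every logged decision reproduces the Metropolis ratio."""
    sigma2 = 0.7
    result = dram_chain(_quadratic_ss, [0.3, -0.2], [-5, -5], [5, 5],
                        0.5 * np.eye(2), 3000, np.random.default_rng(4),
                        n_obs=10, sigma2=sigma2, dr_scale=None,
                        adapt_start=None, track_proposals=True)
    assert len(result.proposals) == 3000
    for rec in result.proposals:
        expected = min(0.0, -0.5 * (rec.ss_proposed - rec.ss_current) / sigma2)
        assert rec.log_alpha == pytest.approx(expected, abs=1e-12)
        assert rec.accepted == (math.log(rec.uniform) < rec.log_alpha)


def test_delayed_rejection_raises_acceptance():
    kwargs = dict(theta0=[0.0], lower=[-5], upper=[5],
                  cov0=25.0 * np.eye(1), n_iter=4000, n_obs=10, sigma2=1.0,
                  adapt_start=None)
    plain = dram_chain(_quadratic_ss, rng=np.random.default_rng(2),
                       dr_scale=None, **kwargs)
    dram = dram_chain(_quadratic_ss, rng=np.random.default_rng(2),
                      dr_scale=0.2, **kwargs)
    assert dram.acceptance_rate > plain.acceptance_rate


def test_pervasive_failure_aborts():
    def mostly_failing(theta):
        return float("inf") if abs(theta[0]) > 1e-3 else float(theta[0] ** 2)

    with pytest.raises(SamplerDivergence):
        dram_chain(mostly_failing, [0.0], [-5], [5], np.eye(1), 5000,
                   np.random.default_rng(0), n_obs=10, sigma2=1.0)


def test_out_of_bounds_start_rejected():
    with pytest.raises(ValueError):
        dram_chain(_quadratic_ss, [10.0], [-5], [5], np.eye(1), 10,
                   np.random.default_rng(0), n_obs=10, sigma2=1.0)
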