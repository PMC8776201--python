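"""Fit specification, cost function, summaries and diagnostics."""

import numpy as np
import pytest

import glucodyn as gd
from glucodyn.calibration import convergence_diagnostics, summarize


class TestFitSpecification:
    def test_default_protocol(self, hyper_preset):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params)
        assert spec.varied == ("delta", "psi")
        assert spec.chain_length == 100_000
        assert spec.bounds["delta"] == (1e-3, 1.0)
        assert spec.bounds["psi"] == (1e-2, 1e2)

        p2 = gd.Model2Parameters(a=45.0, b=0.13, f=10.0, i=2e-6)
        spec2 = gd.FitSpecification(model_id=2, fixed=p2)
        assert spec2.varied == ("a", "b", "f", "i")

    def test_invalid_specifications(self, hyper_preset):
        with pytest.raises(ValueError):
            gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                bounds={"delta": (1.0, 0.5)})
        with pytest.raises(ValueError):
            gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                varied=("nope",))
        with pytest.raises(TypeError):
            gd.FitSpecification(model_id=2, fixed=hyper_preset.params)

    def test_build_params_overwrites_varied_only(self, hyper_preset):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params)
        params = spec.build_params([0.5, 3.0])
        assert (params.delta, params.psi) == (0.5, 3.0)
        assert params.a == hyper_preset.params.a


class TestSumOfSquares:
    def test_perfect_fit_is_zero(self, hyper_preset, noiseless_hyper):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                   init=hyper_preset.init)
        truth = [hyper_preset.params.delta, hyper_preset.params.psi]
        assert gd.sum_of_squares(truth, spec, noiseless_hyper) < 1e-8

    def test_single_observation(self, hyper_preset):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                   init=hyper_preset.init)
        clean = gd.simulate(1, hyper_preset.params, hyper_preset.init,
                            [0.0, 30.0]).glucose
        data = gd.GlucoseDataset(times=np.array([30.0]),
                                 glucose=np.array([clean[1] + 2.0]))
        truth = [hyper_preset.params.delta, hyper_preset.params.psi]
        assert gd.sum_of_squares(truth, spec, data) == pytest.approx(4.0, abs=1e-6)

    def test_hand_computed_offsets(self, hyper_preset):
        # known residuals: SS is exactly their squared sum
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                   init=hyper_preset.init)
        times = np.array([0.0, 60.0, 180.0])
        clean = gd.simulate(1, hyper_preset.params, hyper_preset.init, times).glucose
        offsets = np.array([1.0, -2.0, 3.0])
        data = gd.GlucoseDataset(times=times, glucose=clean + offsets)
        truth = [hyper_preset.params.delta, hyper_preset.params.psi]
        expected = 1.0 + 4.0 + 9.0
        assert gd.sum_of_squares(truth, spec, data) == pytest.approx(
            expected, abs=1e-6)

    def test_out_of_bounds_is_infinite(self, hyper_preset, noiseless_hyper):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params)
        assert gd.sum_of_squares([2.0, 1.0], spec, noiseless_hyper) == np.inf

    def test_integration_failure_is_infinite(self, blowup_params, noiseless_hyper):
        spec = gd.FitSpecification(model_id=2, fixed=blowup_params)
        theta = [blowup_params.a, blowup_params.b, blowup_params.f, 1e-8]
        assert gd.sum_of_squares(theta, spec, noiseless_hyper) == np.inf


class TestLeastSquares:
    def test_noiseless_recovery_within_one_percent(self, hyper_preset,
                                                   noiseless_hyper):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                   init=hyper_preset.init, seed=2)
        theta, ss = gd.least_squares_fit(spec, noiseless_hyper)
        truth = np.array([hyper_preset.params.delta, hyper_preset.params.psi])
        assert np.max(np.abs(theta - truth) / truth) < 0.01
        assert ss < 1e-6

    def test_truth_on_boundary_corner(self, hyper_preset, noiseless_hyper):
        # the generating (delta, psi) sit exactly at the box's lower corner
        spec = gd.FitSpecification(
            model_id=1, fixed=hyper_preset.params, init=hyper_preset.init,
            bounds={"delta": (0.025, 0.1), "psi": (0.02, 0.1)}, seed=2)
        theta, _ = gd.least_squares_fit(spec, noiseless_hyper)
        assert theta == pytest.approx([0.025, 0.02], rel=1e-4)

    def test_at_least_as_good_as_truth(self, hyper_preset, noisy_hyper):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                   init=hyper_preset.init, seed=2)
        theta, ss = gd.least_squares_fit(spec, noisy_hyper)
        truth = [hyper_preset.params.delta, hyper_preset.params.psi]
        assert ss <= gd.sum_of_squares(truth, spec, noisy_hyper) + 1e-9


class TestSummarize:
    def test_constant_chain_gives_zero_width(self):
        chain = np.full((1000, 2), 3.7)
        table = summarize(chain, burn_in_fraction=0.5)
        assert np.all(table["lower"] == 3.7)
        assert np.all(table["median"] == 3.7)
        assert np.all(table["upper"] == 3.7)

    def test_uniform_chain_quantiles(self):
        rng = np.random.default_rng(0)
        chain = rng.uniform(size=(40_000, 1))
        table = summarize(chain, burn_in_fraction=0.0)
        assert table["lower"].iloc[0] == pytest.approx(0.025, abs=0.005)
        assert table["upper"].iloc[0] == pytest.approx(0.975, abs=0.005)
        assert table["median"].iloc[0] == pytest.approx(0.5, abs=0.01)

    def test_ordering_invariant(self, fitted_hyper):
        table = fitted_hyper.summary_
        assert (table["lower"] <= table["median"]).all()
        assert (table["median"] <= table["upper"]).all()

    def test_thinning_invariance(self):
        rng = np.random.default_rng(1)
        chain = rng.normal(size=(30_000, 1))
        full = summarize(chain, burn_in_fraction=0.0)
        thinned = summarize(chain[::3], burn_in_fraction=0.0)
        assert thinned["lower"].iloc[0] == pytest.approx(
            full["lower"].iloc[0], abs=0.1)
        assert thinned["upper"].iloc[0] == pytest.approx(
            full["upper"].iloc[0], abs=0.1)

    def test_empty_post_burn_in_signalled(self):
        with pytest.raises(ValueError):
            summarize(np.zeros((10, 1)), burn_in_fraction=1.0)


class TestConvergenceDiagnostics:
    def test_iid_chain_ess_near_length(self):
        chain = np.random.default_rng(0).normal(size=10_000)
        report = convergence_diagnostics(chain)
        assert report["ess"].iloc[0] == pytest.approx(10_000, rel=0.2)
        assert not report["needs_extension"].iloc[0]

    def test_linear_trend_flagged(self):
        report = convergence_diagnostics(np.linspace(0.0, 1.0, 5000))
        assert abs(report["z"].iloc[0]) > 2
        assert report["needs_extension"].iloc[0]

    def test_duplicated_chain_halves_ess_fraction(self):
        chain = np.random.default_rng(0).normal(size=10_000)
        doubled = np.repeat(chain, 2)
        frac = convergence_diagnostics(chain)["ess"].iloc[0] / chain.size
        frac_doubled = convergence_diagnostics(doubled)["ess"].iloc[0] / doubled.size
        assert frac_doubled == pytest.approx(0.5 * frac, rel=0.15)


class TestRunMCMC:
    def test_same_seed_identical_chains(self, hyper_preset, noisy_hyper):
        spec = gd.FitSpecification(model_id=1, fixed=hyper_preset.params,
                                   init=hyper_preset.init, chain_length=400,
                                   seed=17)
        first = gd.run_mcmc(spec, noisy_hyper)
        second = gd.run_mcmc(spec, noisy_hyper)
        assert np.array_equal(first.chain, second.chain)
        assert np.array_equal(first.sigma2_chain, second.sigma2_chain)
        assert first.acceptance_rate == second.acceptance_rate

    def test_posterior_sample_invariants(self, fitted_hyper):
        sample = fitted_hyper.posterior_
        assert len(sample) == 2500
        assert np.all(sample.ss_chain >= 0)
        assert np.all(sample.sigma2_chain > 0)
        assert sample.names == ("delta", "psi")
        # SS chain is bounded below by the least-squares minimum
        # (up to optimizer/solver noise)
        assert sample.ss_chain.min() >= fitted_hyper.ss_ls_ * (1 - 1e-3) - 1e-6

    def test_posterior_sample_validation(self):
        with pytest.raises(ValueError):
            gd.PosteriorSample(names=("a",), chain=np.zeros((10, 1)),
                               sigma2_chain=np.zeros(10),  # not strictly > 0
                               ss_chain=np.zeros(10), acceptance_rate=0.5)
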