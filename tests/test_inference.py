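"""Pooled likelihood, sigma profiling and multi-start MLE behaviour."""

import math

import numpy as np
import pytest

from hostresponse import (ActivationEffectModel, Dataset, FitConfig,
                          GlobalModel, Measurement, ValidationError,
                          default_true_params, fit_mle, generate,
                          log_likelihood, paper_design, profile_sigma,
                          residuals)
from hostresponse.inference import DegenerateFitWarning


@pytest.fixture(scope="module")
def act_model():
    return ActivationEffectModel("invasion", default_true_params().invasion)


class TestResiduals:
    def test_noise_free_data_gives_zero_residuals(self, truth, noisefree_dataset):
        res = residuals(GlobalModel(truth, "M3"), None, noisefree_dataset)
        assert np.max(np.abs(res)) == 0.0

    def test_single_observation_residual_value(self, act_model):
        # model mean at dose 0 is the baseline 8 -> y=5 gives residual -3
        ds = Dataset([Measurement("invasion", 0.0, 24.0, 5.0)])
        res = residuals(act_model, None, ds)
        assert res[0] == pytest.approx(5.0 - 8.0)

    def test_one_residual_per_measurement(self, truth, noisy_dataset):
        res = residuals(GlobalModel(truth, "M3"), None, noisy_dataset)
        assert len(res) == noisy_dataset.n_tot == 120

    def test_uncovered_readout_rejected(self, act_model, truth):
        ds = generate(truth, paper_design(1), sigma=0.0, seed=0)
        from hostresponse import ConfigurationError
        with pytest.raises(ConfigurationError, match="readout"):
            residuals(act_model, None, ds)


class TestLogLikelihood:
    def test_single_zero_residual_unit_sigma(self, act_model):
        ds = Dataset([Measurement("invasion", 0.0, 24.0, 8.0)])
        ll = log_likelihood(act_model, None, 1.0, ds)
        assert ll == pytest.approx(-math.log(math.sqrt(2 * math.pi)))
        assert ll == pytest.approx(-0.918939, abs=1e-6)

    def test_scales_with_n_for_zero_rss(self, act_model):
        ds = Dataset([Measurement("invasion", 0.0, 24.0, 8.0, i) for i in
                      range(1, 11)])
        ll = log_likelihood(act_model, None, 1.0, ds)
        assert ll == pytest.approx(-10 * math.log(math.sqrt(2 * math.pi)))

    def test_quadratic_scaling_in_residuals(self, act_model):
        y1 = Dataset([Measurement("invasion", 0.0, 24.0, 9.0)])   # residual 1
        y2 = Dataset([Measurement("invasion", 0.0, 24.0, 10.0)])  # residual 2
        l1 = log_likelihood(act_model, None, 1.0, y1)
        l2 = log_likelihood(act_model, None, 1.0, y2)
        # doubling the residual at fixed sigma costs 3*RSS/(2 sigma^2) more
        assert l1 - l2 == pytest.approx(3.0 / 2.0)

    def test_nonpositive_sigma_rejected(self, act_model):
        ds = Dataset([Measurement("invasion", 0.0, 24.0, 8.0)])
        with pytest.raises(ValidationError):
            log_likelihood(act_model, None, 0.0, ds)


class TestProfileSigma:
    def test_matches_rms_residual(self, act_model):
        ds = Dataset([Measurement("invasion", 0.0, 24.0, 9.0, 1),
                      Measurement("invasion", 0.0, 24.0, 7.0, 2)])
        assert profile_sigma(act_model, None, ds) == pytest.approx(1.0)

    def test_zero_rss_warns_degenerate(self, act_model):
        ds = Dataset([Measurement("invasion", 0.0, 24.0, 8.0)])
        with pytest.warns(DegenerateFitWarning):
            assert profile_sigma(act_model, None, ds) == 0.0

    def test_profile_optimality_over_sigma_grid(self, truth, noisy_dataset):
        model = GlobalModel(truth, "M3")
        s_hat = profile_sigma(model, None, noisy_dataset)
        l_hat = log_likelihood(model, None, s_hat, noisy_dataset)
        for s in np.geomspace(0.1, 10, 25):
            assert l_hat >= log_likelihood(model, None, s, noisy_dataset)


class TestFitMLE:
    def test_seeded_fit_is_reproducible(self, truth):
        ds = generate(truth, paper_design(3), seed=5)
        model = lambda: GlobalModel(truth, "M3").rebaselined(ds.control_means())
        cfg = FitConfig(n_starts=3, jitter_first=True, seed=9)
        f1 = fit_mle(model(), ds, cfg)
        f2 = fit_mle(model(), ds, cfg)
        assert np.array_equal(f1.theta, f2.theta)
        assert f1.loglik == f2.loglik

    def test_parameter_count_includes_sigma(self, truth):
        ds = generate(truth, paper_design(2), seed=5)
        model = GlobalModel(truth, "M3")
        fit = fit_mle(model, ds, FitConfig(n_starts=2, seed=0))
        assert fit.n_params == len(model.free_names) + 1 == 9

    def test_single_cell_design_flags_non_identifiability(self, truth):
        rng = np.random.default_rng(0)
        ds = Dataset([Measurement("invasion", 25.0, 48.0,
                                  24.0 + rng.normal(0, 0.5), i)
                      for i in range(1, 6)])
        model = ActivationEffectModel("invasion", truth.invasion)
        fit = fit_mle(model, ds, FitConfig(n_starts=6, jitter_first=True, seed=1))
        assert not fit.identifiable
        assert any("identifiable" in w for w in fit.warnings)

    def test_consistency_error_shrinks_with_replicates(self, truth):
        # median |theta_hat - theta| over free params decreases with n
        errs = []
        for n_rep in (2, 8, 32):
            ds = generate(truth, paper_design(n_rep), seed=17)
            model = GlobalModel(truth, "M3").rebaselined(ds.control_means())
            fit = fit_mle(model, ds, FitConfig(n_starts=2, seed=3))
            t0 = GlobalModel(truth, "M3").init_theta()
            errs.append(np.median(np.abs(fit.theta - t0) / t0))
        assert errs[2] < errs[0]
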