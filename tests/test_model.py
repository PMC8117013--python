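"""Tests of the Bayesian BAI model: posterior, sampler, OVL, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dendrobai.model import (ALPHA_NAMES, PARAM_NAMES, BaiLinearModel,
                             ConvergenceReport, posterior_overlap)
from dendrobai.synthetic import (GroupParams, SyntheticTruth,
                                 simulate_group_bai)


@pytest.fixture(scope="module")
def model(dataset):
    cov = dataset.covariates.loc[1950:2005]
    return BaiLinearModel(dataset.group_bai["BS_M"].loc[1950:2005], cov,
                          group="BS_M")


@pytest.fixture(scope="module")
def fitted(model):
    return model.fit(n_iter=30_000, burn_in=5_000, seed=11)


class TestLogPosterior:
    def test_perfect_fit_closed_form(self, covariates):
        # y exactly equals the predictor, σ = 1: log p = −(n/2)·log 2π
        truth = GroupParams(3.0, 0.01, 0.2, -0.3, -0.5, 0.4, sigma=1.0)
        X = covariates.to_numpy()
        y = truth.baseline + X @ truth.as_alpha_vector()[1:]
        m = BaiLinearModel(pd.Series(y, index=covariates.index), covariates)
        p = np.r_[truth.as_alpha_vector(), 1.0]
        n = len(y)
        assert m.log_posterior(p) == pytest.approx(-0.5 * n * np.log(2 * np.pi))

    def test_outside_bounds_is_minus_inf(self, model):
        bounds = model.default_bounds()
        p = np.zeros(7)
        p[6] = 0.3
        p[0] = bounds[0, 1] * 2
        assert model.log_posterior(p, bounds) == -np.inf

    def test_matches_independent_normal_logpdf_sum(self, model, rng):
        bounds = model.default_bounds()
        for _ in range(10):
            p = np.r_[rng.normal(0, 1, 6), rng.uniform(0.1, 2.0)]
            expected = (sps.norm.logpdf(model.endog, model.exog @ p[:6], p[6]).sum()
                        - np.log(p[6]))
            if np.any(p < bounds[:, 0]) or np.any(p > bounds[:, 1]):
                expected = -np.inf
            assert model.log_posterior(p) == pytest.approx(expected, abs=1e-10)

    def test_nonfinite_params_rejected(self, model):
        with pytest.raises(ValueError):
            model.log_posterior([np.nan, 0, 0, 0, 0, 0, 1.0])


class TestFit:
    def test_degenerate_noise_concentrates_on_truth(self, covariates):
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0.01, 0.2, -0.3, -0.5, 0.4,
                                                sigma=1e-5)},
            n_trees={"BS_PBS": 2})
        bai = simulate_group_bai(truth, covariates, "BS_PBS", seed=3)
        res = BaiLinearModel(bai, covariates).fit(n_iter=20_000, burn_in=5_000,
                                                  seed=1)
        alpha = truth.group_params["BS_PBS"].as_alpha_vector()
        for j, name in enumerate(ALPHA_NAMES):
            assert res.params[name] == pytest.approx(alpha[j], abs=1e-3)

    def test_posterior_centers_on_least_squares(self, model, fitted):
        # flat-prior analytic oracle: α marginals are multivariate t
        # centred on the OLS solution
        beta, _ = model.least_squares()
        for j, name in enumerate(ALPHA_NAMES):
            z = abs(fitted.params[name] - beta[j]) / fitted.sd[name]
            assert z < 3.0

    def test_posterior_sd_matches_t_marginal(self, model, fitted):
        # under flat priors the α covariance is s²·(XᵀX)⁻¹·ν/(ν−2)
        beta, s = model.least_squares()
        n, p = model.exog.shape
        nu = n - p
        cov = s ** 2 * np.linalg.inv(model.exog.T @ model.exog) * nu / (nu - 2)
        for j, name in enumerate(ALPHA_NAMES):
            assert fitted.sd[name] == pytest.approx(np.sqrt(cov[j, j]), rel=0.15)

    def test_seed_reproducibility(self, model):
        a = model.fit(n_iter=3_000, burn_in=500, seed=7)
        b = model.fit(n_iter=3_000, burn_in=500, seed=7)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        c = model.fit(n_iter=3_000, burn_in=500, seed=8)
        assert not a.draws.equals(c.draws)

    def test_acceptance_rates_in_target_band(self, fitted):
        assert ((fitted.acceptance_rates > 0.10) &
                (fitted.acceptance_rates < 0.55)).all()

    def test_retained_draw_count(self, fitted):
        assert fitted.n_retained == 30_000 - 5_000
        assert (fitted.draws["sigma"] > 0).all()

    def test_posterior_sd_grows_with_noise(self, covariates):
        sds = []
        for sigma in (0.2, 0.8):
            truth = SyntheticTruth(
                group_params={"BS_PBS": GroupParams(3.0, 0.0, 0.3, -0.3, -0.5,
                                                    0.4, sigma=sigma)},
                n_trees={"BS_PBS": 2})
            bai = simulate_group_bai(truth, covariates, "BS_PBS", seed=5)
            res = BaiLinearModel(bai, covariates).fit(n_iter=12_000,
                                                      burn_in=2_000, seed=2)
            sds.append(res.sd["alpha_baseline"])
        assert sds[1] > sds[0]

    def test_constant_covariate_warns_but_samples(self, covariates):
        cov = covariates.copy()
        cov["budworm"] = 0.0
        y = pd.Series(3.0 + 0.3 * np.random.default_rng(0).normal(size=len(cov)),
                      index=cov.index)
        m = BaiLinearModel(y, cov)
        with pytest.warns(UserWarning, match="constant"):
            res = m.fit(n_iter=4_000, burn_in=1_000, seed=0)
        assert np.isfinite(res.params["alpha_budworm"])


class TestRSquared:
    def test_perfect_fit_gives_one(self, covariates):
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0.01, 0.2, -0.3, -0.5, 0.4,
                                                sigma=1e-7)},
            n_trees={"BS_PBS": 2})
        bai = simulate_group_bai(truth, covariates, "BS_PBS", seed=3)
        res = BaiLinearModel(bai, covariates).fit(n_iter=10_000, burn_in=2_000,
                                                  seed=1)
        assert res.rsquared == pytest.approx(1.0, abs=1e-6)

    def test_matches_signal_fraction(self, covariates):
        # R² ≈ var(signal)/var(total) for known generating split
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0.0, 0.5, -0.5, -0.8, 0.6,
                                                sigma=0.4)},
            n_trees={"BS_PBS": 2})
        gp = truth.group_params["BS_PBS"]
        X = covariates.to_numpy()
        signal = gp.baseline + X @ gp.as_alpha_vector()[1:]
        r2s = []
        rng = np.random.default_rng(17)
        for _ in range(20):
            bai = simulate_group_bai(truth, covariates, "BS_PBS", rng=rng)
            res = BaiLinearModel(bai, covariates).fit(n_iter=6_000, burn_in=1_000,
                                                      seed=int(rng.integers(2**31)))
            r2s.append(res.rsquared)
        expected = np.var(signal) / (np.var(signal) + gp.sigma ** 2)
        assert np.mean(r2s) == pytest.approx(expected, abs=0.1)


class TestOverlap:
    def test_identical_sets_overlap_fully(self, rng):
        x = rng.normal(size=5_000)
        r = posterior_overlap(x, x)
        assert r.overlap == pytest.approx(1.0, abs=0.02)
        assert not r.significant

    def test_disjoint_supports_do_not_overlap(self, rng):
        r = posterior_overlap(rng.uniform(0, 1, 5_000),
                              rng.uniform(10, 11, 5_000))
        assert r.overlap == pytest.approx(0.0, abs=1e-6)
        assert r.significant

    def test_separated_normals_match_closed_form(self, rng):
        # OVL of N(0,1) vs N(5,1) is 2Φ(−2.5) ≈ 0.0124
        a = rng.normal(0, 1, 50_000)
        b = rng.normal(5, 1, 50_000)
        r = posterior_overlap(a, b)
        assert r.overlap == pytest.approx(2 * sps.norm.cdf(-2.5), abs=0.02)
        assert r.significant

    def test_symmetry_and_affine_invariance(self, rng):
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(1, 2, 20_000)
        r_ab = posterior_overlap(a, b)
        r_ba = posterior_overlap(b, a)
        assert r_ab.overlap == pytest.approx(r_ba.overlap, abs=1e-12)
        r_t = posterior_overlap(3 * a - 7, 3 * b - 7)
        assert r_t.overlap == pytest.approx(r_ab.overlap, abs=0.02)
        assert 0.0 <= r_ab.overlap <= 1.0

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_overlap(np.array([]), np.array([1.0]))


class TestConvergence:
    def test_long_chain_on_wellposed_data_passes(self, fitted):
        rep = fitted.convergence_report()
        assert rep.all_ok
        assert (rep.shrinkage.dropna() < 0.2).all()

    def test_short_drifting_chain_flagged(self):
        draws = pd.DataFrame({"alpha_baseline": np.linspace(0, 1, 10)})
        rep = ConvergenceReport.from_draws(draws)
        assert not rep.stable["alpha_baseline"]

    def test_bimodal_sample_flagged(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 2_000),
                            rng.normal(1, 0.05, 2_000)])
        rep = ConvergenceReport.from_draws(pd.DataFrame({"p": x}))
        assert not rep.unimodal["p"]
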