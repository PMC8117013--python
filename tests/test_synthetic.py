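"""Tests of the synthetic-data generator against its generating truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dendrobai.chronology import build_mean_chronology, ring_widths_to_bai
from dendrobai.covariates import build_covariate_table
from dendrobai.synthetic import (ClimateGenParams, GroupParams, SyntheticTruth,
                                 default_truth, generate_monthly_climate,
                                 simulate_dataset, simulate_group_bai,
                                 simulate_tree_ring_widths)


class TestMonthlyClimate:
    def test_zero_sd_reproduces_climatology_exactly(self):
        params = ClimateGenParams(tavg_sd_c=(0.0,) * 12, prcp_dispersion=0.0)
        clim = generate_monthly_climate(params, range(1950, 1960), seed=0)
        july = clim.data.query("month == 7")["tavg_c"]
        assert np.allclose(july, params.tavg_climatology_c[6])
        jan_prcp = clim.data.query("month == 1")["prcp_mm"]
        assert np.allclose(jan_prcp, params.prcp_mean_mm[0])

    def test_fixed_seed_is_deterministic(self):
        params = ClimateGenParams()
        a = generate_monthly_climate(params, range(1950, 2006), seed=11)
        b = generate_monthly_climate(params, range(1950, 2006), seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_monthly_climate(params, range(1950, 2006), seed=12)
        assert not a.data["tavg_c"].equals(c.data["tavg_c"])

    def test_july_mean_matches_generating_climatology(self):
        # 10,000 simulated Julys around the 16.9 °C boreal normal
        params = ClimateGenParams()
        clim = generate_monthly_climate(params, range(1, 10_001), seed=3)
        july = clim.data.query("month == 7")["tavg_c"]
        se = params.tavg_sd_c[6] / np.sqrt(10_000)
        assert abs(july.mean() - 16.9) < 3 * se

    def test_temperature_ordering_and_positive_precip(self):
        clim = generate_monthly_climate(ClimateGenParams(), range(1950, 1980), seed=5)
        df = clim.data
        assert (df["tmin_c"] <= df["tavg_c"]).all()
        assert (df["tavg_c"] <= df["tmax_c"]).all()
        assert (df["prcp_mm"] >= 0).all()

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            ClimateGenParams(tavg_sd_c=(-1.0,) * 12)

    def test_warming_option_adds_linear_trend(self):
        params = ClimateGenParams(tavg_sd_c=(0.0,) * 12,
                                  warming_slope_c_per_yr=0.02)
        clim = generate_monthly_climate(params, range(1950, 2006), seed=0)
        july = clim.data.query("month == 7").set_index("year")["tavg_c"]
        assert july.loc[2005] - july.loc[1950] == pytest.approx(0.02 * 55)


class TestGroupBai:
    def _flat_truth(self, **gp_kwargs):
        gp = dict(baseline=3.0, trend=0.0, season_length=0.0, summer_heat=0.0,
                  budworm=0.0, caterpillar=0.0, sigma=1e-12)
        gp.update(gp_kwargs)
        return SyntheticTruth(group_params={"BS_PBS": GroupParams(**gp)},
                              n_trees={"BS_PBS": 2})

    def test_baseline_only_gives_constant_series(self, covariates):
        truth = self._flat_truth()
        bai = simulate_group_bai(truth, covariates, "BS_PBS", seed=0)
        assert np.allclose(bai, 3.0, atol=1e-9)

    def test_budworm_effect_hits_epidemic_peak_year(self, covariates):
        truth = self._flat_truth(budworm=-1.0)
        bai = simulate_group_bai(truth, covariates, "BS_PBS", seed=0)
        assert bai.loc[1974] == pytest.approx(2.0, abs=1e-9)
        assert bai.loc[1965] == pytest.approx(3.0, abs=1e-9)

    def test_unknown_group_rejected(self, covariates):
        truth = self._flat_truth()
        with pytest.raises(KeyError):
            simulate_group_bai(truth, covariates, "TA_M", seed=0)

    def test_ar1_of_noise_recovered_in_monte_carlo(self, covariates):
        # 500 replicate paths: residual lag-1 autocorrelation ≈ ar1_coef
        phi = 0.6
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0, 0, 0, 0, 0, sigma=0.5)},
            n_trees={"BS_PBS": 2}, ar1_coef=phi)
        rng = np.random.default_rng(99)
        acs = []
        for _ in range(500):
            bai = simulate_group_bai(truth, covariates, "BS_PBS", rng=rng)
            e = bai.to_numpy() - 3.0
            acs.append(np.corrcoef(e[:-1], e[1:])[0, 1])
        acs = np.asarray(acs)
        # independent oracle: direct AR(1) recursion, same length; compares
        # estimator means so the known small-sample bias cancels
        n = len(bai)
        oracle_rng = np.random.default_rng(1234)
        ref = []
        for _ in range(2000):
            e = np.empty(n)
            e[0] = oracle_rng.normal(0, 0.5)
            z = oracle_rng.normal(0, 0.5 * np.sqrt(1 - phi ** 2), n - 1)
            for t in range(1, n):
                e[t] = phi * e[t - 1] + z[t - 1]
            ref.append(np.corrcoef(e[:-1], e[1:])[0, 1])
        ref = np.asarray(ref)
        se = np.sqrt(acs.var(ddof=1) / len(acs) + ref.var(ddof=1) / len(ref))
        assert abs(acs.mean() - ref.mean()) < 3 * se

    def test_marginal_sd_is_sigma(self, covariates):
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0, 0, 0, 0, 0, sigma=0.5)},
            n_trees={"BS_PBS": 2}, ar1_coef=0.7)
        rng = np.random.default_rng(4)
        draws = np.concatenate([
            (simulate_group_bai(truth, covariates, "BS_PBS", rng=rng) - 3.0).to_numpy()
            for _ in range(200)])
        assert draws.std() == pytest.approx(0.5, rel=0.05)


class TestTreeRingWidths:
    def test_single_noiseless_tree_round_trips_exactly(self):
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0, 0, 0, 0, 0, sigma=1e-12)},
            n_trees={"BS_PBS": 2}, tree_sd=0.0, tree_year_sd=0.0,
            max_pith_offset_mm=1e-9)
        years = pd.Index(range(1950, 2006), name="year")
        gb = pd.Series(2.5, index=years)
        trees = simulate_tree_ring_widths(truth, gb, "BS_PBS", seed=0)
        for t in trees:
            recovered = ring_widths_to_bai(t, pith_offset_mm=0.0)
            common = recovered.loc[t.first_year:]
            assert np.allclose(common, gb.loc[t.first_year:], rtol=1e-9)

    def test_group_mean_recovers_group_bai_within_sem(self):
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0, 0, 0, 0, 0, sigma=1e-12)},
            n_trees={"BS_PBS": 30}, tree_sd=0.2)
        years = pd.Index(range(1940, 2006), name="year")
        gb = pd.Series(np.linspace(2.0, 4.0, len(years)), index=years)
        trees = simulate_tree_ring_widths(truth, gb, "BS_PBS", seed=8)
        recomputed = pd.concat(
            [ring_widths_to_bai(t, t.true_pith_offset_mm) for t in trees], axis=1)
        recomputed = recomputed.sort_index().loc[1955:]   # all trees present
        mean = recomputed.mean(axis=1)
        sem = recomputed.std(axis=1, ddof=1) / np.sqrt(recomputed.shape[1])
        inside = np.abs(mean - gb.loc[1955:]) <= 3 * sem
        assert inside.mean() > 0.95

    def test_constant_bai_gives_strictly_decreasing_widths(self):
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0, 0, 0, 0, 0, sigma=1e-12)},
            n_trees={"BS_PBS": 3}, tree_sd=0.0, tree_year_sd=0.0,
            max_pith_offset_mm=1e-9)
        gb = pd.Series(2.0, index=pd.Index(range(1950, 2006), name="year"))
        trees = simulate_tree_ring_widths(truth, gb, "BS_PBS", seed=0)
        for t in trees:
            assert np.all(np.diff(t.widths_mm) < 0)

    def test_nonpositive_bai_rejected(self, truth):
        gb = pd.Series([1.0, -0.5, 2.0], index=pd.Index([1950, 1951, 1952]))
        with pytest.raises(ValueError):
            simulate_tree_ring_widths(truth, gb, "BS_PBS", seed=0)


class TestFullDataset:
    def test_determinism_and_seed_sensitivity(self, truth):
        a = simulate_dataset(truth, seed=2)
        b = simulate_dataset(truth, seed=2)
        c = simulate_dataset(truth, seed=3)
        g = next(iter(a.group_bai))
        pd.testing.assert_series_equal(a.group_bai[g], b.group_bai[g])
        assert not np.allclose(a.group_bai[g], c.group_bai[g])
        assert np.array_equal(a.trees[g][0].widths_mm, b.trees[g][0].widths_mm)

    def test_round_trip_through_chronology_pipeline(self, dataset):
        # widths → BAI → mean chronology recovers the simulated group BAI
        for group in ("BS_M", "TA_PTA"):
            ch = build_mean_chronology(dataset.trees[group], span=(1950, 2005))
            true = dataset.group_bai[group].loc[1950:2005].to_numpy()
            inside = np.abs(ch.mean_bai - true) <= 4 * np.maximum(ch.sem, 1e-6)
            assert inside.mean() > 0.9

    def test_mean_chronology_tracks_truth_over_replicates(self):
        # 200 replicate studies: the rebuilt mean chronology stays within
        # 3 SEM of the generating group BAI in ≥95% of years overall
        truth = SyntheticTruth(
            group_params={"BS_PBS": GroupParams(3.0, 0.0, 0.3, -0.3, -0.5,
                                                0.4, sigma=0.3)},
            n_trees={"BS_PBS": 8}, first_year=1925, last_year=1990,
            analysis_span=(1950, 1990))
        root = np.random.default_rng(321)
        inside = total = 0
        for _ in range(200):
            cov = build_covariate_table(None, truth.calendar,
                                        span=truth.analysis_span,
                                        years=truth.years)
            gb = simulate_group_bai(truth, cov, "BS_PBS", rng=root).clip(lower=0.05)
            trees = simulate_tree_ring_widths(truth, gb, "BS_PBS", rng=root)
            ch = build_mean_chronology(trees, span=truth.analysis_span)
            true = gb.loc[truth.analysis_span[0]:].to_numpy()
            ok = np.abs(ch.mean_bai - true) <= 3 * np.maximum(ch.sem, 1e-9)
            inside += ok.sum()
            total += ok.size
        assert inside / total >= 0.95

    def test_default_statistics_are_plausible(self, dataset):
        # smoke test: ranges typical of boreal chronologies, not a reproduction
        ar1s, widths = [], []
        for group, trees in dataset.trees.items():
            st = build_mean_chronology(trees, span=(1950, 2005)).stats
            ar1s.append(st.ar1)
            widths.append(st.mean_ring_width_mm)
            assert 0 < st.mean_sensitivity < 1
            assert 0 < st.series_intercorrelation <= 1
        assert all(0.5 <= w <= 2.0 for w in widths)
        assert 0.5 <= np.mean(ar1s) <= 0.85

    def test_persistent_noise_raises_width_autocorrelation(self, truth):
        ds = simulate_dataset(dataclasses.replace(truth, ar1_coef=0.7), seed=4)
        ar1s = [build_mean_chronology(t, span=(1950, 2005)).stats.ar1
                for t in ds.trees.values()]
        assert np.mean(ar1s) > 0.5

    def test_sidecar_written_with_truth(self, dataset, tmp_path):
        import json
        paths = dataset.write(tmp_path / "out")
        sidecar = json.loads((tmp_path / "out" / "truth.json").read_text())
        assert sidecar["group_params"]["BS_M"]["baseline"] == pytest.approx(3.0)
        assert "true_pith_offset_mm" in sidecar
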