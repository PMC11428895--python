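import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from pigspread import occsim, rates, synth
from pigspread.occsim import (
    BetaRateDistribution,
    InvasionModel,
    fit_beta_rates,
    fit_invasion_model,
    simulate,
)

from conftest import FixedRate


def two_unit_landscape(p_high=0.9, p_low=0.1):
    """Two coarse watersheds, one fine unit each, far apart."""
    counties = pd.DataFrame(
        {"county_id": [0, 1], "state_id": ["S00", "S00"],
         "area_km2": [100.0, 100.0], "cx": [0.0, 100.0], "cy": [0.0, 0.0]}
    )
    adjacency = pd.DataFrame({"county_id": [0, 1], "neighbor_id": [1, 0]})
    watersheds = pd.DataFrame(
        {"huc8_id": [0, 1], "region": ["west", "east"],
         "cx": [0.0, 100.0], "cy": [0.0, 0.0]}
    )
    fine_units = pd.DataFrame(
        {"huc12_id": [0, 1], "huc8_id": [0, 1],
         "cx": [0.0, 100.0], "cy": [0.0, 0.0]}
    )
    overlap = pd.DataFrame(
        {"county_id": [0, 1], "huc8_id": [0, 1], "weight": [1.0, 1.0]}
    )
    L = synth.Landscape(counties, adjacency, watersheds, fine_units, overlap)
    covs = pd.DataFrame(
        {"huc8_id": [0, 1], "ruggedness": [logit(p_high), logit(p_low)],
         "lewis_density": 0.0, "temp_range": 0.0, "precip": 0.0}
    )
    model = InvasionModel(
        variant="fixed",
        params=pd.Series(
            {"intercept": 0.0, "ruggedness": 1.0, "lewis_density": 0.0,
             "temp_range": 0.0, "precip": 0.0, "prev_rate": 0.0,
             "distance": 0.0}
        ),
        bse=pd.Series(dtype=float),
        feature_names=("intercept",) + synth.INVASION_PREDICTORS,
    )
    return L, covs, model


class TestFitBetaRates:
    def test_closed_form(self):
        b = fit_beta_rates([0.1, 0.2, 0.3])
        assert b.alpha == pytest.approx(3.0)
        assert b.beta == pytest.approx(12.0)

    def test_mean_matches_sample_mean(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0.05, 0.6, 25)
        b = fit_beta_rates(r)
        assert b.mean == pytest.approx(r.mean())

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fit_beta_rates([0.2, 0.2, 0.2])

    def test_overdispersed_errors(self):
        # v >= m(1-m): no valid beta
        with pytest.raises(ValueError):
            fit_beta_rates([0.01, 0.99, 0.01, 0.99])

    def test_zero_one_shrinkage(self):
        b = fit_beta_rates([0.0, 0.2, 0.5])
        assert b.alpha > 0 and b.beta > 0

    def test_too_few_rates(self):
        with pytest.raises(ValueError):
            fit_beta_rates([0.3])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BetaRateDistribution(0.0, 2.0)


class TestFitInvasionModel:
    @staticmethod
    def _zero_design(k, n):
        m = len(k)
        d = pd.DataFrame({"k": k, "n": n})
        for c in synth.INVASION_PREDICTORS:
            d[c] = 0.0
        d["region"] = "west"
        return d

    def test_intercept_only_closed_form(self):
        # overall invasion fraction 0.25 -> intercept = logit(0.25)
        d = self._zero_design([1, 2, 3], [4, 8, 12])
        m = fit_invasion_model(d, "fixed")
        assert m.params["intercept"] == pytest.approx(logit(0.25), abs=1e-6)

    def test_fixed_variant_has_no_region_offsets(self):
        d = self._zero_design([1, 2], [4, 4])
        m = fit_invasion_model(d, "fixed")
        assert not any("region" in f for f in m.feature_names)

    def test_regional_variants_have_offsets(self, landscape, history):
        _, huc12 = history
        resp = rates.watershed_response(huc12, landscape.fine_to_coarse())
        dyn = occsim.dynamic_covariates(huc12, landscape)
        _, huc8_covs = synth.make_covariates(landscape, [2013], seed=1)
        design = occsim.invasion_design(resp, huc8_covs, dyn, landscape)
        ri = fit_invasion_model(design, "ri")
        rs = fit_invasion_model(design, "rs")
        ri_offsets = [f for f in ri.feature_names if f.startswith("region[")]
        assert len(ri_offsets) == 3  # offsets for all but the baseline region
        assert any(":prev_rate" in f for f in rs.feature_names)
        assert any(":distance" in f for f in rs.feature_names)

    def test_all_invaded_rejected(self):
        d = self._zero_design([4, 4], [4, 4])
        with pytest.raises(ValueError, match="all-invaded"):
            fit_invasion_model(d, "fixed")

    def test_all_uninvaded_rejected(self):
        d = self._zero_design([0, 0], [4, 4])
        with pytest.raises(ValueError, match="all-uninvaded"):
            fit_invasion_model(d, "fixed")

    def test_missing_covariate_named(self):
        d = pd.DataFrame({"k": [1], "n": [4], "ruggedness": [0.0]})
        with pytest.raises(ValueError, match="lewis_density"):
            fit_invasion_model(d, "fixed")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            fit_invasion_model(self._zero_design([1], [4]), "mixed")


class TestParameterRecovery:
    def test_coefficients_within_three_se(self):
        # ~2,000 coarse watershed-years of truth-scenario data
        L = synth.make_landscape(100, 100, 20, seed=50)
        truth_coefs = {
            "ruggedness": 0.6, "lewis_density": -0.4, "temp_range": 0.08,
            "precip": -0.002, "prev_rate": 1.2, "distance": -0.02,
        }
        huc8_covs, huc12, truth = synth.make_truth_scenario(
            L, truth_coefs, years=range(2004, 2025), seed=51,
            intercept=-2.5, mode="bernoulli",
            ext_beta=(1e-6, 1.0),  # effectively no extinction
        )
        resp = rates.invasion_response(huc12, L.fine_to_coarse())
        dyn = occsim.dynamic_covariates(huc12, L)
        design = occsim.invasion_design(resp, huc8_covs, dyn, L)
        design = design[design["n"] > 0]
        model = fit_invasion_model(design, "fixed")
        for name, true_val in {**truth_coefs, "intercept": -2.5}.items():
            est, se = model.params[name], model.bse[name]
            assert abs(est - true_val) <= 3 * se, (
                f"{name}: est {est:.4f} truth {true_val} se {se:.4f}"
            )

    def test_beta_parameters_within_20pct(self):
        L = synth.make_landscape(16, 8, 25, seed=52)
        _, _, truth = synth.make_truth_scenario(
            L, [0.0] * 6, inv_beta=(3.0, 12.0), ext_beta=(2.0, 18.0),
            years=range(501), seed=53, mode="rate_constrained",
        )
        inv_fit = fit_beta_rates(truth.inv_rate_draws)
        ext_fit = fit_beta_rates(truth.ext_rate_draws)
        assert inv_fit.alpha == pytest.approx(3.0, rel=0.2)
        assert inv_fit.beta == pytest.approx(12.0, rel=0.2)
        assert ext_fit.alpha == pytest.approx(2.0, rel=0.2)
        assert ext_fit.beta == pytest.approx(18.0, rel=0.2)


class TestPredictInvasionProb:
    def test_all_zero_linear_predictor_gives_half(self):
        L, covs, model = two_unit_landscape()
        covs = covs.assign(ruggedness=0.0)
        status = pd.Series([False, False], index=[0, 1])
        p = occsim.predict_invasion_prob(model, covs, L, status)
        np.testing.assert_allclose(p, 0.5)

    def test_invaded_units_excluded(self):
        L, covs, model = two_unit_landscape()
        status = pd.Series([True, False], index=[0, 1])
        p = occsim.predict_invasion_prob(model, covs, L, status)
        assert list(p.index) == [1]

    def test_monotone_decreasing_in_distance(self):
        params = pd.Series(
            {"intercept": 0.0, "ruggedness": 0.0, "lewis_density": 0.0,
             "temp_range": 0.0, "precip": 0.0, "prev_rate": 0.0,
             "distance": -0.5}
        )
        model = InvasionModel("fixed", params, pd.Series(dtype=float),
                              ("intercept",) + synth.INVASION_PREDICTORS)
        d = pd.DataFrame(
            {c: 0.0 for c in synth.INVASION_PREDICTORS}, index=range(5)
        )
        d["distance"] = [0.0, 1.0, 2.0, 5.0, 10.0]
        p = model.predict_prob(d)
        assert (np.diff(p) < 0).all()

    def test_hand_computed_logit(self):
        params = pd.Series(
            {"intercept": -1.0, "ruggedness": 2.0, "lewis_density": 0.0,
             "temp_range": 0.0, "precip": 0.0, "prev_rate": 0.5,
             "distance": -0.1}
        )
        model = InvasionModel("fixed", params, pd.Series(dtype=float),
                              ("intercept",) + synth.INVASION_PREDICTORS)
        d = pd.DataFrame(
            {c: 0.0 for c in synth.INVASION_PREDICTORS}, index=range(3)
        )
        d["ruggedness"] = [0.0, 1.0, 0.5]
        d["prev_rate"] = [0.0, 0.2, 1.0]
        d["distance"] = [10.0, 0.0, 3.0]
        expected = expit(
            -1.0 + 2.0 * d["ruggedness"] + 0.5 * d["prev_rate"]
            - 0.1 * d["distance"]
        )
        np.testing.assert_allclose(model.predict_prob(d), expected, atol=1e-12)


class TestSimulate:
    def test_degenerate_rates_freeze_state(self):
        L, covs, model = two_unit_landscape()
        init = pd.Series([True, False], index=[0, 1])
        res = simulate(model, L, covs, init, FixedRate(0.0), FixedRate(0.0),
                       horizon=4, reps=8, seed=1)
        for r in range(8):
            for t in range(4):
                np.testing.assert_array_equal(res.fine_status[r, t],
                                              [True, False])

    def test_weighted_selection_frequency(self):
        # weights 0.9/0.1, one invasion per year, frequency within 3
        # binomial sigmas at 3,000 replicates
        L, covs, model = two_unit_landscape(0.9, 0.1)
        init = pd.Series([False, False], index=[0, 1])
        reps = 3000
        res = simulate(model, L, covs, init, FixedRate(0.5), FixedRate(0.0),
                       horizon=1, reps=reps, seed=2)
        freq = res.fine_status[:, 0, 0].mean()
        assert abs(freq - 0.9) < 3 * np.sqrt(0.9 * 0.1 / reps)

    def test_output_shape(self, landscape):
        _, covs, _ = two_unit_landscape()
        _, huc8_covs = synth.make_covariates(landscape, [2013], seed=3)
        model = InvasionModel(
            "fixed",
            pd.Series({"intercept": -1.0, **{c: 0.0 for c in
                                             synth.INVASION_PREDICTORS}}),
            pd.Series(dtype=float),
            ("intercept",) + synth.INVASION_PREDICTORS,
        )
        n_fine = len(landscape.fine_units)
        init = pd.Series(False, index=landscape.fine_units["huc12_id"])
        init.iloc[:3] = True
        res = simulate(model, landscape, huc8_covs, init,
                       BetaRateDistribution(3, 12),
                       BetaRateDistribution(2, 18),
                       horizon=8, reps=25, seed=4)
        assert res.fine_status.shape == (25, 8, n_fine)
        assert res.coarse_props.shape == (25, 8, 6)
        assert res.years == tuple(range(2014, 2022))

    def test_seed_reproducibility_and_stream_independence(self, landscape):
        _, huc8_covs = synth.make_covariates(landscape, [2013], seed=3)
        model = InvasionModel(
            "fixed",
            pd.Series({"intercept": -0.5, **{c: 0.0 for c in
                                             synth.INVASION_PREDICTORS}}),
            pd.Series(dtype=float),
            ("intercept",) + synth.INVASION_PREDICTORS,
        )
        init = pd.Series(False, index=landscape.fine_units["huc12_id"])
        init.iloc[:5] = True
        kw = dict(horizon=4, reps=12, seed=9)
        a = simulate(model, landscape, huc8_covs, init,
                     BetaRateDistribution(3, 12), BetaRateDistribution(2, 18),
                     **kw)
        b = simulate(model, landscape, huc8_covs, init,
                     BetaRateDistribution(3, 12), BetaRateDistribution(2, 18),
                     **kw)
        np.testing.assert_array_equal(a.fine_status, b.fine_status)
        # replicates are not all identical (independent streams)
        assert any(
            not np.array_equal(a.fine_status[0], a.fine_status[r])
            for r in range(1, 12)
        )

    def test_conservation_per_replicate_year(self, landscape):
        _, huc8_covs = synth.make_covariates(landscape, [2013], seed=3)
        model = InvasionModel(
            "fixed",
            pd.Series({"intercept": -0.5, **{c: 0.0 for c in
                                             synth.INVASION_PREDICTORS}}),
            pd.Series(dtype=float),
            ("intercept",) + synth.INVASION_PREDICTORS,
        )
        init = pd.Series(False, index=landscape.fine_units["huc12_id"])
        init.iloc[:5] = True
        res = simulate(model, landscape, huc8_covs, init,
                       BetaRateDistribution(3, 12),
                       BetaRateDistribution(2, 18),
                       horizon=5, reps=10, seed=10)
        for r in range(10):
            prev = int(init.sum())
            for t in range(5):
                now = int(res.fine_status[r, t].sum())
                assert now == prev + res.invasion_counts[r, t] \
                    - res.extinction_counts[r, t]
                prev = now

    def test_expected_growth_matches_beta_mean(self):
        # invasion mean m, extinction 0: invaded grows by ~ m x uninvaded
        L = synth.make_landscape(36, 6, 20, seed=55)
        _, huc8_covs = synth.make_covariates(L, [2013], seed=56)
        model = InvasionModel(
            "fixed",
            pd.Series({"intercept": 0.0, **{c: 0.0 for c in
                                            synth.INVASION_PREDICTORS}}),
            pd.Series(dtype=float),
            ("intercept",) + synth.INVASION_PREDICTORS,
        )
        init = pd.Series(False, index=L.fine_units["huc12_id"])
        init.iloc[:10] = True
        n_uninv = 110
        m = 0.05
        inv = BetaRateDistribution(5, 95)  # mean 0.05
        reps = 2000
        res = simulate(model, L, huc8_covs, init, inv, FixedRate(0.0),
                       horizon=1, reps=reps, seed=57)
        mean_new = res.invasion_counts[:, 0].mean()
        sd_rate = np.sqrt(5 * 95 / (100**2 * 101))
        tol = 3 * sd_rate * n_uninv / np.sqrt(reps) + 0.5
        assert abs(mean_new - m * n_uninv) < tol

    def test_count_capped_at_pool(self):
        L, covs, model = two_unit_landscape()
        init = pd.Series([False, False], index=[0, 1])
        res = simulate(model, L, covs, init, FixedRate(1.0), FixedRate(0.0),
                       horizon=1, reps=3, seed=11)
        assert (res.invasion_counts == 2).all()

    def test_bad_args(self):
        L, covs, model = two_unit_landscape()
        init = pd.Series([False, False], index=[0, 1])
        with pytest.raises(ValueError):
            simulate(model, L, covs, init, FixedRate(0), FixedRate(0),
                     horizon=0)
        with pytest.raises(ValueError):
            simulate(model, L, covs, init, FixedRate(0), FixedRate(0), reps=0)


class TestDistances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        xy = rng.uniform(0, 100, (n, 2))
        status = rng.random(n) < 0.3
        if not status.any():
            status[0] = True
        d = occsim.nearest_invaded_distance(xy, status)
        for i in range(n):
            if status[i]:
                assert d[i] == 0.0
            else:
                brute = min(
                    np.hypot(*(xy[i] - xy[j])) for j in range(n) if status[j]
                )
                assert d[i] == pytest.approx(brute)

    def test_zero_iff_invaded(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 10, (20, 2))
        status = np.zeros(20, dtype=bool)
        status[[2, 7]] = True
        d = occsim.nearest_invaded_distance(xy, status)
        assert (d[status] == 0).all()
        assert (d[~status] > 0).all()


class TestSummarize:
    @staticmethod
    def _result(coarse_props):
        arr = np.asarray(coarse_props, dtype=float)
        reps, horizon, n_coarse = arr.shape
        return occsim.SimulationResult(
            years=tuple(2014 + t for t in range(horizon)),
            fine_ids=np.arange(1),
            coarse_ids=np.arange(n_coarse),
            fine_status=np.zeros((reps, horizon, 1), dtype=bool),
            coarse_props=arr,
            invasion_counts=np.zeros((reps, horizon), dtype=int),
            extinction_counts=np.zeros((reps, horizon), dtype=int),
        )

    def test_single_replicate_median_is_trajectory(self):
        res = self._result([[[0.2], [0.7]]])
        s = occsim.summarize(res)
        assert list(s["median"]) == [0.2, 0.7]

    def test_median_definition(self):
        res = self._result([[[0.2]], [[0.4]], [[0.9]]])
        s = occsim.summarize(res)
        assert s["median"].iloc[0] == pytest.approx(0.4)

    def test_bands_contain_median(self, landscape):
        rng = np.random.default_rng(8)
        res = self._result(rng.uniform(size=(40, 3, 4)))
        s = occsim.summarize(res)
        assert (s["lo95"] <= s["median"]).all()
        assert (s["median"] <= s["hi95"]).all()


class TestToCounty:
    def test_full_overlap(self):
        props = pd.DataFrame({"huc8_id": [0], "year": [2014], "median": [0.4]})
        overlap = pd.DataFrame({"county_id": [0], "huc8_id": [0],
                                "weight": [1.0]})
        out = occsim.to_county(props, overlap)
        assert out["prop"].iloc[0] == pytest.approx(0.4)

    def test_even_split(self):
        props = pd.DataFrame({"huc8_id": [0, 1], "year": 2014,
                              "median": [0.2, 0.6]})
        overlap = pd.DataFrame({"county_id": [0, 0], "huc8_id": [0, 1],
                                "weight": [0.5, 0.5]})
        out = occsim.to_county(props, overlap)
        assert out["prop"].iloc[0] == pytest.approx(0.4)

    def test_all_zero(self):
        props = pd.DataFrame({"huc8_id": [0, 1], "year": 2014,
                              "median": [0.0, 0.0]})
        overlap = pd.DataFrame({"county_id": [0, 0], "huc8_id": [0, 1],
                                "weight": [0.5, 0.5]})
        assert (occsim.to_county(props, overlap)["prop"] == 0).all()

    def test_unnormalized_weights_rejected(self):
        props = pd.DataFrame({"huc8_id": [0], "year": [2014], "median": [0.4]})
        overlap = pd.DataFrame({"county_id": [0], "huc8_id": [0],
                                "weight": [0.7]})
        with pytest.raises(ValueError, match="not normalized"):
            occsim.to_county(props, overlap)
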