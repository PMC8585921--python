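"""Delta-GLM estimator contracts: closed-form oracle equivalence, AIC
selection, transform conventions, scale invariance, and uncertainty."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trawlkit import delta_glm, synthetic
from trawlkit.delta_glm import FitError


def _year_only_fit(hauls, stations, taxon="t"):
    return delta_glm.fit_delta_glm(hauls, stations, taxon, candidate_covariates=[()])


def _random_table(seed, n_years=3, hauls_per_year=12):
    """Small random hurdle table plus closed-form year-only MLEs."""
    rng = np.random.default_rng(seed)
    years = list(range(2001, 2001 + n_years))
    rows = []
    for y in years:
        for i in range(hauls_per_year):
            positive = rng.random() < 0.7
            cpue = float(np.round(np.exp(rng.normal(2.0, 1.0)))) if positive else 0.0
            rows.append({"haul_id": f"{y}-{i}", "year": y, "julian_day": 130 + i,
                         "night_id": f"{y}-n{i // 3}", "station_id": "S001",
                         "cpue_t": cpue})
    hauls = pd.DataFrame(rows)
    # ensure >= 1 positive per year so the closed form is defined everywhere
    for y in years:
        sub = hauls[hauls["year"] == y]
        if (sub["cpue_t"] == 0).all():
            hauls.loc[sub.index[0], "cpue_t"] = 5.0
    stations = pd.DataFrame(
        {"station_id": ["S001"], "region": ["north"], "depth_stratum": ["shelf"],
         "bottom_depth_m": [50.0], "distance_to_shore_km": [5.0],
         "reduced_year_flag": [True]})
    expected = {}
    for y in years:
        sub = hauls[hauls["year"] == y]["cpue_t"]
        p = (sub > 0).mean()
        mu = np.log(sub[sub > 0]).mean()
        expected[y] = p * np.exp(mu)
    return hauls, stations, expected


class TestOracleEquivalence:
    def test_worked_example_closed_form(self, worked_example):
        hauls, stations = worked_example
        fit = _year_only_fit(hauls, stations)
        idx = delta_glm.compute_index(fit)
        assert idx.table.loc[2001, "point_index"] == pytest.approx(
            0.5 * np.sqrt(27), abs=1e-6)
        assert idx.table.loc[2002, "point_index"] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_year_only_matches_proportion_times_geomean(self, seed):
        hauls, stations, expected = _random_table(seed)
        fit = _year_only_fit(hauls, stations)
        idx = delta_glm.compute_index(fit)
        for y, x in expected.items():
            assert idx.table.loc[y, "point_index"] == pytest.approx(x, abs=1e-6)

    def test_all_positive_degenerates_to_positive_model(self, worked_example):
        hauls, stations = worked_example
        hauls = hauls.copy()
        hauls["cpue_t"] = hauls["cpue_t"].replace(0, 1)
        fit = _year_only_fit(hauls, stations)
        assert fit.binomial_degenerate
        idx = delta_glm.compute_index(fit)
        for y in (2001, 2002):
            sub = hauls.loc[hauls["year"] == y, "cpue_t"]
            assert idx.table.loc[y, "point_index"] == pytest.approx(
                np.exp(np.log(sub).mean()), abs=1e-6)


class TestIndexConventions:
    def test_scale_invariance_and_z_stability(self, worked_example):
        hauls, stations = worked_example
        base = delta_glm.compute_index(_year_only_fit(hauls, stations))
        scaled_hauls = hauls.copy()
        scaled_hauls["cpue_t"] = scaled_hauls["cpue_t"] * 7.0
        scaled = delta_glm.compute_index(_year_only_fit(scaled_hauls, stations))
        np.testing.assert_allclose(scaled.table["point_index"],
                                   7.0 * base.table["point_index"], rtol=1e-9)
        np.testing.assert_allclose(scaled.table["z_score"], base.table["z_score"],
                                   rtol=1e-9)

    def test_z_scores_have_mean0_sd1_over_baseline(self, default_scenario):
        design, _, hauls = default_scenario
        idx = delta_glm.naive_index(hauls, "sanddab_like",
                                    baseline_years=range(1990, 2020))
        z = idx.table.loc[1990:2019, "z_score"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_positive_year_pinned_at_zero_with_flag(self, worked_example):
        hauls, stations = worked_example
        hauls = hauls.copy()
        hauls.loc[hauls["year"] == 2002, "cpue_t"] = 0.0
        fit = _year_only_fit(hauls, stations)
        idx = delta_glm.compute_index(fit)
        assert idx.table.loc[2002, "point_index"] == 0.0
        assert idx.table.loc[2002, "log_index"] == 0.0
        assert idx.table.loc[2002, "flag"] == "low_info"

    def test_lognormal_bias_correction_is_constant_multiplier(self, worked_example):
        hauls, stations = worked_example
        fit = _year_only_fit(hauls, stations)
        plain = delta_glm.compute_index(fit).table["point_index"]
        corr = delta_glm.compute_index(fit, bias_correct=True).table["point_index"]
        ratio = corr / plain
        assert ratio.std() == pytest.approx(0.0, abs=1e-12)
        assert (ratio > 1).all()


class TestAICSelection:
    def test_selected_set_attains_brute_force_minimum(self, default_scenario):
        design, _, hauls = default_scenario
        fit = delta_glm.fit_delta_glm(hauls, design, "anchovy_like")
        for sub in ("binomial", "positive"):
            tab = fit.aic_table[sub]
            assert tab[fit.selected_covariates[sub]] == min(tab.values())
            # never a strict superset with equal-or-higher AIC
            sel = set(fit.selected_covariates[sub])
            for cand, aic in tab.items():
                if set(cand) < sel:
                    assert tab[fit.selected_covariates[sub]] < aic

    def test_strong_depth_effect_is_selected(self):
        years = list(range(2001, 2005))
        hits = 0
        n_sim = 20
        for rep in range(n_sim):
            design = synthetic.make_design(n_stations=24, seed=rep)
            tax = synthetic.TaxonParams(
                "t", year_effects={y: 3.0 for y in years}, depth_association=1.5)
            hauls = synthetic.simulate_hauls(design, [tax], years,
                                             hauls_per_year=50, seed=100 + rep)
            fit = delta_glm.fit_delta_glm(
                hauls, design, "t", candidate_covariates=[(), ("depth_stratum",)])
            if fit.selected_covariates["positive"] == ("depth_stratum",):
                hits += 1
        assert hits >= 0.9 * n_sim

    def test_seasonal_candidates_included_for_rockfish_like(self, default_scenario):
        design, _, hauls = default_scenario
        fit = delta_glm.fit_delta_glm(hauls, design, "rockfish_like", seasonal=True)
        assert any("julian_bin" in cand for cand in fit.aic_table["positive"])


class TestUncertainty:
    @pytest.mark.parametrize("method", ["bootstrap", "posterior"])
    def test_interval_contains_point_and_se_finite(self, default_scenario, method):
        design, _, hauls = default_scenario
        fit = delta_glm.fit_delta_glm(hauls, design, "sanddab_like",
                                      candidate_covariates=[("depth_stratum",)])
        series = delta_glm.estimate_uncertainty(fit, method=method, n_draws=200,
                                                seed=5)
        tab = series.table
        assert (tab["lo95"] <= tab["point_index"]).all()
        assert (tab["hi95"] >= tab["point_index"]).all()
        assert np.isfinite(tab["se_log"]).all()

    def test_reduced_year_has_larger_se_than_full_years(self, default_scenario):
        design, _, hauls = default_scenario
        fit = delta_glm.fit_delta_glm(hauls, design, "sanddab_like",
                                      candidate_covariates=[()])
        series = delta_glm.estimate_uncertainty(fit, method="posterior",
                                                n_draws=400, seed=5)
        tab = series.table
        assert tab.loc[2020, "se_log"] > tab.loc[1990:2019, "se_log"].max()

    def test_fifteen_hauls_noisier_than_sixtytwo_paired(self):
        """Same generative year sampled at 15 vs 62 hauls: smaller effort
        gives a larger se_log in nearly all paired replicates."""
        years = [2001, 2002]
        wins = 0
        n_pairs = 15
        for rep in range(n_pairs):
            design = synthetic.make_design(n_stations=20, seed=rep)
            tax = synthetic.TaxonParams("t", year_effects={y: 3.0 for y in years})
            ses = {}
            for n in (15, 62):
                hauls = synthetic.simulate_hauls(design, [tax], years,
                                                 hauls_per_year=n, seed=200 + rep)
                fit = delta_glm.fit_delta_glm(hauls, design, "t",
                                              candidate_covariates=[()])
                s = delta_glm.estimate_uncertainty(fit, method="posterior",
                                                   n_draws=300, seed=rep)
                ses[n] = s.table.loc[2001, "se_log"]
            wins += ses[15] > ses[62]
        assert wins >= n_pairs - 1

    def test_too_few_draws_rejected(self, default_scenario):
        design, _, hauls = default_scenario
        fit = delta_glm.fit_delta_glm(hauls, design, "sanddab_like",
                                      candidate_covariates=[()])
        with pytest.raises(ValueError, match="n_draws"):
            delta_glm.estimate_uncertainty(fit, n_draws=50)


class TestNaiveIndex:
    def test_mean_log1p_arithmetic(self):
        hauls = pd.DataFrame(
            {"haul_id": ["a", "b", "c"], "year": 2001, "julian_day": 130,
             "night_id": "n", "station_id": "S001",
             "cpue_t": [0.0, np.e - 1, np.e ** 2 - 1]})
        idx = delta_glm.naive_index(hauls, "t")
        assert idx.table.loc[2001, "log_index"] == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_year_is_zero(self):
        hauls = pd.DataFrame(
            {"haul_id": ["a", "b"], "year": [2001, 2001], "julian_day": 130,
             "night_id": "n", "station_id": "S001", "cpue_t": [0.0, 0.0]})
        idx = delta_glm.naive_index(hauls, "t")
        assert idx.table.loc[2001, "log_index"] == 0.0


class TestFitErrors:
    def test_single_year_rejected(self, worked_example):
        hauls, stations = worked_example
        with pytest.raises(FitError, match="2 years"):
            delta_glm.fit_delta_glm(hauls[hauls["year"] == 2001], stations, "t")

    def test_too_few_positives_rejected(self, worked_example):
        hauls, stations = worked_example
        hauls = hauls.copy()
        hauls["cpue_t"] = 0.0
        hauls.loc[0, "cpue_t"] = 1.0
        with pytest.raises(FitError, match="positive"):
            delta_glm.fit_delta_glm(hauls, stations, "t")

    def test_unknown_taxon_rejected(self, worked_example):
        hauls, stations = worked_example
        with pytest.raises(KeyError, match="cpue_nope"):
            delta_glm.fit_delta_glm(hauls, stations, "nope")


class TestParameterRecovery:
    def test_year_contrasts_unbiased_on_hurdle_data(self):
        """Estimated log-index contrasts between two years track the true
        contrast with no systematic bias (continuous-catch mode)."""
        years = [2001, 2002]
        errs = []
        for rep in range(40):
            design = synthetic.make_design(n_stations=20, seed=1)
            tax = synthetic.TaxonParams(
                "t", year_effects={2001: 3.0, 2002: 2.3})
            hauls = synthetic.simulate_hauls(design, [tax], years,
                                             hauls_per_year=62, seed=300 + rep,
                                             integer_counts=False)
            fit = delta_glm.fit_delta_glm(hauls, design, "t",
                                          candidate_covariates=[()])
            idx = delta_glm.compute_index(fit).table["point_index"]
            errs.append(np.log(idx.loc[2001] / idx.loc[2002]) - 0.7)
        mean_err = np.mean(errs)
        mc_se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(mean_err) < 3 * mc_se + 0.01
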