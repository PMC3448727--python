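"""Mixed-model ANOVAs, covariate screening, hatchling ANOVA and regressions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import larvaclock.growth_stats as gs
import larvaclock.synthetic_data as sd

REGIONS = ("central", "northern", "northernmost")


def _balanced_records(
    rng,
    region_effects=(0.0, 0.0, 0.0),
    photo_effect=0.0,
    noise=0.002,
    n_subpops=2,
    n_fams=2,
    n_reps=3,
    interaction=None,
):
    """Balanced two-way records with optional effects, no latent clustering."""
    rows = []
    for r_idx, region in enumerate(REGIONS):
        for p in range(1, n_subpops + 1):
            pop = f"{region}-p{p}"
            for f in range(1, n_fams + 1):
                fam = f"{pop}-f{f}"
                for photo in ("southern", "northern"):
                    for rep in range(n_reps):
                        mu = 0.015 + region_effects[r_idx]
                        if photo == "northern":
                            mu += photo_effect
                            if interaction is not None:
                                mu += interaction[r_idx]
                        rows.append(
                            {
                                "individual_id": f"{fam}-{photo[0]}{rep}",
                                "family": fam,
                                "sub_population": pop,
                                "region": region,
                                "photoperiod": photo,
                                "summer_fall_rate": mu + rng.normal(0.0, noise),
                                "spring_rate": mu + rng.normal(0.0, noise),
                                "hatch_size_mm": 0.45 + rng.normal(0.0, 0.01),
                                "size_day84_mm": 1.2 + rng.normal(0.0, 0.05),
                            }
                        )
    return pd.DataFrame(rows)


class TestFitSeasonalModel:
    def test_pure_photoperiod_shift_detected(self, rng):
        records = _balanced_records(rng, photo_effect=0.005, noise=1e-6)
        fit = gs.fit_seasonal_model(
            records, "summer_fall", gs.ModelSpec(response="summer_fall_rate", covariate=None)
        )
        assert fit.term("C(photoperiod)").p < 1e-10
        # Null terms have uniform p-values; with the fixed seed both stay
        # clear of the rejection region.
        assert fit.term("C(region)").p > 0.05
        assert fit.term("C(region):C(photoperiod)").p > 0.05

    def test_region_effect_detected(self, rng):
        records = _balanced_records(rng, region_effects=(0.006, 0.0, -0.006))
        fit = gs.fit_seasonal_model(
            records, "summer_fall", gs.ModelSpec(response="summer_fall_rate", covariate=None)
        )
        region = fit.term("C(region)")
        assert region.df == 2
        assert region.p < 1e-6

    def test_crossing_interaction_detected(self, rng):
        records = _balanced_records(
            rng, interaction=(-0.006, 0.003, 0.003), noise=0.001
        )
        fit = gs.fit_seasonal_model(
            records, "spring", gs.ModelSpec(response="spring_rate", covariate=None)
        )
        inter = fit.term("C(region):C(photoperiod)")
        assert inter.df == 2
        assert inter.p < 1e-4

    def test_wald_two_level_factor_equals_z_squared(self, rng):
        # For a 2-level factor the Wald chi-square is (estimate/SE)^2.
        records = _balanced_records(rng, photo_effect=0.002)
        spec = gs.ModelSpec(
            response="summer_fall_rate", covariate=None, interaction=False
        )
        fit = gs.fit_seasonal_model(records, "summer_fall", spec)
        coef = fit.fixed_effects.loc["C(photoperiod)[T.southern]"]
        z2 = (coef["estimate"] / coef["se"]) ** 2
        assert fit.term("C(photoperiod)").chisq == pytest.approx(z2, rel=1e-6)

    def test_interaction_wald_vs_permutation_oracle(self, rng):
        # Freedman-Lane permutation of additive-model residuals as an
        # independent oracle for the interaction p-value on unclustered data.
        records = _balanced_records(
            rng, interaction=(-0.004, 0.002, 0.002), noise=0.004, n_subpops=1, n_fams=1,
            n_reps=4,
        )
        spec = gs.ModelSpec(response="summer_fall_rate", covariate=None)
        fit = gs.fit_seasonal_model(records, "summer_fall", spec)
        wald_p = fit.term("C(region):C(photoperiod)").p

        import patsy

        y = records["summer_fall_rate"].to_numpy()
        x_add = patsy.dmatrix("C(region) + C(photoperiod)", records)
        x_full = patsy.dmatrix("C(region) * C(photoperiod)", records)
        beta_add, *_ = np.linalg.lstsq(x_add, y, rcond=None)
        fitted = np.asarray(x_add) @ beta_add
        resid = y - fitted

        def interaction_stat(yv):
            beta, res_ss, *_ = np.linalg.lstsq(x_full, yv, rcond=None)
            rss_full = np.sum((yv - np.asarray(x_full) @ beta) ** 2)
            beta0, *_ = np.linalg.lstsq(x_add, yv, rcond=None)
            rss_add = np.sum((yv - np.asarray(x_add) @ beta0) ** 2)
            return rss_add - rss_full

        observed = interaction_stat(y)
        perm_rng = np.random.default_rng(99)
        draws = 2000
        hits = sum(
            interaction_stat(fitted + perm_rng.permutation(resid)) >= observed
            for _ in range(draws)
        )
        perm_p = (hits + 1) / (draws + 1)
        assert abs(wald_p - perm_p) < 0.05

    def test_empty_or_single_level_rejected(self, rng):
        records = _balanced_records(rng).query("photoperiod == 'northern'")
        with pytest.raises(ValueError, match="level"):
            gs.fit_seasonal_model(
                records, "summer_fall",
                gs.ModelSpec(response="summer_fall_rate", covariate=None),
            )


class TestScreenCovariate:
    def _spec(self):
        return gs.ModelSpec(response="summer_fall_rate", covariate=None)

    def test_response_as_covariate_is_kept(self, rng):
        records = _balanced_records(rng)
        records["leaky"] = records["summer_fall_rate"]
        decision, p = gs.screen_covariate(records, self._spec(), "leaky")
        assert decision == "keep"
        assert p < 1e-10

    def test_constant_covariate_dropped(self, rng):
        records = _balanced_records(rng)
        records["flat"] = 1.0
        decision, p = gs.screen_covariate(records, self._spec(), "flat")
        assert decision == "drop"
        assert np.isnan(p)

    def test_all_missing_covariate_dropped_with_warning(self, rng):
        records = _balanced_records(rng)
        records["ghost"] = np.nan
        with pytest.warns(UserWarning, match="all-missing"):
            decision, _ = gs.screen_covariate(records, self._spec(), "ghost")
        assert decision == "drop"

    def test_noise_covariate_usually_dropped(self):
        # Null covariates should survive screening at roughly the alpha rate.
        dropped = 0
        n_reps = 30
        for i in range(n_reps):
            rep_rng = np.random.default_rng(500 + i)
            records = _balanced_records(rep_rng, n_subpops=1, n_fams=2, n_reps=2)
            records["junk"] = rep_rng.normal(size=len(records))
            decision, _ = gs.screen_covariate(records, self._spec(), "junk")
            dropped += decision == "drop"
        assert dropped >= 0.8 * n_reps


class TestHatchlingAnova:
    def test_hand_computed_sums_of_squares(self):
        # 3 regions x 5 hatchlings, textbook one-way ANOVA by explicit SS.
        data = {
            "central": [0.42, 0.44, 0.43, 0.45, 0.41],
            "northern": [0.46, 0.47, 0.48, 0.46, 0.48],
            "northernmost": [0.50, 0.51, 0.49, 0.52, 0.50],
        }
        table = pd.DataFrame(
            [
                {"region": r, "family": f"{r}-f", "head_width_mm": w}
                for r, ws in data.items()
                for w in ws
            ]
        )
        grand = np.mean([w for ws in data.values() for w in ws])
        ss_between = sum(5 * (np.mean(ws) - grand) ** 2 for ws in data.values())
        ss_within = sum((w - np.mean(ws)) ** 2 for ws in data.values() for w in ws)
        expected_f = (ss_between / 2) / (ss_within / 12)
        f, df1, df2, p = gs.hatchling_anova(table)
        assert (df1, df2) == (2, 12)
        assert f == pytest.approx(expected_f, abs=1e-10)
        assert p < 0.001

    def test_zero_within_variance_distinct_means(self):
        table = pd.DataFrame(
            [
                {"region": r, "head_width_mm": w}
                for r, w in (("a", 0.4), ("a", 0.4), ("b", 0.5), ("b", 0.5))
            ]
        )
        f, _, _, p = gs.hatchling_anova(table)
        assert f >= 1e12
        assert p == 0.0

    def test_constant_data(self):
        table = pd.DataFrame({"region": ["a"] * 3 + ["b"] * 3, "head_width_mm": [0.5] * 6})
        f, _, _, p = gs.hatchling_anova(table)
        assert f == 0.0
        assert p == 1.0

    def test_singleton_region_excluded(self):
        table = pd.DataFrame(
            {
                "region": ["a", "a", "b", "b", "c"],
                "head_width_mm": [0.4, 0.42, 0.5, 0.52, 0.6],
            }
        )
        with pytest.warns(UserWarning, match="excluded"):
            f, df1, df2, _ = gs.hatchling_anova(table)
        assert (df1, df2) == (1, 2)

    def test_too_few_regions(self):
        table = pd.DataFrame({"region": ["a"] * 4, "head_width_mm": [0.4, 0.41, 0.42, 0.43]})
        with pytest.raises(ValueError):
            gs.hatchling_anova(table)


class TestAdultSizeModel:
    def test_identical_sexes_give_zero_sex_chisq(self, rng):
        rows = []
        for region in REGIONS:
            for w in 3.6 + rng.normal(0.0, 0.2, size=10):
                for sex in ("male", "female"):  # identical widths per pair
                    rows.append(
                        {
                            "region": region,
                            "population": f"{region}-a1",
                            "sex": sex,
                            "head_width_mm": w,
                        }
                    )
        fit = gs.adult_size_model(pd.DataFrame(rows))
        assert fit.term("C(sex)").chisq == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_limit_matches_ols_anova(self, rng):
        # One population per region with zero population variance: the mixed
        # fit collapses and must reproduce the fixed-effects two-way ANOVA.
        rows = []
        for region in REGIONS:
            for sex in ("male", "female"):
                for i in range(15):
                    rows.append(
                        {
                            "region": region,
                            "population": f"{region}-a1",
                            "sex": sex,
                            "head_width_mm": 3.6
                            + (0.03 if sex == "male" else 0.0)
                            + rng.normal(0.0, 0.1),
                        }
                    )
        adults = pd.DataFrame(rows)
        fit = gs.adult_size_model(adults)
        ols = smf.ols("head_width_mm ~ C(region) * C(sex)", data=adults).fit()
        for name in fit.fixed_effects.index:
            assert fit.fixed_effects.loc[name, "estimate"] == pytest.approx(
                ols.params[name], rel=1e-6, abs=1e-9
            )

    def test_sex_offset_recovered(self):
        adults = sd.simulate_adults(rng=7)
        fit = gs.adult_size_model(adults)
        contrasts = [e for e in fit.log if e.startswith("sex_contrast=")]
        assert contrasts, fit.log
        value = float(contrasts[0].split("=")[1])
        assert value == pytest.approx(0.06, abs=0.08)
        assert fit.term("C(sex)").df == 1
        assert fit.term("C(region)").df == 2
        assert fit.term("C(region):C(sex)").df == 2


class TestHatchGrowthRegression:
    def _records(self, slope, noise, rng, n=40):
        hatch = rng.uniform(0.40, 0.55, size=n)
        rate = 0.03 + slope * hatch + rng.normal(0.0, noise, size=n)
        return pd.DataFrame(
            {
                "individual_id": [f"i{i}" for i in range(n)],
                "family": [f"f{i % 10}" for i in range(n)],
                "photoperiod": "northern",
                "summer_fall_rate": rate,
                "spring_rate": rate,
                "hatch_size_mm": hatch,
            }
        )

    def test_exact_negative_relationship(self, rng):
        records = self._records(-0.05, 0.0, rng)
        fit = gs.hatch_growth_regression(records, "summer_fall")
        assert fit.sign == -1
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-0.05, abs=1e-12)

    def test_restricted_to_treatment(self, rng):
        records = self._records(-0.05, 0.001, rng)
        southern = records.copy()
        southern["photoperiod"] = "southern"
        southern["summer_fall_rate"] = -southern["summer_fall_rate"]
        fit = gs.hatch_growth_regression(
            pd.concat([records, southern], ignore_index=True), "summer_fall"
        )
        assert fit.n == len(records)
        assert fit.sign == -1

    def test_family_aggregation_mode(self, rng):
        records = self._records(-0.05, 0.001, rng)
        fit = gs.hatch_growth_regression(records, "summer_fall", unit="family")
        assert fit.n == records["family"].nunique()
        assert fit.sign == -1

    def test_null_association_small_r2(self):
        pvals = []
        for i in range(20):
            rep_rng = np.random.default_rng(900 + i)
            records = self._records(0.0, 0.005, rep_rng)
            pvals.append(gs.hatch_growth_regression(records, "summer_fall").p)
        # p-values roughly uniform under the null: not all small.
        assert np.mean(np.array(pvals) < 0.05) < 0.3

    def test_too_few_points(self, rng):
        records = self._records(-0.05, 0.0, rng, n=2)
        with pytest.raises(ValueError):
            gs.hatch_growth_regression(records, "summer_fall")
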