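"""Cohort derivation and association statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from quotedtext.cohort import (
    ContingencyTable,
    MISSING,
    bin_age,
    bin_contacts,
    bin_imd,
    bin_referral_year,
    crosstab,
    derive_cohort,
    distribution_report,
    fit_logistic,
    fit_logistic_grouped,
    map_ethnicity,
    map_icd10,
    odds_ratio_2x2,
    pearson_chi2,
    trend_chi2,
)


class TestCategoryMapping:
    @pytest.mark.parametrize(
        "raw,group",
        [
            ("Caribbean", "Black"),
            ("white and Asian", "Asian"),
            ("British", "White European"),
            ("any other ethnic group", "Other"),
            ("", MISSING),
            ("Martian", MISSING),
        ],
    )
    def test_ethnicity(self, raw, group):
        assert map_ethnicity(raw) == group

    @pytest.mark.parametrize(
        "code,group",
        [
            ("F20.0", "F2x"),
            ("Z63", "Zx"),
            ("", "Not recorded"),
            ("G40", "Any other letter x"),
            ("f33", "F3x"),
            (None, "Not recorded"),
        ],
    )
    def test_icd10(self, code, group):
        assert map_icd10(code) == group

    @pytest.mark.parametrize(
        "age,band", [(15, "1–15"), (16, "16–25"), (86, "86+"), (95, "86+"), (None, MISSING)]
    )
    def test_age_bands(self, age, band):
        assert bin_age(age) == band

    @pytest.mark.parametrize(
        "score,band",
        [(20, "0≤x≤20"), (20.0001, "20<x≤30"), (30, "20<x≤30"), (30.5, "30<x≤93"), (0, "0≤x≤20")],
    )
    def test_imd_boundaries_inclusive_upper(self, score, band):
        assert bin_imd(score) == band

    @pytest.mark.parametrize("n,band", [(0, "0"), (7, "1–7"), (43, "43+"), (60, "43+")])
    def test_contacts_bands(self, n, band):
        assert bin_contacts(n) == band

    def test_referral_schemes(self):
        assert bin_referral_year(2006) == "Before 2007"
        assert bin_referral_year(2019) == "2019–2020"
        assert bin_referral_year(2006, scheme="table2") == "1918–2014"
        assert bin_referral_year(2016, scheme="table2") == "2015–2020"
        with pytest.raises(ValueError):
            bin_referral_year(2000, scheme="bogus")


class TestCrosstab:
    def test_counts_match_generator_bookkeeping(self, small_registry):
        from quotedtext.synthetic import RegistryConfig, generate_registry

        reg, truth = generate_registry(RegistryConfig(n_patients=500, seed=3), return_truth=True)
        cohort = derive_cohort(reg)
        tab = crosstab(cohort, "inpatient_12m")
        # inpatient has no injected missingness, so counts equal the truth's
        expected = truth.groupby(["inpatient_12m", "has_quote"]).size()
        for i, lab in enumerate(tab.exposure_labels):
            if lab == MISSING:
                continue
            assert tab.counts[i, 0] == expected.get((lab, True), 0)
            assert tab.counts[i, 1] == expected.get((lab, False), 0)

    def test_all_missing_variable(self):
        cohort = pd.DataFrame(
            {"gender": [MISSING] * 4, "has_quote": [True, False, True, False]}
        )
        tab = crosstab(cohort, "gender")
        assert tab.exposure_labels == [MISSING]
        with pytest.raises(ValueError):
            pearson_chi2(tab)

    def test_unknown_variable(self):
        with pytest.raises(KeyError):
            crosstab(pd.DataFrame({"has_quote": [True]}), "nope")


def _table(rows, scores=None, variable="v"):
    return ContingencyTable(
        variable=variable,
        exposure_labels=[f"c{i}" for i in range(len(rows))],
        counts=np.asarray(rows),
        ordinal_scores=scores,
    )


class TestPearsonChi2:
    def test_equal_proportions_zero(self):
        r = pearson_chi2(_table([[10, 30], [20, 60]]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_invariance(self, rng):
        rows = rng.integers(5, 50, size=(4, 2))
        a = pearson_chi2(_table(rows.tolist()))
        b = pearson_chi2(_table(rows[::-1].tolist()))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.df == b.df

    def test_zero_margin_names_category(self):
        with pytest.raises(ValueError, match="c1"):
            pearson_chi2(_table([[5, 5], [0, 0]]))

    def test_missing_row_excluded(self):
        t = ContingencyTable(
            variable="v",
            exposure_labels=["a", "b", MISSING],
            counts=np.array([[10, 20], [15, 25], [99, 1]]),
        )
        with_missing_excluded = pearson_chi2(t)
        manual = pearson_chi2(_table([[10, 20], [15, 25]]))
        assert with_missing_excluded.statistic == pytest.approx(manual.statistic)


class TestTrendChi2:
    def test_equal_proportions_zero(self):
        r = trend_chi2(_table([[5, 15], [10, 30], [20, 60]], scores=[1, 2, 3]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_worked_closed_form(self):
        # scores (0,1,2), n=10 each, events (2,5,8): (N-1)·r² = 29·0.24 = 6.96
        r = trend_chi2(_table([[2, 8], [5, 5], [8, 2]], scores=[0, 1, 2]))
        assert r.statistic == pytest.approx(6.96, abs=1e-9)
        assert r.df == 1

    def test_never_exceeds_pearson(self, rng):
        for _ in range(20):
            rows = rng.integers(1, 40, size=(4, 2)).tolist()
            t = _table(rows, scores=[1, 2, 3, 4])
            assert trend_chi2(t).statistic <= pearson_chi2(t).statistic + 1e-9

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            trend_chi2(_table([[5, 5], [6, 4]], scores=[2, 2]))


class TestOddsRatio:
    def test_symmetry_is_one(self):
        assert odds_ratio_2x2(5, 5, 5, 5).odds_ratio == pytest.approx(1.0)

    def test_hand_computed_ci(self):
        est = odds_ratio_2x2(20, 10, 10, 20)
        assert est.odds_ratio == pytest.approx(4.0)
        assert est.se_log_or == pytest.approx(np.sqrt(0.3))
        assert est.ci_low == pytest.approx(np.exp(np.log(4) - 1.96 * np.sqrt(0.3)))
        assert round(est.ci_low, 2) == 1.37 and round(est.ci_high, 2) == 11.70

    def test_antisymmetry_under_row_swap(self):
        a = odds_ratio_2x2(20, 10, 7, 30)
        b = odds_ratio_2x2(7, 30, 20, 10)
        assert b.odds_ratio == pytest.approx(1 / a.odds_ratio)
        assert b.ci_low == pytest.approx(1 / a.ci_high)
        assert b.ci_high == pytest.approx(1 / a.ci_low)

    def test_zero_cell_requires_haldane(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 10, 5, 5)
        est = odds_ratio_2x2(0, 10, 5, 5, haldane=True)
        assert est.odds_ratio > 0


class TestLogistic:
    def test_saturated_binary_model_equals_2x2_or(self):
        # grouped counts: exposed 356/457, unexposed 8746/33042
        fit = fit_logistic_grouped([0, 1], [33042, 457], [8746, 356])
        est = odds_ratio_2x2(356, 457 - 356, 8746, 33042 - 8746)
        assert fit.terms["score"]["odds_ratio"] == pytest.approx(est.odds_ratio, abs=1e-6)

    def test_grouped_equals_subject_level(self):
        scores, totals, events = [1, 2, 3], [40, 50, 60], [5, 15, 30]
        g = fit_logistic_grouped(scores, totals, events)
        rows = []
        for s, n, e in zip(scores, totals, events):
            rows += [{"x": s, "y": 1}] * e + [{"x": s, "y": 0}] * (n - e)
        df = pd.DataFrame(rows)
        import statsmodels.api as sm

        res = sm.GLM(df["y"], sm.add_constant(df["x"].astype(float)),
                     family=sm.families.Binomial()).fit()
        assert g.terms["score"]["coefficient"] == pytest.approx(float(res.params.iloc[1]), abs=1e-6)

    def test_parameter_recovery_from_generator(self):
        from quotedtext.synthetic import RegistryConfig, generate_registry

        config = RegistryConfig(
            n_patients=30_000,
            quote_model_coefficients={"intercept": -1.0, ("inpatient_12m", "yes"): 2.0},
            missingness_rates={},
            seed=123,
        )
        reg, truth = generate_registry(config, return_truth=True)
        grouped = truth.groupby("inpatient_12m")["has_quote"].agg(["size", "sum"])
        fit = fit_logistic_grouped(
            [0.0, 1.0],
            [grouped.loc["no", "size"], grouped.loc["yes", "size"]],
            [grouped.loc["no", "sum"], grouped.loc["yes", "sum"]],
        )
        b0, b1 = fit.terms["intercept"], fit.terms["score"]
        assert abs(b0["coefficient"] - (-1.0)) <= 3 * b0["se"]
        assert abs(b1["coefficient"] - 2.0) <= 3 * b1["se"]

    def test_cohort_fit_complete_case_drops_missing(self):
        df = pd.DataFrame(
            {
                "gender": ["Female", "Male", MISSING, "Male"],
                "has_quote": [False, True, True, False],
            }
        )
        fit = fit_logistic(df, ["gender"])
        assert fit.n_used == 3

    def test_perfect_separation_flagged_not_raised(self):
        df = pd.DataFrame(
            {
                "gender": ["Female"] * 20 + ["Male"] * 20,
                "has_quote": [False] * 20 + [True] * 20,
            }
        )
        fit = fit_logistic(df, ["gender"])
        assert fit.converged is False

    def test_requires_a_predictor(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"has_quote": [True]}), [])


class TestDistributionReport:
    def test_planted_effect_directions_recovered(self):
        from quotedtext.synthetic import RegistryConfig, generate_registry

        reg = generate_registry(RegistryConfig(n_patients=8000, seed=5))
        cohort = derive_cohort(reg)
        report = distribution_report(cohort)
        un = report["unadjusted"].set_index(["variable", "level"])
        # generating model: inpatient strongly positive, referral recency negative
        assert un.loc[("inpatient_12m", "yes"), "odds_ratio"] > 1
        assert un.loc[("referral_band", "per category"), "odds_ratio"] < 1
        assert un.loc[("ethnicity5", "Black"), "odds_ratio"] > 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            distribution_report(pd.DataFrame())

    def test_degenerate_variable_skipped_with_reason(self):
        from quotedtext.synthetic import RegistryConfig, generate_registry

        reg = generate_registry(RegistryConfig(n_patients=300, seed=6))
        reg["gender"] = ""
        cohort = derive_cohort(reg)
        report = distribution_report(cohort)
        assert "gender" in set(report["skipped"]["variable"])
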