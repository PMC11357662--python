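"""Logistic association models: closed-form checks, trend, interaction, joint."""

import numpy as np
import pandas as pd
import pytest

from prsgre import datasets
from prsgre.exceptions import (ConfigurationError, EmptyCellWarning,
                               SeparationError)
from prsgre.models import (ModelSpec, add_prs_scales, fit_logistic,
                           interaction_test, joint_or_table, or_with_ci,
                           per_tertile_trend)


def frame_from_2x2(a, b, c, d):
    """Rows for counts: a=exposed cases, b=exposed controls, c, d unexposed."""
    rows = ([("non_advanced_adenoma", 1.0)] * a + [("no_finding", 1.0)] * b
            + [("non_advanced_adenoma", 0.0)] * c + [("no_finding", 0.0)] * d)
    return pd.DataFrame(rows, columns=["outcome_class", "E"])


SPEC_2X2 = ModelSpec(exposure="E", covariates=(), prs_term=None)


class TestFitLogistic:
    @pytest.mark.parametrize("cells", [
        (10, 20, 30, 40), (5, 50, 12, 7), (33, 21, 14, 60), (8, 8, 8, 8),
    ])
    def test_matches_closed_form_2x2(self, cells):
        a, b, c, d = cells
        fit = fit_logistic(SPEC_2X2, frame_from_2x2(a, b, c, d))
        assert fit.params["E"] == pytest.approx(np.log(a * d / (b * c)),
                                                abs=1e-6)

    def test_published_exposure_counts_give_crude_or(self):
        ctrl_low, case_low, ctrl_high, case_high = datasets.PROCESSED_MEAT_2X2
        fit = fit_logistic(SPEC_2X2, frame_from_2x2(case_high, ctrl_high,
                                                    case_low, ctrl_low))
        assert np.exp(fit.params["E"]) == pytest.approx(
            (case_high * ctrl_low) / (ctrl_high * case_low), abs=1e-4)
        assert np.exp(fit.params["E"]) == pytest.approx(1.573, abs=0.001)

    def test_null_predictor_within_three_se(self, analysis_frame):
        rng = np.random.default_rng(0)
        df = analysis_frame.copy()
        df["noise"] = rng.normal(size=len(df))
        fit = fit_logistic(ModelSpec(exposure="noise", covariates=(),
                                     prs_term=None), df)
        assert abs(fit.params["noise"]) < 3 * fit.se("noise")

    def test_separation_raises_with_diagnostics(self):
        df = frame_from_2x2(30, 0, 0, 30)  # predictor determines outcome
        with pytest.raises(SeparationError):
            fit_logistic(SPEC_2X2, df)

    def test_exposure_in_adjustment_set_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(exposure="bmi", covariates=("age", "bmi"))

    def test_reference_levels_follow_category_order(self, analysis_frame):
        spec = ModelSpec(exposure="processed_meat", covariates=("sex",),
                         prs_term="tertile")
        fit = fit_logistic(spec, analysis_frame)
        assert fit.term_columns["exposure"] == ["processed_meat[>1/week]"]
        assert fit.term_columns["prs"] == ["prs_tertile[T2]",
                                           "prs_tertile[T3]"]


class TestORWithCI:
    def test_wald_interval(self):
        fit = fit_logistic(SPEC_2X2, frame_from_2x2(10, 20, 30, 40))
        fit.params["E"] = 0.0
        fit.cov.loc["E", "E"] = 0.01
        orr, lo, hi = or_with_ci(fit, "E")
        assert (round(orr, 2), round(lo, 2), round(hi, 2)) == (1.0, 0.82, 1.22)

    def test_zero_se_collapses_interval(self):
        fit = fit_logistic(SPEC_2X2, frame_from_2x2(10, 20, 30, 40))
        fit.params["E"] = np.log(2.0)
        fit.cov.loc["E", "E"] = 0.0
        assert or_with_ci(fit, "E") == pytest.approx((2.0, 2.0, 2.0))

    def test_absent_term_rejected(self):
        fit = fit_logistic(SPEC_2X2, frame_from_2x2(10, 20, 30, 40))
        with pytest.raises(KeyError):
            or_with_ci(fit, "nope")


def test_trend_or_consistent_with_percentile_coefficient(analysis_frame):
    # One tertile step spans ~33.3 percentiles, so the ordinal-tertile OR
    # should approximate exp(33.33 * b_P) from the linear-percentile fit.
    spec = ModelSpec(exposure="processed_meat", covariates=("age", "sex"),
                     prs_term="percentile")
    lin = fit_logistic(spec, analysis_frame)
    trend = per_tertile_trend(spec, analysis_frame)
    implied = np.exp(33.33 * lin.params["prs_percentile"])
    fitted = np.exp(trend.params["prs_tertile_code"])
    assert abs(np.log(implied / fitted)) < 0.1


class TestInteraction:
    def _null_frame(self, n=4000, seed=1):
        rng = np.random.default_rng(seed)
        e = (rng.random(n) < 0.5).astype(float)
        pct = rng.permutation(n) * 100.0 / (n + 1)
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 0.2 * e + 0.0105 * pct)))
        y = np.where(rng.random(n) < p, "non_advanced_adenoma", "no_finding")
        return pd.DataFrame({"outcome_class": y, "E": e,
                             "prs_percentile": pct})

    def test_deterministic_given_data(self):
        df = self._null_frame()
        spec = ModelSpec(exposure="E", covariates=(), prs_term="percentile")
        p1 = interaction_test(spec, df)["p_value"]
        p2 = interaction_test(spec, df)["p_value"]
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0

    def test_wald_and_lrt_agree_at_large_n(self):
        df = self._null_frame(n=8000, seed=2)
        spec = ModelSpec(exposure="E", covariates=(), prs_term="percentile")
        pw = interaction_test(spec, df, method="wald")["p_value"]
        pl = interaction_test(spec, df, method="lrt")["p_value"]
        assert pw == pytest.approx(pl, abs=0.02)

    def test_detects_strong_interaction(self):
        rng = np.random.default_rng(3)
        n = 20000
        e = (rng.random(n) < 0.5).astype(float)
        x = (rng.random(n) < 0.5).astype(float)  # binary PRS-like contrast
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 0.2 * e + 0.3 * x + 0.5 * e * x)))
        y = np.where(rng.random(n) < p, "non_advanced_adenoma", "no_finding")
        df = pd.DataFrame({"outcome_class": y, "E": e, "prs_percentile": x})
        spec = ModelSpec(exposure="E", covariates=(), prs_term="percentile")
        assert interaction_test(spec, df)["p_value"] < 0.05


class TestJointTable:
    def test_reference_cell_is_exactly_one(self, analysis_frame):
        spec = ModelSpec(exposure="processed_meat", covariates=("age", "sex"))
        grid = joint_or_table(spec, analysis_frame)
        ref = grid.iloc[0]
        assert (ref["processed_meat"], ref["prs_tertile"]) == ("<=1/week", "T1")
        assert ref["OR"] == 1.0
        assert len(grid) == 6

    def test_grid_monotone_under_positive_effects(self):
        from prsgre.cohort import apply_exclusions
        from prsgre.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_participants=20000, b_E=0.3, seed=17)
        kept = apply_exclusions(simulate_cohort(cfg).phenotypes).kept
        df = add_prs_scales(kept, reference="cohort")
        spec = ModelSpec(exposure="processed_meat", covariates=())
        grid = joint_or_table(spec, df).set_index(
            ["processed_meat", "prs_tertile"])["OR"]
        for e in ("<=1/week", ">1/week"):
            assert grid[e]["T1"] < grid[e]["T2"] < grid[e]["T3"]
        for t in ("T1", "T2", "T3"):
            assert grid["<=1/week"][t] < grid[">1/week"][t]

    def test_empty_cell_flagged(self):
        rng = np.random.default_rng(4)
        n = 400
        df = pd.DataFrame({
            "outcome_class": rng.choice(["no_finding", "non_advanced_adenoma"], n),
            "processed_meat": pd.Categorical(
                rng.choice(["<=1/week", ">1/week"], n),
                categories=["<=1/week", ">1/week"]),
            "prs_tertile": pd.Categorical(
                rng.choice(["T1", "T2"], n), categories=["T1", "T2", "T3"]),
        })
        spec = ModelSpec(exposure="processed_meat", covariates=())
        with pytest.warns(EmptyCellWarning):
            grid = joint_or_table(spec, df)
        assert grid["OR"].isna().sum() == 2


def test_collapsibility_approximately_holds_at_low_prevalence():
    # Adding a covariate independent of outcome and exposure barely moves
    # the exposure coefficient when prevalence is low.
    rng = np.random.default_rng(5)
    n = 20000
    e = (rng.random(n) < 0.5).astype(float)
    p = 1.0 / (1.0 + np.exp(-(-3.2 + 0.3 * e)))
    y = np.where(rng.random(n) < p, "non_advanced_adenoma", "no_finding")
    df = pd.DataFrame({"outcome_class": y, "E": e,
                       "Z": rng.normal(size=n)})
    crude = fit_logistic(ModelSpec(exposure="E", covariates=()), df)
    adj = fit_logistic(ModelSpec(exposure="E", covariates=("Z",)), df)
    assert abs(adj.params["E"] - crude.params["E"]) < 0.5 * crude.se("E")
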