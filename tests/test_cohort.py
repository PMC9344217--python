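"""Exclusions, encoding, standardisation and the model suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foveapit import cohort as ch
from foveapit import synthetic as syn


@pytest.fixture(scope="module")
def cohort():
    return syn.generate_cohort(
        1500,
        effects={"sex_male": 0.36, "ethnicity_black": {"female": -0.7, "male": -0.8},
                 "income_trend": 0.06},
        seed=21)


class TestExclusions:
    def make_row(self, **over):
        base = {"person_id": "p0", "eye": "right", "sex": "female",
                "se_diopters": 0.0, "va_letters": 85.0}
        base.update({f: False for f in ch.EXCLUSION_FLAGS})
        base.update(over)
        return base

    def test_disease_flag_excluded_with_reason(self):
        df = pd.DataFrame([self.make_row(diabetic_retinopathy=True),
                           self.make_row(person_id="p1")])
        kept, tally = ch.apply_exclusions(df)
        assert len(kept) == 1
        assert tally["diabetic_retinopathy"] == 1

    def test_sensitivity_refraction_bounds(self):
        df = pd.DataFrame([self.make_row(se_diopters=-6.5),
                           self.make_row(person_id="p1", se_diopters=6.5),
                           self.make_row(person_id="p2", va_letters=79),
                           self.make_row(person_id="p3")])
        kept_plain, _ = ch.apply_exclusions(df, sensitivity=False)
        assert len(kept_plain) == 4
        kept, tally = ch.apply_exclusions(df, sensitivity=True)
        assert len(kept) == 1
        assert tally["se_below_minus6"] == 1
        assert tally["se_above_plus6"] == 1
        assert tally["va_below_80"] == 1

    def test_healthy_eye_retained_both_modes(self):
        df = pd.DataFrame([self.make_row(va_letters=85, se_diopters=0.0)])
        assert len(ch.apply_exclusions(df, False)[0]) == 1
        assert len(ch.apply_exclusions(df, True)[0]) == 1

    def test_missing_flags_rejected(self):
        with pytest.raises(ValueError, match="flags"):
            ch.apply_exclusions(pd.DataFrame({"person_id": ["p0"]}))

    def test_tally_order_and_first_reason_counting(self, cohort):
        kept, tally = ch.apply_exclusions(cohort)
        assert list(tally) == ch.EXCLUSION_FLAGS
        assert len(kept) + sum(tally.values()) == len(cohort)


class TestZscore:
    def test_simple_example(self):
        assert ch.zscore_fc([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            ch.zscore_fc([2.0, 2.0, 2.0])

    def test_round_trip(self):
        x = np.array([3.0, 1.0, 7.0, -2.0])
        z = ch.zscore_fc(x)
        assert np.allclose(z * x.std(ddof=1) + x.mean(), x)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40, unique=True))
    def test_idempotence(self, values):
        z = ch.zscore_fc(values)
        assert np.allclose(ch.zscore_fc(z), z, atol=1e-10)


class TestEncoding:
    def test_reporting_increments(self, cohort):
        X = ch.encode_covariates(cohort, ch.ModelSpec(3, stratum="female"))
        row = cohort.iloc[0]
        assert X.iloc[0]["age_per_decade"] == pytest.approx(row["age"] / 10)
        assert X.iloc[0]["cprt_per_10um"] == pytest.approx(row["cprt_um"] / 10)
        assert X.iloc[0]["mc_per_001"] == pytest.approx(row["mc"] / 0.01)
        assert X.iloc[0]["height_per_5cm"] == pytest.approx(row["height_cm"] / 5)

    def test_missing_category_gets_own_level(self, cohort):
        df = cohort.copy()
        df.loc[df.index[0], "ethnicity"] = "missing"
        X = ch.encode_covariates(df, ch.ModelSpec(1))
        assert "ethnicity_missing" in X.columns
        assert X.iloc[0]["ethnicity_missing"] == 1.0

    def test_unknown_category_raises(self, cohort):
        df = cohort.copy()
        df.loc[df.index[0], "ethnicity"] = "klingon"
        with pytest.raises(ValueError, match="unknown ethnicity"):
            ch.encode_covariates(df, ch.ModelSpec(1))

    def test_model_nesting(self, cohort):
        """Model 2 extends model 1; model 3 extends model 2."""
        specs = {m: set(ch.encode_covariates(cohort, ch.ModelSpec(m, stratum="female")))
                 for m in (1, 2, 3)}
        assert specs[1] < specs[2] < specs[3]

    def test_pooled_design_contains_sex(self, cohort):
        X = ch.encode_covariates(cohort, ch.ModelSpec(1, stratum=None))
        assert "sex_male" in X.columns

    def test_income_trend_scoring(self, cohort):
        X = ch.encode_covariates(cohort, ch.ModelSpec(3, income_as_trend=True))
        informative = cohort["income"].isin(syn.INCOME_INFORMATIVE)
        assert set(np.unique(X.loc[informative.to_numpy(), "income_trend"])) <= {1, 2, 3, 4, 5}
        assert (X.loc[~informative.to_numpy(), "income_trend"] == 0).all()
        assert "income_prefer_not" in X.columns
        assert "income_18_31k" not in X.columns


class TestFits:
    def test_effects_recovered_within_ci(self, cohort):
        included, _ = ch.apply_exclusions(cohort)
        f1 = ch.fit_multilevel(included, ch.ModelSpec(1, "fc_raw", None))
        lo, hi = f1.fit.ci("sex_male")
        assert lo < 0.36 < hi
        f3f = ch.fit_multilevel(included, ch.ModelSpec(3, "fc_raw", "female"))
        lo, hi = f3f.fit.ci("ethnicity_black")
        assert lo < -0.7 < hi

    def test_zscore_outcome_is_raw_over_sd(self, cohort):
        included, _ = ch.apply_exclusions(cohort)
        raw = ch.fit_multilevel(included, ch.ModelSpec(1, "fc_raw", "female"))
        z = ch.fit_multilevel(included, ch.ModelSpec(1, "fc_z", "female"))
        sd = included["fc_raw"].std(ddof=1)
        slopes = [t for t in z.params.index if t != "intercept"]
        assert np.allclose(z.params.loc[slopes, "estimate"],
                           raw.params.loc[slopes, "estimate"] / sd, atol=1e-7)

    def test_income_trend_recovery_and_errors(self, cohort):
        included, _ = ch.apply_exclusions(cohort)
        res = ch.linear_trend_test(included, ch.ModelSpec(3, "fc_raw", "male"))
        lo, hi = res.fit.ci("income_trend")
        assert lo < 0.06 < hi
        single = included.copy()
        single["income"] = "lt_18k"
        with pytest.raises(ValueError, match="informative income"):
            ch.linear_trend_test(single, ch.ModelSpec(3, "fc_raw", "male"))

    def test_empty_stratum_rejected(self, cohort):
        males_only = cohort[cohort.sex == "male"]
        with pytest.raises(ValueError, match="stratum"):
            ch.fit_multilevel(males_only, ch.ModelSpec(1, "fc_raw", "female"))

    def test_n_eyes_at_most_twice_persons(self, cohort):
        included, _ = ch.apply_exclusions(cohort)
        res = ch.fit_multilevel(included, ch.ModelSpec(1, "fc_raw", "female"))
        assert res.n_eyes <= 2 * res.n_persons


class TestSuite:
    @pytest.fixture(scope="class")
    def suite(self, cohort):
        return ch.run_analysis_suite(cohort, models=(1, 3), sensitivity=True)

    def test_expected_tables_present(self, suite):
        names = set(suite["tables"])
        assert {"model1_female", "model1_male", "model3_female", "model3_male",
                "sex_difference", "income_trend_female", "income_trend_male",
                "sensitivity_model3_female", "sensitivity_model3_male"} <= names

    def test_model1_fixed_effects(self, suite):
        terms = set(suite["tables"]["model1_female"]["term"])
        assert "age_per_decade" in terms
        assert "height_per_5cm" in terms
        assert "ethnicity_black" in terms
        assert any(t.startswith("center_") for t in terms)
        assert "va_per_5letters" not in terms  # model-2 covariate

    def test_strata_share_term_structure(self, suite):
        f = list(suite["tables"]["model3_female"]["term"])
        m = list(suite["tables"]["model3_male"]["term"])
        assert f == m

    def test_sex_difference_attenuation_direction(self):
        """With a positive height effect confounding the sex difference,
        the crude male-female gap exceeds the height-adjusted one."""
        df = syn.generate_cohort(
            3000, effects={"sex_male": 0.36, "height_per_5cm": 0.10}, seed=22)
        out = ch.run_analysis_suite(df, models=(1,), sensitivity=False,
                                    outcome="fc_raw")
        t = out["tables"]["sex_difference"].set_index("term")
        crude = t.loc["sex_male_crude", "estimate"]
        adjusted = t.loc["sex_male_model1", "estimate"]
        assert crude > adjusted
        assert adjusted == pytest.approx(0.36, abs=0.15)

    def test_exclusion_tally_reported(self, suite):
        assert "diabetic_retinopathy" in suite["exclusions"]
        assert "sensitivity_va_below_80" in suite["exclusions"]
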