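"""Cohort-level association analysis of foveal curvature.

Implements the epidemiological stage of the pipeline: eye-level
exclusions, z-standardisation of the FC outcome, covariate encoding on
the reporting increments, and sex-stratified multilevel models 1-3 with
a person-level random intercept (eyes nested in participants), fitted by
REML with Satterthwaite-approximated coefficient tests.

Model 1 adjusts for age, ethnicity, height and assessment centre;
model 2 adds the ocular covariates (VA, SE, corneal astigmatism, IOP,
macular curvature, centre-point retinal thickness); model 3 adds
deprivation, education, fluid intelligence, income and birth order.
Missing categorical data are kept as an explicit extra level of each
variable.  Continuous covariates enter per their reporting increment:
age per decade, height per 5 cm, VA per 5 letters, CPRT per 10 um, MC
per 0.01, SE and astigmatism per diopter, IOP per mm Hg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic as syn
from .mixedlm import MixedFitResult, fit_random_intercept

#: continuous covariates -> (source column, divisor, design term name)
CONTINUOUS_TERMS = {
    "age": ("age", 10.0, "age_per_decade"),
    "height": ("height_cm", 5.0, "height_per_5cm"),
    "va": ("va_letters", 5.0, "va_per_5letters"),
    "se": ("se_diopters", 1.0, "se_per_diopter"),
    "astigmatism": ("astigmatism_diopters", 1.0, "astigmatism_per_diopter"),
    "iop": ("iop_mmhg", 1.0, "iop_per_mmhg"),
    "mc": ("mc", 0.01, "mc_per_001"),
    "cprt": ("cprt_um", 10.0, "cprt_per_10um"),
    "fluid_intelligence": ("fluid_intelligence", 1.0, "fluid_intelligence"),
}

#: categorical covariates -> closed level list (first level = reference)
CATEGORICAL_LEVELS = {
    "ethnicity": syn.ETHNICITY_LEVELS,
    "center": syn.CENTER_LEVELS,
    "townsend": syn.TOWNSEND_LEVELS,
    "education": syn.EDUCATION_LEVELS,
    "income": syn.INCOME_LEVELS,
    "birth_order": syn.BIRTH_ORDER_LEVELS,
}

MODEL_COVARIATES = {
    1: ["age", "ethnicity", "height", "center"],
    2: ["age", "ethnicity", "height", "center",
        "va", "se", "astigmatism", "iop", "mc", "cprt"],
    3: ["age", "ethnicity", "height", "center",
        "va", "se", "astigmatism", "iop", "mc", "cprt",
        "townsend", "education", "fluid_intelligence", "income", "birth_order"],
}

EXCLUSION_FLAGS = list(syn.DISEASE_FLAGS)


@dataclass
class ModelSpec:
    """One multilevel model: covariate set, outcome, stratum, options."""

    model_id: int = 1
    outcome: str = "fc_z"  # fc_z | fc_raw | fc_raw_x100
    stratum: str | None = None  # "female" | "male" | None (pooled + sex term)
    income_as_trend: bool = False

    def covariates(self) -> list[str]:
        try:
            return MODEL_COVARIATES[self.model_id]
        except KeyError:
            raise ValueError(f"unknown model id {self.model_id!r}") from None


@dataclass
class FitResult:
    """Mixed-model fit plus analysis metadata."""

    fit: MixedFitResult
    model: ModelSpec
    n_eyes: int
    n_persons: int
    dropped_terms: list = field(default_factory=list)

    @property
    def params(self) -> pd.DataFrame:
        return self.fit.params


# ---------------------------------------------------------------------------
# exclusions and standardisation
# ---------------------------------------------------------------------------

def apply_exclusions(cohort: pd.DataFrame, sensitivity: bool = False):
    """Eye-level exclusion filter with a per-reason tally.

    Disease/surgery-flagged eyes are always removed; with
    sensitivity=True, eyes with SE beyond +/-6 D or VA below 80 ETDRS
    letters are additionally removed.  Each eye counts toward the first
    matching reason, in application order.
    """
    missing = [f for f in EXCLUSION_FLAGS if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks exclusion flags: {missing}")
    keep = np.ones(len(cohort), dtype=bool)
    tally: dict[str, int] = {}
    for flag in EXCLUSION_FLAGS:
        hit = keep & cohort[flag].astype(bool).to_numpy()
        tally[flag] = int(hit.sum())
        keep &= ~hit
    if sensitivity:
        for reason, hit in [
            ("se_below_minus6", cohort["se_diopters"].to_numpy() < -6),
            ("se_above_plus6", cohort["se_diopters"].to_numpy() > 6),
            ("va_below_80", cohort["va_letters"].to_numpy() < 80),
        ]:
            hit = keep & hit
            tally[reason] = int(hit.sum())
            keep &= ~hit
    return cohort.loc[keep].copy(), tally


def zscore_fc(values) -> np.ndarray:
    """Standardise FC to zero mean / unit sample SD (the z-score outcome)."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to standardise")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero standard deviation; cannot z-score")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------

def encode_covariates(table: pd.DataFrame, model: ModelSpec) -> pd.DataFrame:
    """Design matrix (with intercept) on the reporting-increment scale.

    Continuous covariates are divided by their stated increment;
    categoricals are dummy-coded against their reference level with the
    explicit "missing" level kept as its own dummy.  With
    model.income_as_trend the ordered income bands collapse to a single
    1..5 score while non-informative levels keep their dummies.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    if model.stratum is None:
        cols["sex_male"] = (table["sex"] == "male").to_numpy(float)
    for cov in model.covariates():
        if cov in CONTINUOUS_TERMS:
            src, div, name = CONTINUOUS_TERMS[cov]
            cols[name] = table[src].to_numpy(float) / div
        elif cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            values = table[cov].astype(str)
            unknown = set(values.unique()) - set(levels)
            if unknown:
                raise ValueError(f"unknown {cov} categories: {sorted(unknown)}")
            if cov == "income" and model.income_as_trend:
                score = np.zeros(len(table))
                for i, lev in enumerate(syn.INCOME_INFORMATIVE):
                    score[(values == lev).to_numpy()] = i + 1
                cols["income_trend"] = score
                for lev in levels[1:]:
                    if lev not in syn.INCOME_INFORMATIVE:
                        cols[f"income_{lev}"] = (values == lev).to_numpy(float)
            else:
                for lev in levels[1:]:
                    cols[f"{cov}_{lev}"] = (values == lev).to_numpy(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=table.index)


def _outcome(table: pd.DataFrame, full_table: pd.DataFrame, model: ModelSpec):
    if model.outcome == "fc_z":
        mu = full_table["fc_raw"].mean()
        sd = full_table["fc_raw"].std(ddof=1)
        if sd <= 0:
            raise ValueError("zero FC variance in the analysis sample")
        return (table["fc_raw"].to_numpy(float) - mu) / sd
    if model.outcome == "fc_raw":
        return table["fc_raw"].to_numpy(float)
    if model.outcome == "fc_raw_x100":
        return 100.0 * table["fc_raw"].to_numpy(float)
    raise ValueError(f"unknown outcome {model.outcome!r}")


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_multilevel(table: pd.DataFrame, model: ModelSpec) -> FitResult:
    """REML fit of the spec'd model on (a stratum of) the analysis table.

    The z-score reference is the full table passed in (both sexes pooled),
    computed before any stratum subsetting.
    """
    if model.stratum is not None:
        sub = table[table["sex"] == model.stratum]
        if sub.empty:
            raise ValueError(f"stratum {model.stratum!r} is empty")
    else:
        sub = table
    X = encode_covariates(sub, model)
    dropped = [c for c in X.columns if c != "intercept" and X[c].std() == 0]
    X = X.drop(columns=dropped)
    y = _outcome(sub, table, model)
    fit = fit_random_intercept(X, y, sub["person_id"].to_numpy())
    return FitResult(fit=fit, model=model, n_eyes=len(sub),
                     n_persons=sub["person_id"].nunique(), dropped_terms=dropped)


def linear_trend_test(table: pd.DataFrame, model: ModelSpec) -> FitResult:
    """Refit with income scored 1..5 as a single ordered term.

    Non-informative income levels ("prefer not to say", missing) keep
    their adjustment dummies but do not contribute to the score.
    """
    sub = table if model.stratum is None else table[table["sex"] == model.stratum]
    informative = sub["income"].isin(syn.INCOME_INFORMATIVE)
    if sub.loc[informative, "income"].nunique() < 3:
        raise ValueError("need >= 3 informative income levels for a trend test")
    trend_model = ModelSpec(model_id=model.model_id, outcome=model.outcome,
                            stratum=model.stratum, income_as_trend=True)
    if "income" not in trend_model.covariates():
        raise ValueError(f"model {model.model_id} does not include income")
    return fit_multilevel(table, trend_model)


# ---------------------------------------------------------------------------
# analysis suite
# ---------------------------------------------------------------------------

def _table_from_fit(res: FitResult) -> pd.DataFrame:
    t = res.params.copy()
    t["n_eyes"] = res.n_eyes
    t["n_persons"] = res.n_persons
    return t.reset_index()


def run_analysis_suite(cohort: pd.DataFrame, models=(1, 2, 3),
                       sensitivity: bool = True, outcome: str = "fc_z"):
    """Exclusions, then every (model, stratum) fit plus the pooled sex
    difference and income trend; optional sensitivity refits.

    Returns {"tables": {name: DataFrame}, "exclusions": tally dict}.
    """
    included, tally = apply_exclusions(cohort, sensitivity=False)
    tables: dict[str, pd.DataFrame] = {}
    for mid in models:
        pair = {s: _table_from_fit(fit_multilevel(included, ModelSpec(mid, outcome, s)))
                for s in ("female", "male")}
        # strata share one term structure even if a rare level is absent
        # (and hence dropped) in one of them
        terms = list(dict.fromkeys(
            list(pair["female"]["term"]) + list(pair["male"]["term"])))
        for s, tab in pair.items():
            tables[f"model{mid}_{s}"] = (
                tab.set_index("term").reindex(terms).reset_index())
    # crude and model-1-adjusted pooled sex difference
    crude = fit_multilevel(included, ModelSpec(1, outcome, None))
    Xs = pd.DataFrame({"intercept": np.ones(len(included)),
                       "sex_male": (included["sex"] == "male").to_numpy(float)},
                      index=included.index)
    y = _outcome(included, included, ModelSpec(1, outcome, None))
    crude_fit = fit_random_intercept(Xs, y, included["person_id"].to_numpy())
    tables["sex_difference"] = pd.DataFrame({
        "term": ["sex_male_crude", "sex_male_model1"],
        "estimate": [crude_fit.params.loc["sex_male", "estimate"],
                     crude.params.loc["sex_male", "estimate"]],
        "ci_low": [crude_fit.params.loc["sex_male", "ci_low"],
                   crude.params.loc["sex_male", "ci_low"]],
        "ci_high": [crude_fit.params.loc["sex_male", "ci_high"],
                    crude.params.loc["sex_male", "ci_high"]],
        "p": [crude_fit.params.loc["sex_male", "p"],
              crude.params.loc["sex_male", "p"]],
    })
    if 3 in models:
        for stratum in ("female", "male"):
            res = linear_trend_test(included, ModelSpec(3, outcome, stratum))
            tables[f"income_trend_{stratum}"] = _table_from_fit(res)
    if sensitivity:
        sens_included, sens_tally = apply_exclusions(cohort, sensitivity=True)
        for stratum in ("female", "male"):
            res = fit_multilevel(sens_included, ModelSpec(3, outcome, stratum))
            tables[f"sensitivity_model3_{stratum}"] = _table_from_fit(res)
        tally = {**tally, **{f"sensitivity_{k}": v for k, v in sens_tally.items()}}
    return {"tables": tables, "exclusions": tally}
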