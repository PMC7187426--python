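"""Usual-intake estimator: parameter recovery, invariances, edge cases."""

import numpy as np
import pandas as pd
import pytest

from vitaplan.intake import (EarTable, UsualIntake, VarianceIdentificationError,
                             fit_usual_intake, prevalence_inadequate)
from vitaplan.regions import Region
from vitaplan.survey import generate_survey


def _simulated(profile, ear_table, n=1500, seed=7, within_cv=None, repeat=0.3):
    if within_cv is not None:
        profile = profile.with_updates(within_cv=within_cv)
    return generate_survey(profile, n, repeat, seed=seed, ear_table=ear_table)


@pytest.mark.parametrize("region", [Region.NORTH, Region.SOUTH])
@pytest.mark.parametrize("within_cv", [0.3, 0.5, 0.7])
def test_prevalence_recovery_across_within_cv_grid(profiles, ear_table, region,
                                                   within_cv):
    """Estimated prevalence below the EAR within +/-0.02 of generator truth
    for n >= 1000 across the within-person variability grid."""
    df = _simulated(profiles[region], ear_table, n=1500, seed=31, within_cv=within_cv)
    res = UsualIntake(df).fit()
    truth = (df["usual_intake_true"].to_numpy() < ear_table.for_records(df)).mean()
    assert res.prevalence_inadequate(ear_table) == pytest.approx(truth, abs=0.02)


def test_variance_components_recovered(profiles, ear_table):
    profile = profiles[Region.NORTH]
    df = _simulated(profile, ear_table, n=20_000, seed=13)
    res = UsualIntake(df).fit()
    assert res.transform_lambda == 0.0          # data are lognormal
    assert res.var_between == pytest.approx(np.log1p(profile.between_cv ** 2), rel=0.05)
    assert res.var_within == pytest.approx(np.log1p(profile.within_cv ** 2), rel=0.10)


def test_reml_matches_statsmodels_mixedlm(toy_profile, ear_table):
    """Independent-route check of the variance components against MixedLM."""
    sm = pytest.importorskip("statsmodels.api")
    import statsmodels.formula.api as smf

    df = _simulated(toy_profile, ear_table, n=400, seed=3, repeat=1.0)
    res = UsualIntake(df, transform_lambda=0.0).fit()
    long = pd.melt(df, id_vars="child_id",
                   value_vars=["day1_intake", "day2_intake"]).dropna()
    long["y"] = np.log(long["value"])
    mlm = smf.mixedlm("y ~ 1", long, groups=long["child_id"]).fit(reml=True)
    assert res.var_between == pytest.approx(float(mlm.cov_re.iloc[0, 0]), rel=0.02)
    assert res.var_within == pytest.approx(float(mlm.scale), rel=0.02)


def test_identical_repeat_days_give_zero_within_variance(toy_profile, ear_table):
    df = _simulated(toy_profile, ear_table, n=300, seed=5, repeat=1.0)
    df["day2_intake"] = df["day1_intake"]
    res = UsualIntake(df).fit()
    assert res.var_within < 1e-6
    np.testing.assert_allclose(res.person_usual, df["day1_intake"], rtol=1e-3)


def test_scale_equivariance(toy_profile, ear_table):
    """Multiplying intakes by k shifts prevalence exactly like scaling the EAR."""
    df = _simulated(toy_profile, ear_table, n=800, seed=8)
    res = UsualIntake(df, transform_lambda=0.0).fit()
    k = 3.0
    scaled = df.copy()
    scaled[["day1_intake", "day2_intake"]] *= k
    res_k = UsualIntake(scaled, transform_lambda=0.0).fit()
    p = res.prevalence_inadequate(ear_table)
    p_k = res_k.prevalence_inadequate(ear_table.scaled(k))
    assert p_k == pytest.approx(p, abs=1e-12)


def test_shrinkage_reduces_variance(profiles, ear_table):
    df = _simulated(profiles[Region.SOUTH], ear_table, n=2000, seed=17)
    res = UsualIntake(df).fit()
    assert np.var(np.log(res.person_usual)) <= np.var(np.log(df["day1_intake"]))


def test_shift_monotonicity(profiles, ear_table):
    """Adding vitamin A never increases prevalence of inadequacy."""
    df = _simulated(profiles[Region.NORTH], ear_table, n=1000, seed=23)
    res = UsualIntake(df).fit()
    prevs = [res.prevalence_inadequate(ear_table, shift=s)
             for s in (0.0, 10.0, 50.0, 200.0, 10_000.0)]
    assert all(a >= b for a, b in zip(prevs, prevs[1:]))
    assert prevs[-1] == 0.0


def test_degenerate_ear_tables(toy_profile, ear_table):
    df = _simulated(toy_profile, ear_table, n=300, seed=2)
    res = fit_usual_intake(df)
    tiny = EarTable([(6, 59, 1e-9)])
    huge = EarTable([(6, 59, 1e9)])
    assert prevalence_inadequate(res, tiny) == 0.0
    assert prevalence_inadequate(res, huge) == 1.0


def test_missing_ear_bracket_names_the_bracket():
    table = EarTable([(12, 47, 210.0)])
    with pytest.raises(KeyError, match="55"):
        table.lookup(55)


def test_errors_on_unidentifiable_or_too_small_input(toy_profile, ear_table):
    df = _simulated(toy_profile, ear_table, n=300, seed=4)
    no_repeat = df.copy()
    no_repeat["day2_intake"] = np.nan
    with pytest.raises(VarianceIdentificationError):
        UsualIntake(no_repeat)
    with pytest.raises(ValueError, match="at least 30"):
        UsualIntake(df.head(10))
    few_repeat = df.copy()
    keep = few_repeat.index[few_repeat["day2_intake"].notna()][5:]
    few_repeat.loc[keep, "day2_intake"] = np.nan
    with pytest.raises(ValueError, match="at least 10"):
        UsualIntake(few_repeat)


def test_summary_mentions_key_quantities(toy_profile, ear_table):
    df = _simulated(toy_profile, ear_table, n=300, seed=6)
    res = fit_usual_intake(df)
    text = res.summary()
    assert "Box-Cox lambda" in text and "var between" in text
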