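"""Synthetic survey generator: reproducibility, calibration, and structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitaplan.regions import Region, project_child_population
from vitaplan.survey import generate_survey


def test_same_seed_is_bit_identical(toy_profile, ear_table):
    a = generate_survey(toy_profile, 500, 0.3, seed=11, ear_table=ear_table)
    b = generate_survey(toy_profile, 500, 0.3, seed=11, ear_table=ear_table)
    pd.testing.assert_frame_equal(a, b)
    c = generate_survey(toy_profile, 500, 0.3, seed=12, ear_table=ear_table)
    assert not a["day1_intake"].equals(c["day1_intake"])


def test_true_prevalence_matches_calibration_target(profiles, ear_table):
    """NORTH profile, n=2000: generator-known prevalence below the EAR hits
    the printed 73% within the calibration tolerance."""
    df = generate_survey(profiles[Region.NORTH], 2000, 0.3, seed=1,
                         ear_table=ear_table)
    ears = ear_table.for_records(df)
    prev = (df["usual_intake_true"].to_numpy() < ears).mean()
    assert prev == pytest.approx(0.73, abs=0.01)


@pytest.mark.parametrize("target", [0.35, 0.55, 0.73])
def test_prevalence_calibration_across_targets(toy_profile, ear_table, target):
    profile = toy_profile.with_updates(baseline_inadequate_prev=target)
    df = generate_survey(profile, 1500, 0.3, seed=5, ear_table=ear_table)
    ears = ear_table.for_records(df)
    prev = (df["usual_intake_true"].to_numpy() < ears).mean()
    assert prev == pytest.approx(target, abs=0.01)


def test_calibration_monotone_in_target(toy_profile, ear_table):
    """Raising the target prevalence never raises the calibrated median."""
    medians = []
    for target in (0.3, 0.5, 0.7):
        profile = toy_profile.with_updates(baseline_inadequate_prev=target)
        df = generate_survey(profile, 2000, 0.3, seed=9, ear_table=ear_table)
        medians.append(np.median(df["usual_intake_true"]))
    assert medians[0] >= medians[1] >= medians[2]


def test_zero_within_cv_means_day_equals_usual(toy_profile, ear_table):
    profile = toy_profile.with_updates(within_cv=0.0)
    df = generate_survey(profile, 200, 1.0, seed=2, ear_table=ear_table)
    np.testing.assert_allclose(df["day1_intake"], df["usual_intake_true"])
    np.testing.assert_allclose(df["day2_intake"], df["usual_intake_true"])


def test_zero_consumer_fraction_zeroes_amounts(toy_profile, ear_table):
    profile = toy_profile.with_updates(oil_consumer_frac=0.0)
    df = generate_survey(profile, 200, 0.3, seed=3, ear_table=ear_table)
    assert (df["oil_g_day"] == 0).all()


def test_consumer_fractions_within_binomial_bounds(profiles, ear_table):
    n = 20_000
    for region, profile in profiles.items():
        df = generate_survey(profile, n, 0.3, seed=21, ear_table=ear_table)
        for col, frac in [("oil_g_day", profile.oil_consumer_frac),
                          ("bouillon_g_day", profile.bouillon_consumer_frac),
                          ("maize_kcal_day", profile.maize_consumer_frac)]:
            observed = (df[col] > 0).mean()
            half_width = stats.norm.ppf(0.995) * np.sqrt(frac * (1 - frac) / n)
            assert abs(observed - frac) < half_width + 1e-9, (region, col)


def test_repeat_subsample_size(toy_profile, ear_table):
    df = generate_survey(toy_profile, 5000, 0.3, seed=4, ear_table=ear_table)
    frac = df["day2_intake"].notna().mean()
    assert frac == pytest.approx(0.3, abs=0.03)
    assert (df.loc[df["day2_intake"].notna(), "day2_intake"] > 0).all()


def test_input_validation(toy_profile, ear_table):
    with pytest.raises(ValueError):
        generate_survey(toy_profile, 10, 0.3, seed=1, ear_table=ear_table)
    with pytest.raises(ValueError):
        generate_survey(toy_profile, 100, 0.0, seed=1, ear_table=ear_table)


class TestPopulationProjection:
    def test_defaults_reproduce_printed_child_year_totals(self, profiles):
        totals = {Region.NORTH: 12_700, Region.SOUTH: 13_900, Region.CITIES: 5_800}
        national = 0.0
        for region, profile in profiles.items():
            pops = project_child_population(profile, 10)
            assert pops.sum() == pytest.approx(totals[region], rel=0.01)
            national += pops.sum()
        assert national == pytest.approx(32_500, rel=0.01)

    def test_zero_growth_is_constant(self, toy_profile):
        profile = toy_profile.with_updates(pop_growth_rate=0.0)
        assert np.ptp(project_child_population(profile, 5)) == 0.0

    def test_geometric_definition(self, toy_profile):
        profile = toy_profile.with_updates(base_child_population=1000.0,
                                           pop_growth_rate=0.02)
        np.testing.assert_allclose(project_child_population(profile, 2),
                                   [1000.0, 1020.0])

    def test_rejects_nonpositive_years(self, toy_profile):
        with pytest.raises(ValueError):
            project_child_population(toy_profile, 0)
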