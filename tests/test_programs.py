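"""Program dose arithmetic, scenario specs, and the scenario engine."""

import numpy as np
import pandas as pd
import pytest

from vitaplan.programs import (Program, ProgramKind, ScenarioSpec,
                               ScenarioSpecError, added_intake, bau_spec,
                               default_programs, spec_from_years)
from vitaplan.regions import Region


@pytest.fixture(scope="module")
def programs(cfg):
    return default_programs(cfg)


@pytest.fixture()
def record():
    return pd.DataFrame({
        "oil_g_day": [10.0], "bouillon_g_day": [2.0], "maize_kcal_day": [300.0],
        "vas_received": [0],
    })


class TestAddedIntake:
    def test_oil_at_44_percent(self, programs, record, cfg):
        add = added_intake(record, programs["oil44"], 1, cfg)
        assert add[0] == pytest.approx(10 * 12 * 0.44)  # 52.8 ug RAE/day

    def test_bouillon_delivers_nothing_during_startup(self, programs, record, cfg):
        assert added_intake(record, programs["bouillon"], 2, cfg)[0] == 0.0
        assert added_intake(record, programs["bouillon"], 4, cfg)[0] == \
            pytest.approx(2.0 * 80.0)

    def test_maize_content_per_kcal(self, programs, record, cfg):
        assert added_intake(record, programs["maize"], 5, cfg)[0] == \
            pytest.approx(300 * 0.34)

    def test_vas_only_for_recipients(self, programs, record, cfg):
        assert added_intake(record, programs["vas_north"], 1, cfg)[0] == 0.0
        record["vas_received"] = 1
        assert added_intake(record, programs["vas_north"], 1, cfg)[0] == 167.0

    def test_negative_amounts_rejected(self, programs, record, cfg):
        record["oil_g_day"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            added_intake(record, programs["oil44"], 1, cfg)


class TestProgramValidation:
    def test_dose_factors_bounded(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            Program("p", ProgramKind.OIL_44, frozenset(Region), (1.2,) * 10)

    def test_enhanced_oil_must_ramp_to_full(self):
        with pytest.raises(ValueError, match="reach 1.0"):
            Program("p", ProgramKind.OIL_ENHANCED, frozenset(Region),
                    (0.44, 0.72, 0.9) + (0.9,) * 7)
        with pytest.raises(ValueError, match="nondecreasing"):
            Program("p", ProgramKind.OIL_ENHANCED, frozenset(Region),
                    (0.9, 0.72, 1.0) + (1.0,) * 7)


class TestScenarioSpec:
    def test_national_program_needs_all_regions(self, programs):
        spec = ScenarioSpec(frozenset({("bouillon", Region.NORTH, 5)}), programs)
        with pytest.raises(ScenarioSpecError, match="not all regions"):
            spec.validate(10)

    def test_oil_variants_mutually_exclusive(self, programs):
        active = {("oil44", r, 1) for r in Region} | {("oil_enhanced", r, 1) for r in Region}
        with pytest.raises(ScenarioSpecError, match="both active"):
            ScenarioSpec(frozenset(active), programs).validate(10)

    def test_unknown_program_and_scope(self, programs):
        with pytest.raises(ScenarioSpecError, match="unknown program"):
            ScenarioSpec(frozenset({("nope", Region.NORTH, 1)}), programs).validate(10)
        with pytest.raises(ScenarioSpecError, match="not deployable"):
            ScenarioSpec(frozenset({("vas_north", Region.SOUTH, 1)}), programs).validate(10)


class TestScenarioEngine:
    def test_empty_spec_is_identity(self, pipeline, programs):
        spec = ScenarioSpec(frozenset(), programs)
        df = pipeline.engine.run_scenario(spec)
        for region in Region:
            rows = df[df.region == region.value]
            base = pipeline.engine.data[region].baseline_prev
            assert np.allclose(rows["prevalence_inadequate"], base)
            assert (rows["effective_coverage_frac"] == 0).all()
            assert (rows["reach_frac"] == 0).all()

    def test_saturating_dose_covers_whole_baseline(self, pipeline):
        for region in Region:
            rd = pipeline.engine.data[region]
            assert rd._wmean(rd.prob_below(10_000.0)) == pytest.approx(0.0, abs=1e-6)

    def test_combination_superadditivity(self, pipeline):
        """Coverage of a program pair is at least each member's coverage."""
        eng = pipeline.engine
        for region in Region:
            for year in (1, 5, 10):
                both = eng.region_year(region, ["oil_enhanced", "bouillon"], year)
                solo_o = eng.region_year(region, ["oil_enhanced"], year)
                solo_b = eng.region_year(region, ["bouillon"], year)
                assert both["effective_coverage_frac"] >= max(
                    solo_o["effective_coverage_frac"],
                    solo_b["effective_coverage_frac"]) - 1e-9

    def test_fortification_reach_equals_consumer_fraction(self, pipeline):
        eng = pipeline.engine
        for region in Region:
            profile = pipeline.calibrations[region].profile
            out = eng.region_year(region, ["bouillon"], 5)
            se = np.sqrt(profile.bouillon_consumer_frac
                         * (1 - profile.bouillon_consumer_frac) / len(eng.data[region].usual))
            assert out["reach_frac"] == pytest.approx(
                profile.bouillon_consumer_frac, abs=4 * se)

    def test_coverage_cy_scales_linearly_with_population(self, pipeline):
        from vitaplan.programs import ScenarioEngine
        eng = pipeline.engine
        doubled = {r: 2.0 * p for r, p in eng.populations.items()}
        eng2 = ScenarioEngine(eng.data, eng.programs, doubled, eng.cfg)
        a = eng.region_year(Region.SOUTH, ["bouillon"], 6)
        b = eng2.region_year(Region.SOUTH, ["bouillon"], 6)
        assert b["effective_coverage_cy"] == pytest.approx(2 * a["effective_coverage_cy"])

    def test_bau_spec_structure(self, programs):
        spec = bau_spec(programs)
        assert ("oil44", Region.SOUTH, 7) in spec.active
        assert ("vas_cities", Region.CITIES, 10) in spec.active
        assert ("vas_cities", Region.NORTH, 1) not in spec.active

    def test_spec_from_years_validates(self, programs):
        spec = spec_from_years(programs, {"oil_enhanced": range(1, 11),
                                          "vas_north": [1, 2]})
        assert len(spec.active_in(Region.NORTH, 1)) == 2
        assert spec.active_in(Region.SOUTH, 1) == ["oil_enhanced"]
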