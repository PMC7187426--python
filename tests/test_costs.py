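"""Cost model calibration and cost-effectiveness arithmetic."""

import numpy as np
import pytest

from vitaplan.costs import CostModel, UndefinedRatioError, cost_effectiveness
from vitaplan.programs import ScenarioSpec, bau_spec, default_programs, spec_from_years
from vitaplan.regions import Region, population_base, project_child_population

PRINTED_TOTALS = {
    "oil44": 2657, "oil_enhanced": 4851, "bouillon": 2932, "maize": 1398,
    "vas_north": 8766, "vas_south": 12_963, "vas_cities": 5194,
}


@pytest.fixture(scope="module")
def cost_model(cfg):
    programs = default_programs(cfg)
    growth = cfg["populations"]["growth_rate"]
    pops = {}
    for region in Region:
        base = population_base(cfg["populations"]["ten_year_total"][region.value],
                               growth, 10)
        pops[region] = base * (1 + growth) ** np.arange(10)
    return CostModel(cfg, pops, programs)


def test_program_totals_match_printed_cells(cost_model):
    for pid, printed in PRINTED_TOTALS.items():
        assert cost_model.program_horizon_cost(pid) == pytest.approx(printed, rel=0.02)


def test_bau_total_within_band(cost_model, cfg):
    spec = bau_spec(default_programs(cfg))
    total = cost_model.horizon_cost(spec).set_index("region").loc["NATIONAL", "total_cost"]
    assert total == pytest.approx(30_051, rel=0.02)


def test_optimal_activation_total(cost_model, cfg):
    spec = spec_from_years(default_programs(cfg), {
        "oil_enhanced": range(1, 11), "bouillon": range(1, 11), "vas_north": [1, 2],
    })
    total = cost_model.horizon_cost(spec).set_index("region").loc["NATIONAL", "total_cost"]
    assert total == pytest.approx(9537, rel=0.02)


def test_mature_south_fortification_pair(cost_model):
    joint = (cost_model.annual_cost("oil_enhanced", Region.SOUTH, 6)
             + cost_model.annual_cost("bouillon", Region.SOUTH, 6))
    assert joint == pytest.approx(336, abs=2)


def test_mature_south_vas_annual(cost_model):
    assert cost_model.annual_cost("vas_south", Region.SOUTH, 5) == \
        pytest.approx(1300, rel=0.02)


def test_vas_variable_component(cost_model, cfg):
    fixed_only = cost_model.annual_cost("vas_south", Region.SOUTH, 1,
                                        child_population=0.0)
    with_pop = cost_model.annual_cost("vas_south", Region.SOUTH, 1)
    assert 0 < fixed_only < with_pop
    # strictly increasing in population
    costs = [cost_model.annual_cost("vas_south", Region.SOUTH, y) for y in range(1, 11)]
    assert all(a < b for a, b in zip(costs, costs[1:]))


def test_regional_totals_sum_to_national(cost_model, cfg):
    df = cost_model.horizon_cost(bau_spec(default_programs(cfg))).set_index("region")
    regions = df.drop(index="NATIONAL")["total_cost"].sum()
    assert regions == pytest.approx(df.loc["NATIONAL", "total_cost"])


def test_horizon_cost_additivity(cost_model, cfg):
    programs = default_programs(cfg)
    a = spec_from_years(programs, {"bouillon": range(1, 6)})
    b = spec_from_years(programs, {"bouillon": range(6, 11)})
    union = ScenarioSpec(a.active | b.active, programs)
    total = (cost_model.horizon_cost(a).set_index("region").loc["NATIONAL", "total_cost"]
             + cost_model.horizon_cost(b).set_index("region").loc["NATIONAL", "total_cost"])
    assert cost_model.horizon_cost(union).set_index("region").loc["NATIONAL", "total_cost"] \
        == pytest.approx(total)


def test_unknown_program_and_bad_year(cost_model):
    with pytest.raises(KeyError, match="nope"):
        cost_model.annual_cost("nope", Region.NORTH, 1)
    with pytest.raises(ValueError, match="year"):
        cost_model.annual_cost("oil44", Region.NORTH, 11)
    with pytest.raises(KeyError, match="not deployable"):
        cost_model.annual_cost("vas_north", Region.SOUTH, 1)


class TestCostEffectiveness:
    @pytest.mark.parametrize("cost,denom,kind,expected", [
        (2657, 5075, "per_cy", 0.52),        # oil-44, national
        (26_923, 8586, "per_cy", 3.14),      # VAS, national
        (2657, 17_188, "per_child", 0.15),   # oil-44 reach, national
        (2657, 9724, "per_death", 273),      # oil-44 deaths, national
        (30_051, 12_836, "per_cy", 2.34),    # BAU
        (100.0, 100.0, "per_cy", 1.00),      # identity
    ])
    def test_printed_ratios(self, cost, denom, kind, expected):
        assert cost_effectiveness(cost, denom, kind) == expected

    def test_zero_denominator_is_explicit(self):
        with pytest.raises(UndefinedRatioError):
            cost_effectiveness(100.0, 0.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            cost_effectiveness(1.0, 1.0, "per_banana")
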