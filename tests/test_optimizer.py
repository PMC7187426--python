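"""Portfolio optimizer: exactness against brute force, invariants, edge cases."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitaplan.optimizer import FortOption, OptimizationProblem, solve
from vitaplan.regions import Region

REGIONS = (Region.NORTH, Region.SOUTH)


def _random_problem(seed, n_years=3, floor=None, lives_floor=None):
    """A reduced instance: three fortification options, two regions, a few
    VAS year slots with random benefits and costs."""
    rng = np.random.default_rng(seed)
    options = []
    for i, key in enumerate([("none", 0, 0), ("fortA", 0, 0), ("fortB", 0, 0)]):
        pids = () if i == 0 else (key[0],)
        cost = 0.0 if i == 0 else float(rng.uniform(50, 150))
        increments = {}
        for region in REGIONS:
            for year in range(1, n_years + 1):
                if i:
                    increments[(key[0], region, year)] = (float(rng.uniform(5, 30)),
                                                          float(rng.uniform(10, 60)))
        vas_margin = {
            (region, year): (float(rng.uniform(0, 25)), float(rng.uniform(0, 50)))
            for region in REGIONS for year in range(1, n_years + 1)
        }
        options.append(FortOption(
            key=key, program_ids=pids, cost=cost,
            prog_costs={p: cost for p in pids} if pids else {},
            coverage=sum(v[0] for v in increments.values()),
            lives=sum(v[1] for v in increments.values()),
            increments=increments, vas_margin=vas_margin,
        ))
    vas_costs = {(region, year): float(rng.uniform(5, 25))
                 for region in REGIONS for year in range(1, n_years + 1)}
    if floor is None:
        floor = float(rng.uniform(50, 160))
    return OptimizationProblem(floor=floor, options=options, vas_costs=vas_costs,
                               horizon=n_years, lives_floor=lives_floor,
                               bau_key=("fortA", 0, 0))


def _brute_force(problem):
    """Exhaustive enumeration over fortification options x VAS subsets."""
    slots = sorted(problem.vas_costs, key=lambda ry: (ry[0].value, ry[1]))
    best = None
    for opt in problem.options:
        for k in range(len(slots) + 1):
            for chosen in itertools.combinations(slots, k):
                cov = opt.coverage + sum(opt.vas_margin[ry][0] for ry in chosen)
                lives = opt.lives + sum(opt.vas_margin[ry][1] for ry in chosen)
                if cov < problem.floor - 1e-9:
                    continue
                if problem.lives_floor is not None and lives < problem.lives_floor - 1e-9:
                    continue
                cost = opt.cost + sum(problem.vas_costs[ry] for ry in chosen)
                if best is None or cost < best:
                    best = cost
    return best


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("use_lives", [False, True])
def test_agrees_with_brute_force_enumeration(seed, use_lives):
    problem = _random_problem(seed, lives_floor=220.0 if use_lives else None)
    expected = _brute_force(problem)
    result = solve(problem)
    if expected is None:
        assert result.status == "infeasible"
    else:
        assert result.status == "optimal"
        assert result.total_cost == pytest.approx(expected, abs=1e-6)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000),
       floor=st.floats(0.0, 250.0),
       lives_floor=st.one_of(st.none(), st.floats(0.0, 400.0)))
def test_exact_optimum_property(seed, floor, lives_floor):
    """For any reduced instance and floor pair, the solver's cost equals the
    exhaustive-enumeration optimum (or both report infeasibility)."""
    problem = _random_problem(seed, n_years=2, floor=floor, lives_floor=lives_floor)
    expected = _brute_force(problem)
    result = solve(problem)
    if expected is None:
        assert result.status == "infeasible"
    else:
        assert result.total_cost == pytest.approx(expected, abs=1e-6)
        assert result.total_coverage >= problem.floor - 1e-9
        if problem.lives_floor is not None:
            assert result.total_lives >= problem.lives_floor - 1e-9


def test_zero_floor_selects_empty_bundle():
    problem = _random_problem(3, floor=0.0)
    result = solve(problem)
    assert result.status == "optimal"
    assert result.total_cost == 0.0
    assert result.fort_key == ("none", 0, 0)
    assert not result.activations


def test_unreachable_floor_reports_infeasible_with_max_attainable():
    problem = _random_problem(4, floor=1e6)
    result = solve(problem)
    assert result.status == "infeasible"
    max_cov, max_lives = result.max_attainable
    assert 0 < max_cov < 1e6 and max_lives > 0


def test_optimal_cost_monotone_in_floor():
    base = _random_problem(5, floor=0.0)
    costs = []
    for floor in np.linspace(0, solve(base).max_attainable[0] * 0.95, 8):
        problem = _random_problem(5, floor=float(floor))
        costs.append(solve(problem).total_cost)
    assert all(a <= b + 1e-9 for a, b in zip(costs, costs[1:]))


def test_doubling_costs_keeps_the_activation_set():
    problem = _random_problem(6, floor=120.0)
    result = solve(problem)
    doubled_options = [
        FortOption(key=o.key, program_ids=o.program_ids, cost=2 * o.cost,
                   prog_costs={p: 2 * c for p, c in o.prog_costs.items()},
                   coverage=o.coverage, lives=o.lives, increments=o.increments,
                   vas_margin=o.vas_margin)
        for o in problem.options
    ]
    doubled = OptimizationProblem(
        floor=problem.floor, options=doubled_options,
        vas_costs={k: 2 * v for k, v in problem.vas_costs.items()},
        horizon=problem.horizon, lives_floor=problem.lives_floor)
    again = solve(doubled)
    assert again.activations == result.activations
    assert again.total_cost == pytest.approx(2 * result.total_cost)


def test_solution_never_costs_more_than_a_feasible_bau():
    """Whenever the BAU bundle is feasible it is a candidate, so the optimum
    is bounded above by its cost."""
    problem = _random_problem(7, floor=0.0)
    bau = next(o for o in problem.options if o.key == problem.bau_key)
    bau_cov = bau.coverage + sum(m[0] for m in bau.vas_margin.values())
    bau_cost = bau.cost + sum(problem.vas_costs.values())
    problem.floor = bau_cov  # floor set exactly at BAU's outcome
    result = solve(problem)
    assert result.status == "optimal"
    assert result.total_cost <= bau_cost + 1e-6


def test_single_program_universe_forces_full_schedule():
    """With only one VAS stream available and the floor at its total
    coverage, every year must be active and the cost is its horizon cost."""
    n_years = 4
    margins = {(Region.NORTH, y): (10.0, 0.0) for y in range(1, n_years + 1)}
    none = FortOption(key=("none", 0, 0), program_ids=(), cost=0.0, prog_costs={},
                      coverage=0.0, lives=0.0, increments={}, vas_margin=margins)
    vas_costs = {(Region.NORTH, y): 7.0 for y in range(1, n_years + 1)}
    problem = OptimizationProblem(floor=40.0, options=[none], vas_costs=vas_costs,
                                  horizon=n_years)
    result = solve(problem)
    assert result.vas_years[Region.NORTH] == list(range(1, n_years + 1))
    assert result.total_cost == pytest.approx(28.0)


def test_perturbation_truncates_negative_benefits():
    problem = _random_problem(8, floor=10.0)
    ec_mult = {(pid, region): -5.0 for pid in ("fortA", "fortB")
               for region in REGIONS}
    perturbed = problem.with_perturbation(ec_mult, {})
    for opt in perturbed.options:
        assert opt.coverage >= 0.0 and opt.lives >= 0.0
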