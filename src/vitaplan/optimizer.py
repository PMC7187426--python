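"""Minimum-cost program portfolio selection under national benefit floors.

The decision problem mirrors the planning reality: fortification programs
(oil at 44% or enhanced, bouillon, biofortified maize) are national,
sunk-start-up commitments — once the investment starts it is not interrupted
— while VAS can be switched per macroregion and per year.  The solver
enumerates the twelve structural fortification configurations and, for each,
solves a small mixed-integer program choosing the VAS (region, year)
activations that close the remaining benefit gaps at minimum cost (HiGHS via
:func:`scipy.optimize.milp`).  The reported solution is exactly optimal for
this discrete model; ties are broken toward the lexicographically smallest
activation set.

Two floors express "meet at least the business-as-usual outcomes": total
child-years effectively covered, and total child deaths averted.  Both are
constrained by default — the lives floor is what keeps high-dose
supplementation in the North in the early years, when fortification is not
yet delivering, and what excludes biofortified maize (broad but shallow
coverage) from the optimal set.  Pass ``lives_floor=None`` to optimise on
coverage alone.

Combination benefits are tabulated by the dietary model per program subset
(doses add within a child; benefits are *not* additive across programs), so
each fortification configuration carries its own VAS marginal benefit per
region-year.
"""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp


@contextlib.contextmanager
def _quiet_fd1():
    """Silence HiGHS's direct-to-fd-1 incumbent chatter around a solve."""
    try:
        saved = os.dup(1)
    except OSError:  # pragma: no cover - no usable stdout fd
        yield
        return
    try:
        with open(os.devnull, "wb") as devnull:
            os.dup2(devnull.fileno(), 1)
            yield
    finally:
        try:  # flush libc's buffered writes while fd 1 still points at devnull
            import ctypes
            ctypes.CDLL(None).fflush(None)
        except Exception:  # pragma: no cover
            pass
        os.dup2(saved, 1)
        os.close(saved)

from .costs import CostModel
from .programs import Program, ScenarioSpec, spec_from_years
from .regions import Region

__all__ = ["FortOption", "OptimizationProblem", "OptimizationResult",
           "build_problem", "solve"]

_OIL_MODES = ("none", "oil44", "oil_enhanced")
_EPS = 1e-7


@dataclass(frozen=True)
class FortOption:
    """One all-horizon fortification configuration.

    ``increments`` decompose the configuration's benefits per (program,
    region, year) in the fixed stacking order oil, bouillon, maize — each
    value is a (child-years, lives) pair; ``vas_margin`` holds the marginal
    (child-years, lives) of adding that region's VAS on top."""

    key: tuple                        # (oil_mode, bouillon, maize)
    program_ids: tuple                # fortification program ids committed
    cost: float                       # '000s USD over the horizon
    prog_costs: dict = field(hash=False)
    coverage: float = 0.0             # '000s CY over the horizon (no VAS)
    lives: float = 0.0                # deaths averted over the horizon (no VAS)
    increments: dict = field(hash=False, default_factory=dict)
    vas_margin: dict = field(hash=False, default_factory=dict)


@dataclass
class OptimizationProblem:
    floor: float                      # '000s CY national over the horizon
    options: list                     # list[FortOption]
    vas_costs: dict                   # (region, year) -> '000s USD
    horizon: int
    lives_floor: float | None = None  # deaths averted over the horizon
    bau_key: tuple = ("oil44", 0, 0)

    def max_attainable(self) -> tuple:
        cov = max(o.coverage + sum(m[0] for m in o.vas_margin.values() if m[0] > 0)
                  for o in self.options)
        lives = max(o.lives + sum(m[1] for m in o.vas_margin.values() if m[1] > 0)
                    for o in self.options)
        return cov, lives

    def with_perturbation(self, ec_mult: dict, cost_mult: dict) -> "OptimizationProblem":
        """A perturbed copy: benefit increments scaled by per-(program,
        region) multipliers (applied to coverage and lives alike), program
        costs by per-program multipliers.  Negative perturbed increments are
        truncated at zero; the floors are left untouched."""
        new_options = []
        for opt in self.options:
            cov = lives = 0.0
            for (pid, region, year), (inc_cy, inc_lv) in opt.increments.items():
                g = max(ec_mult.get((pid, region), 1.0), 0.0)
                cov += max(inc_cy * g, 0.0)
                lives += max(inc_lv * g, 0.0)
            margins = {}
            for (region, year), (m_cy, m_lv) in opt.vas_margin.items():
                g = max(ec_mult.get((f"vas_{region.value.lower()}", region), 1.0), 0.0)
                margins[(region, year)] = (max(m_cy, 0.0) * g, max(m_lv, 0.0) * g)
            prog_costs = {pid: c * cost_mult.get(pid, 1.0)
                          for pid, c in opt.prog_costs.items()}
            new_options.append(replace(
                opt, cost=sum(prog_costs.values()), prog_costs=prog_costs,
                coverage=cov, lives=lives, vas_margin=margins,
            ))
        vas_costs = {
            (region, year): c * cost_mult.get(f"vas_{region.value.lower()}", 1.0)
            for (region, year), c in self.vas_costs.items()
        }
        return OptimizationProblem(self.floor, new_options, vas_costs, self.horizon,
                                   self.lives_floor, self.bau_key)


@dataclass
class OptimizationResult:
    status: str                       # "optimal" | "infeasible"
    total_cost: float
    total_coverage: float
    total_lives: float
    slack: float                      # coverage above the floor
    lives_slack: float = float("nan")
    fort_key: tuple | None = None
    fort_program_ids: tuple = ()
    vas_years: dict = field(default_factory=dict)   # region -> sorted years
    activations: frozenset = frozenset()
    max_attainable: tuple = (float("nan"), float("nan"))

    def to_spec(self, programs: dict, horizon: int) -> ScenarioSpec:
        years = {pid: range(1, horizon + 1) for pid in self.fort_program_ids}
        for region, ys in self.vas_years.items():
            if ys:
                years[f"vas_{region.value.lower()}"] = ys
        return spec_from_years(programs, years, horizon)

    def summary(self) -> str:
        lines = [f"status: {self.status}",
                 f"total cost ('000s USD): {self.total_cost:,.0f}",
                 f"total coverage ('000s CY): {self.total_coverage:,.0f}",
                 f"total deaths averted: {self.total_lives:,.0f}",
                 f"coverage slack: {self.slack:,.0f}",
                 f"fortification: {', '.join(self.fort_program_ids) or '(none)'}"]
        for region, ys in sorted(self.vas_years.items(), key=lambda kv: kv[0].value):
            if ys:
                lines.append(f"VAS {region.value}: years {ys}")
        return "\n".join(lines)


def build_problem(combo_table: pd.DataFrame, cost_model: CostModel,
                  programs: dict[str, Program], floor: float,
                  horizon: int = 10,
                  lives_floor: float | None = None) -> OptimizationProblem:
    """Assemble the optimization problem from the dietary-model combination
    table (see ``ScenarioEngine.combination_table``) and the cost model.
    Raises if a needed combination row is absent."""
    has_lives = "lives" in combo_table.columns
    if lives_floor is not None and not has_lives:
        raise ValueError("lives_floor set but the combination table has no lives column")
    ec = {}
    for row in combo_table.itertuples(index=False):
        lives = getattr(row, "lives", 0.0) if has_lives else 0.0
        ec[(Region(row.region), row.year, row.oil, row.bouillon, row.maize,
            row.vas)] = (row.ec_cy, lives)

    def lookup(region, year, oil, bou, mz, vas):
        key = (region, year, oil, bou, mz, vas)
        if key not in ec:
            raise KeyError(f"combination outcome missing for {key}")
        return ec[key]

    _oil_pid = {"oil44": "oil44", "oil_enhanced": "oil_enhanced"}
    options = []
    for oil in _OIL_MODES:
        for bou in (0, 1):
            for mz in (0, 1):
                pids = []
                if oil != "none":
                    pids.append(_oil_pid[oil])
                if bou:
                    pids.append("bouillon")
                if mz:
                    pids.append("maize")
                prog_costs = {pid: cost_model.program_horizon_cost(pid) for pid in pids}
                increments, vas_margin = {}, {}
                for region in Region:
                    for year in range(1, horizon + 1):
                        prev = (0.0, 0.0)
                        stack = []
                        if oil != "none":
                            stack.append((_oil_pid[oil], oil, 0, 0))
                        if bou:
                            stack.append(("bouillon", oil, 1, 0))
                        if mz:
                            stack.append(("maize", oil, bou, 1))
                        for pid, o, b, m in stack:
                            cov = lookup(region, year, o, b, m, 0)
                            increments[(pid, region, year)] = (cov[0] - prev[0],
                                                               cov[1] - prev[1])
                            prev = cov
                        with_vas = lookup(region, year, oil, bou, mz, 1)
                        vas_margin[(region, year)] = (with_vas[0] - prev[0],
                                                      with_vas[1] - prev[1])
                options.append(FortOption(
                    key=(oil, bou, mz), program_ids=tuple(pids),
                    cost=sum(prog_costs.values()), prog_costs=prog_costs,
                    coverage=sum(v[0] for v in increments.values()),
                    lives=sum(v[1] for v in increments.values()),
                    increments=increments, vas_margin=vas_margin,
                ))
    vas_costs = {
        (region, year): cost_model.annual_cost(f"vas_{region.value.lower()}", region, year)
        for region in Region for year in range(1, horizon + 1)
    }
    return OptimizationProblem(floor=floor, options=options, vas_costs=vas_costs,
                               horizon=horizon, lives_floor=lives_floor)


def _solve_vas_cover(items: list, gap_cy: float, gap_lives: float):
    """Min-cost subset of (key, (m_cy, m_lives), cost) items with total
    margins meeting both gaps.

    Exact branch-and-bound via HiGHS; returns (cost, chosen keys) or None if
    infeasible.  A tiny index-proportional epsilon on the objective makes the
    optimum unique, hence deterministic."""
    gap_cy = max(gap_cy, 0.0)
    gap_lives = max(gap_lives, 0.0)
    if gap_cy <= 0 and gap_lives <= 0:
        return 0.0, []
    items = [it for it in items if it[1][0] > 1e-9 or it[1][1] > 1e-9]
    if (sum(m[0] for _, m, _ in items) < gap_cy - 1e-9
            or sum(m[1] for _, m, _ in items) < gap_lives - 1e-9):
        return None
    m_cy = np.array([m[0] for _, m, _ in items])
    m_lv = np.array([m[1] for _, m, _ in items])
    costs = np.array([c for _, _, c in items])
    obj = costs + _EPS * np.arange(len(items))
    constraints = [LinearConstraint(m_cy[None, :], lb=gap_cy)]
    if gap_lives > 0:
        constraints.append(LinearConstraint(m_lv[None, :], lb=gap_lives))
    with _quiet_fd1():
        res = milp(c=obj, constraints=constraints,
                   integrality=np.ones(len(items)), bounds=(0, 1))
    if res.status != 0:  # pragma: no cover - guarded by the margin-sum check
        return None
    chosen = [i for i in range(len(items)) if res.x[i] > 0.5]
    true_cost = float(costs[chosen].sum())
    return true_cost, [items[i][0] for i in chosen]


def solve(problem: OptimizationProblem) -> OptimizationResult:
    """Provably optimal activation set for the discrete model."""
    best = None
    use_lives = problem.lives_floor is not None
    for opt in sorted(problem.options, key=lambda o: o.key):
        gap_cy = problem.floor - opt.coverage
        gap_lives = (problem.lives_floor - opt.lives) if use_lives else 0.0
        items = [((region, year), margin, problem.vas_costs[(region, year)])
                 for (region, year), margin in sorted(
                     opt.vas_margin.items(), key=lambda kv: (kv[0][0].value, kv[0][1]))]
        sub = _solve_vas_cover(items, gap_cy, gap_lives)
        if sub is None:
            continue
        vas_cost, chosen = sub
        total_cost = opt.cost + vas_cost
        coverage = opt.coverage + sum(m[0] for ry, m, _ in items if ry in chosen)
        lives = opt.lives + sum(m[1] for ry, m, _ in items if ry in chosen)
        acts = set()
        for pid in opt.program_ids:
            for region in Region:
                for year in range(1, problem.horizon + 1):
                    acts.add((pid, region, year))
        for region, year in chosen:
            acts.add((f"vas_{region.value.lower()}", region, year))
        cand = (total_cost, tuple(sorted((p, r.value, y) for p, r, y in acts)),
                opt, chosen, coverage, lives, frozenset(acts))
        if best is None or cand[0] < best[0] - 1e-6 or (
                abs(cand[0] - best[0]) <= 1e-6 and cand[1] < best[1]):
            best = cand
    if best is None:
        mc, ml = problem.max_attainable()
        return OptimizationResult(status="infeasible", total_cost=float("nan"),
                                  total_coverage=mc, total_lives=ml,
                                  slack=float("nan"),
                                  max_attainable=problem.max_attainable())
    total_cost, _, opt, chosen, coverage, lives, acts = best
    vas_years = {region: sorted(y for r, y in chosen if r == region) for region in Region}
    return OptimizationResult(
        status="optimal", total_cost=total_cost, total_coverage=coverage,
        total_lives=lives, slack=coverage - problem.floor,
        lives_slack=(lives - problem.lives_floor) if use_lives else float("nan"),
        fort_key=opt.key, fort_program_ids=opt.program_ids, vas_years=vas_years,
        activations=acts, max_attainable=problem.max_attainable(),
    )
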