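"""Monte Carlo robustness analysis of the portfolio optimization.

Each replicate perturbs every program's effective-coverage stream (one
multiplicative normal draw per program x region, truncated at zero,
applied to both child-years and deaths averted) and every program's cost
stream (one uniform multiplicative draw in [1-b, 1+b] per program), then
re-solves the optimization.  The benefit floors stay at their
business-as-usual point values.  Inclusion frequencies follow the
convention that VAS counts as included in a replicate only if it is active
for at least ``vas_min_years`` of the horizon; fortification programs count
if selected at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optimizer import OptimizationProblem, solve
from .regions import Region

__all__ = ["MonteCarloSummary", "run_monte_carlo"]

_FORT_PIDS = ("oil44", "oil_enhanced", "bouillon", "maize")


@dataclass
class MonteCarloSummary:
    n_sims: int
    seed: int
    ec_cv: float
    cost_band: float
    vas_inclusion_min_years: int
    inclusion_freq: dict                 # program label -> percent of replicates
    totals: dict                         # metric -> (point, p2.5, p97.5)
    n_infeasible: int
    point: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"program": k, "inclusion_pct": v}
                for k, v in self.inclusion_freq.items()]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_sims": self.n_sims, "seed": self.seed, "ec_cv": self.ec_cv,
            "cost_band": self.cost_band,
            "vas_inclusion_min_years": self.vas_inclusion_min_years,
            "inclusion_freq": self.inclusion_freq,
            "totals": {k: list(v) for k, v in self.totals.items()},
            "n_infeasible": self.n_infeasible,
            "point": self.point,
        }

    def summary(self) -> str:
        lines = [f"Monte Carlo: {self.n_sims} replicates "
                 f"(EC CV {self.ec_cv:.0%}, cost band +/-{self.cost_band:.0%}), "
                 f"{self.n_infeasible} infeasible",
                 "program inclusion (% of replicates):"]
        for k, v in self.inclusion_freq.items():
            lines.append(f"  {k:28s} {v:6.1f}")
        for k, (pt, lo, hi) in self.totals.items():
            lines.append(f"{k}: {pt:,.2f} ({lo:,.2f} - {hi:,.2f})")
        return "\n".join(lines)


def _vas_label(region: Region) -> str:
    return f"vas_{region.value.lower()}"


def run_monte_carlo(problem: OptimizationProblem, ec_cv: float = 0.05,
                    cost_band: float = 0.20, n_sims: int = 1000, seed: int = 0,
                    vas_min_years: int = 3,
                    cost_common_share: float = 1.0,
                    ec_correlation: str = "region",
                    floor_mode: str = "bau") -> MonteCarloSummary:
    """Re-solve the optimization under benefit and cost uncertainty.

    ``cost_common_share`` splits the +/-``cost_band`` draw into a costing-
    level factor shared by all programs (the budgets derive from one costing
    exercise and one CFA/USD exchange rate) and a program-specific residual;
    1.0 means fully systematic, 0.0 fully independent across programs.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not 0.0 <= cost_common_share <= 1.0:
        raise ValueError("cost_common_share must lie in [0, 1]")
    if ec_correlation not in ("region", "family", "program"):
        raise ValueError(f"unknown ec_correlation {ec_correlation!r}")
    if floor_mode not in ("bau", "fixed"):
        raise ValueError(f"unknown floor_mode {floor_mode!r}")
    rng = np.random.default_rng(seed)

    point = solve(problem)
    labels = list(_FORT_PIDS) + [_vas_label(r) for r in Region]
    counts = {k: 0 for k in labels}
    costs, coverages, cost_per_cy = [], [], []
    n_infeasible = 0

    # EC draw granularity: all programs' coverage estimates in a region come
    # from the same survey and the same fitted intake distribution, so their
    # errors co-move; by default one draw per region perturbs every program's
    # stream there.  "family" draws per program family (the two oil variants
    # always share, their uncertainty stems from the same consumption data);
    # "program" draws fully independently.
    families = ["oil", "bouillon", "maize"] + [_vas_label(r) for r in Region]
    fam_of = {"oil44": "oil", "oil_enhanced": "oil", "bouillon": "bouillon",
              "maize": "maize", **{_vas_label(r): _vas_label(r) for r in Region}}
    gamma = cost_common_share
    for _ in range(n_sims):
        if ec_correlation == "region":
            reg_mult = {region: max(rng.normal(1.0, ec_cv), 0.0) for region in Region}
            ec_mult = {(pid, region): reg_mult[region]
                       for pid in labels for region in Region}
        elif ec_correlation == "family":
            fam_mult = {(fam, region): max(rng.normal(1.0, ec_cv), 0.0)
                        for fam in families for region in Region}
            ec_mult = {(pid, region): fam_mult[(fam_of[pid], region)]
                       for pid in labels for region in Region}
        else:  # "program"
            ec_mult = {(pid, region): max(rng.normal(1.0, ec_cv), 0.0)
                       for pid in labels for region in Region}
        common = rng.uniform(-cost_band, cost_band)
        cost_mult = {pid: 1.0 + gamma * common
                     + (1.0 - gamma) * rng.uniform(-cost_band, cost_band)
                     for pid in labels}
        perturbed = problem.with_perturbation(ec_mult, cost_mult)
        if floor_mode == "bau":
            # the floors are the BAU bundle's own outcomes, which share the
            # perturbed coverage estimates (same survey, same dietary model)
            bau = next(o for o in perturbed.options if o.key == perturbed.bau_key)
            perturbed.floor = bau.coverage + sum(
                m[0] for m in bau.vas_margin.values())
            if perturbed.lives_floor is not None:
                perturbed.lives_floor = bau.lives + sum(
                    m[1] for m in bau.vas_margin.values())
        res = solve(perturbed)
        if res.status != "optimal":
            n_infeasible += 1
            continue
        chosen_fort = set(res.fort_program_ids)
        for pid in _FORT_PIDS:
            counts[pid] += pid in chosen_fort
        for region in Region:
            counts[_vas_label(region)] += len(res.vas_years.get(region, [])) >= vas_min_years
        costs.append(res.total_cost)
        coverages.append(res.total_coverage)
        cost_per_cy.append(res.total_cost / res.total_coverage)

    n_ok = n_sims - n_infeasible
    freq = {k: 100.0 * v / n_ok if n_ok else float("nan") for k, v in counts.items()}

    def interval(vals, pt):
        return (pt, float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))

    totals = {}
    if n_ok:
        totals = {
            "total_cost": interval(costs, point.total_cost),
            "total_coverage_cy": interval(coverages, point.total_coverage),
            "cost_per_cy": interval(cost_per_cy,
                                    point.total_cost / point.total_coverage),
        }
    return MonteCarloSummary(
        n_sims=n_sims, seed=seed, ec_cv=ec_cv, cost_band=cost_band,
        vas_inclusion_min_years=vas_min_years, inclusion_freq=freq,
        totals=totals, n_infeasible=n_infeasible,
        point={"total_cost": point.total_cost,
               "total_coverage_cy": point.total_coverage,
               "vas_years": {r.value: point.vas_years.get(r, []) for r in Region},
               "fort_programs": list(point.fort_program_ids)},
    )
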