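"""Program cost model: annual and 10-year costs, and cost-effectiveness ratios.

All monetary amounts are '000s of 2013 USD (500 CFA = 1 USD was the exchange
rate of the underlying budgets; no discounting is applied).  Fortification
programs carry national annual cost streams — start-up-era and mature-year
levels differ — apportioned to macroregions by fixed shares calibrated to
the printed regional program totals.  VAS is costed per region as a fixed
annual component plus a per-child component scaling with the child
population (the one cost element that varies over time); 90% of the Child
Health Days overhead is attributed to VAS, embedded in the calibrated
totals.  Validation studies are costed per study per region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .programs import Program, ProgramKind, ScenarioSpec
from .regions import Region

__all__ = ["CostModel", "cost_effectiveness", "UndefinedRatioError"]


class UndefinedRatioError(ZeroDivisionError):
    """Cost-effectiveness ratio with a zero denominator."""


class CostModel:
    """Annual program costs per (program, region, year).

    Parameters
    ----------
    cfg : merged configuration (see ``data/defaults.yaml`` for the cost block)
    populations : region -> array of annual child populations ('000s),
        needed for the per-child component of VAS costs.
    programs : program registry (ids -> Program), to map ids to cost kinds.
    """

    def __init__(self, cfg: dict, populations: dict[Region, np.ndarray],
                 programs: dict[str, Program]):
        self.cfg = cfg
        self.populations = populations
        self.programs = programs
        self.horizon = cfg["horizon_years"]

        cc = cfg["costs"]
        self._fort = {
            kind: (np.asarray(block["annual"], float),
                   {Region(r): s for r, s in block["region_share"].items()})
            for kind, block in cc["fortification"].items()
        }
        vas = cc["vas"]
        self._vas_fixed, self._vas_per_child = {}, {}
        for region in Region:
            total = float(vas["ten_year_total"][region.value])
            pop = populations[region][: self.horizon]
            self._vas_fixed[region] = vas["fixed_share"] * total / self.horizon
            self._vas_per_child[region] = (1.0 - vas["fixed_share"]) * total / pop.sum()
        self._validation = {Region(r): float(v)
                            for r, v in cc["validation_study"].items()}

    # -- per-cell costs --------------------------------------------------

    def annual_cost(self, program_id: str, region: Region, year: int,
                    child_population: float | None = None) -> float:
        """Cost ('000s USD) of one program in one region in one year."""
        if program_id not in self.programs:
            raise KeyError(f"unknown program id {program_id!r}")
        if not 1 <= year <= self.horizon:
            raise ValueError(f"year {year} outside 1..{self.horizon}")
        region = Region(region)
        prog = self.programs[program_id]
        if prog.kind is ProgramKind.VAS:
            if region not in prog.scope:
                raise KeyError(f"{program_id} is not deployable in {region}")
            pop = (self.populations[region][year - 1]
                   if child_population is None else child_population)
            return self._vas_fixed[region] + self._vas_per_child[region] * pop
        annual, shares = self._fort[prog.kind.value]
        return float(annual[year - 1]) * shares[region]

    def validation_cost(self, region: Region) -> float:
        return self._validation[Region(region)]

    # -- aggregates ------------------------------------------------------

    def horizon_cost(self, spec: ScenarioSpec) -> pd.DataFrame:
        """Total cost per region plus the national total over the horizon."""
        spec.validate(self.horizon)
        totals = {region: 0.0 for region in Region}
        for pid, region, year in spec.active:
            totals[Region(region)] += self.annual_cost(pid, region, year)
        rows = [{"region": r.value, "total_cost": c} for r, c in totals.items()]
        rows.append({"region": "NATIONAL", "total_cost": sum(totals.values())})
        return pd.DataFrame(rows)

    def program_horizon_cost(self, program_id: str, region: Region | None = None) -> float:
        """10-year cost of one program, in one region or over its whole scope."""
        prog = self.programs[program_id]
        regions = [Region(region)] if region is not None else sorted(prog.scope)
        return sum(self.annual_cost(program_id, r, y)
                   for r in regions for y in range(1, self.horizon + 1))


def cost_effectiveness(total_cost: float, denom: float, kind: str = "per_cy") -> float:
    """Cost-effectiveness ratio on the conventional reporting scale.

    ``total_cost`` is in '000s USD.  ``kind``:

    * ``per_cy`` — denom in '000s child-years effectively covered; USD/CY,
      rounded to cents;
    * ``per_child`` — denom in '000s children reached; USD/child, cents;
    * ``per_death`` — denom in deaths averted (count); USD, whole dollars.
    """
    if denom == 0:
        raise UndefinedRatioError(f"cost-effectiveness denominator is zero ({kind})")
    if kind in ("per_cy", "per_child"):
        return round(total_cost / denom, 2)
    if kind == "per_death":
        return round(total_cost * 1000.0 / denom)
    raise ValueError(f"unknown ratio kind {kind!r}")
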