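"""GAVA-constrained policy pathways per macroregion.

A pathway starts from business as usual and builds out the efficient
fortification pair — enhanced oil (44-72-100% of target over three years) and
bouillon (benefits from year 4) — while retaining VAS until the GAVA
criteria for withdrawal are met:

1. the prevalence of inadequate *dietary* intake (fortification only; VAS is
   not diet) falls below the threshold (default 2.5%), which triggers a
   biomarker validation study that year;
2. in two-study mode, a second study follows in a nonconsecutive year
   (trigger year + 2); in one-study mode the single study suffices;
3. VAS is withdrawn the year after the final confirming study, i.e. at most
   three years after the trigger in two-study mode.

Regions that never cross the threshold retain VAS for the whole horizon and
are charged a single validation study (default year 4) documenting that
withdrawal conditions are not met.  Validation studies are assumed to
confirm the dietary prediction; a hook allows injecting a failed validation,
which resets the machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .costs import CostModel
from .mortality import MortalityProfile
from .programs import ScenarioEngine
from .regions import Region

__all__ = ["GavaPhase", "GavaState", "PathwayResult", "run_pathway", "compare_scenarios"]

FORT_PROGRAMS = ("oil_enhanced", "bouillon")


class GavaPhase(str, Enum):
    VAS_ON = "VAS_ON"
    TRIGGERED = "TRIGGERED"
    VALIDATION_DONE_1 = "VALIDATION_DONE_1"
    VALIDATION_DONE_2 = "VALIDATION_DONE_2"
    VAS_OFF = "VAS_OFF"


@dataclass
class GavaState:
    phase: GavaPhase = GavaPhase.VAS_ON
    trigger_year: int | None = None
    validation_years: list = field(default_factory=list)


@dataclass
class PathwayResult:
    region: Region
    mode: str                       # "one_study" | "two_study"
    table: pd.DataFrame             # one row per year
    state: GavaState
    vas_off_year: int | None       # first year without VAS, if any

    @property
    def total_cost(self) -> float:
        return float(self.table[["cost_fortification", "cost_vas",
                                 "cost_validation"]].sum().sum())


def run_pathway(region: Region, engine: ScenarioEngine, cost_model: CostModel,
                mortality_profile: MortalityProfile, mode: str = "two_study",
                threshold: float = 0.025, second_study_gap: int = 2,
                default_validation_year: int = 4,
                validation_outcomes: dict | None = None) -> PathwayResult:
    """Simulate one macroregion's year-by-year pathway.

    ``validation_outcomes`` maps year -> bool; a False result (failed
    biomarker confirmation) resets the withdrawal machinery to VAS_ON.
    """
    if mode not in ("one_study", "two_study"):
        raise ValueError(f"mode must be one_study or two_study, got {mode!r}")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    outcomes = validation_outcomes or {}
    horizon = engine.horizon
    vas_id = f"vas_{region.value.lower()}"
    rd = engine.data[region]
    state = GavaState()
    scheduled: list[int] = []
    vas_on = True
    vas_off_year = None
    rows = []

    for year in range(1, horizon + 1):
        fort_active = list(FORT_PROGRAMS)
        active = fort_active + ([vas_id] if vas_on else [])

        # dietary adequacy is judged on fortification alone: VAS is the
        # program whose withdrawal is being decided, and it is not diet
        prev_diet = engine.prevalence(region, fort_active, year)
        prev_all = engine.prevalence(region, active, year)

        if state.trigger_year is None and prev_diet < threshold:
            state.trigger_year = year
            state.phase = GavaPhase.TRIGGERED
            scheduled = [year]
            if mode == "two_study":
                second = year + second_study_gap
                if second <= horizon:
                    scheduled.append(second)

        validation_cost = 0.0
        if year in scheduled:
            validation_cost = cost_model.validation_cost(region)
            confirmed = outcomes.get(year, True)
            if not confirmed:
                state = GavaState()         # failed validation: start over
                scheduled = []
            else:
                state.validation_years.append(year)
                done = len(state.validation_years)
                state.phase = (GavaPhase.VALIDATION_DONE_1 if done == 1
                               else GavaPhase.VALIDATION_DONE_2)
                required = 1 if mode == "one_study" else 2
                if done >= required and vas_on:
                    vas_off_year = year + 1   # withdrawn from next year

        out = engine.region_year(region, active, year)
        fort_out = engine.region_year(region, fort_active, year)
        lives_total = mortality_profile.deaths_averted(
            out["effective_coverage_frac"], year, rd.baseline_prev)
        lives_fort = mortality_profile.deaths_averted(
            fort_out["effective_coverage_frac"], year, rd.baseline_prev)
        cost_fort = sum(cost_model.annual_cost(pid, region, year) for pid in fort_active)
        cost_vas = cost_model.annual_cost(vas_id, region, year) if vas_on else 0.0
        rows.append({
            "year": year, "region": region.value,
            "oil_enhanced": 1, "bouillon": 1, "vas": int(vas_on),
            "prevalence_inadequate": prev_diet,
            "prevalence_with_vas": prev_all,
            "effective_coverage_frac": out["effective_coverage_frac"],
            "lives_saved_fortification": lives_fort,
            "lives_saved_total": lives_total,
            "cost_fortification": cost_fort,
            "cost_vas": cost_vas,
            "cost_validation": validation_cost,
        })

        if vas_off_year is not None and year + 1 >= vas_off_year:
            if vas_on:
                state.phase = GavaPhase.VAS_OFF
            vas_on = False

    # a region that never crossed the threshold still pays one study
    # documenting that withdrawal conditions are not met
    if state.trigger_year is None and default_validation_year <= horizon:
        idx = default_validation_year - 1
        rows[idx]["cost_validation"] = cost_model.validation_cost(region)
        state.validation_years.append(default_validation_year)

    return PathwayResult(region=region, mode=mode, table=pd.DataFrame(rows),
                        state=state, vas_off_year=vas_off_year)


def compare_scenarios(regions, engine: ScenarioEngine, cost_model: CostModel,
                      mortality_profiles: dict,
                      modes=("one_study", "two_study"), **kwargs) -> pd.DataFrame:
    """Ten-year cost comparison: BAU vs the pathway under each mode.

    Returns one row per region plus a NATIONAL row with columns
    ``bau_cost``, ``one_study_cost``, ``two_study_cost`` ('000s USD) and the
    incremental cost of the two-study over the one-study pathway."""
    horizon = engine.horizon
    rows = []
    for region in regions:
        vas_id = f"vas_{region.value.lower()}"
        bau = sum(cost_model.annual_cost("oil44", region, y)
                  + cost_model.annual_cost(vas_id, region, y)
                  for y in range(1, horizon + 1))
        row = {"region": region.value, "bau_cost": bau}
        for mode in modes:
            res = run_pathway(region, engine, cost_model,
                              mortality_profiles[region], mode=mode, **kwargs)
            row[f"{mode}_cost"] = res.total_cost
        if {"one_study", "two_study"} <= set(modes):
            row["two_minus_one"] = row["two_study_cost"] - row["one_study_cost"]
        rows.append(row)
    df = pd.DataFrame(rows)
    total = df.drop(columns="region").sum()
    total["region"] = "NATIONAL"
    return pd.concat([df, total.to_frame().T], ignore_index=True)
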