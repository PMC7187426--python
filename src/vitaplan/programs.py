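"""Intervention programs and the scenario engine.

Five program kinds add vitamin A to children's intake:

* ``OIL_44`` — the existing edible-oil fortification program, delivering 44%
  of the 12 mg/kg target level throughout;
* ``OIL_ENHANCED`` — the strengthened oil program ramping 44% - 72% - 100% of
  target over three years;
* ``BOUILLON`` — bouillon-cube fortification at 80 mg/kg, with a 3-year
  start-up during which costs accrue but no nutrient is delivered;
* ``MAIZE_BIOFORT`` — biofortified maize at 0.34 ug RAE/kcal after a 3-year
  phase-in;
* ``VAS`` — semiannual high-dose supplementation via Child Health Days,
  entered as a constant 167 ug RAE/day equivalent for reached children.

A scenario activates programs per (region, year).  The engine adds each
active program's contribution to every child's usual intake and re-evaluates
prevalence of inadequacy under the fitted usual-intake machinery, yielding
reach, effective coverage (baseline prevalence minus scenario prevalence,
floored at zero), child-years covered, deaths averted, and cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .intake import EarTable, UsualIntakeResults
from .regions import Region

__all__ = [
    "ProgramKind", "Program", "ScenarioSpec", "ScenarioSpecError",
    "default_programs", "added_intake", "RegionData", "ScenarioEngine",
    "bau_spec", "spec_from_years",
]

FORTIFICATION_KINDS = frozenset({"OIL_44", "OIL_ENHANCED", "BOUILLON", "MAIZE_BIOFORT"})


class ProgramKind(str, Enum):
    OIL_44 = "OIL_44"
    OIL_ENHANCED = "OIL_ENHANCED"
    BOUILLON = "BOUILLON"
    MAIZE_BIOFORT = "MAIZE_BIOFORT"
    VAS = "VAS"


@dataclass(frozen=True)
class Program:
    """One intervention program with a dose-factor schedule over the horizon."""

    id: str
    kind: ProgramKind
    scope: frozenset
    content_schedule: tuple

    def __post_init__(self):
        sched = self.content_schedule
        if any(not 0.0 <= f <= 1.0 for f in sched):
            raise ValueError(f"{self.id}: dose factors must lie in [0, 1]")
        if self.kind in (ProgramKind.BOUILLON, ProgramKind.MAIZE_BIOFORT):
            if self.startup_years and any(f != 0.0 for f in sched[: self.startup_years]):
                raise ValueError(f"{self.id}: start-up years must carry zero benefit")
        if self.kind is ProgramKind.OIL_ENHANCED:
            if any(b < a for a, b in zip(sched, sched[1:])):
                raise ValueError(f"{self.id}: enhanced-oil schedule must be nondecreasing")
            if len(sched) >= 3 and sched[2] < 1.0:
                raise ValueError(f"{self.id}: enhanced-oil schedule must reach 1.0 by year 3")

    @property
    def startup_years(self) -> int:
        n = 0
        for f in self.content_schedule:
            if f != 0.0:
                break
            n += 1
        return n

    def factor(self, year: int) -> float:
        if not 1 <= year <= len(self.content_schedule):
            raise ValueError(f"year {year} outside program schedule")
        return self.content_schedule[year - 1]

    @property
    def national(self) -> bool:
        return self.kind.value in FORTIFICATION_KINDS


def default_programs(cfg: dict) -> dict[str, Program]:
    """The candidate program universe: national fortification programs plus
    one macroregion-deployable VAS program per region."""
    sched = cfg["programs"]["schedules"]
    all_regions = frozenset(Region)
    programs = {
        "oil44": Program("oil44", ProgramKind.OIL_44, all_regions, tuple(sched["OIL_44"])),
        "oil_enhanced": Program("oil_enhanced", ProgramKind.OIL_ENHANCED, all_regions,
                                tuple(sched["OIL_ENHANCED"])),
        "bouillon": Program("bouillon", ProgramKind.BOUILLON, all_regions,
                            tuple(sched["BOUILLON"])),
        "maize": Program("maize", ProgramKind.MAIZE_BIOFORT, all_regions,
                         tuple(sched["MAIZE_BIOFORT"])),
    }
    for region in Region:
        pid = f"vas_{region.value.lower()}"
        programs[pid] = Program(pid, ProgramKind.VAS, frozenset({region}),
                                tuple(sched["VAS"]))
    return programs


class ScenarioSpecError(ValueError):
    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid scenario specification:\n- " + "\n- ".join(self.violations))


@dataclass(frozen=True)
class ScenarioSpec:
    """Set of (program_id, region, year) activations plus the program registry."""

    active: frozenset
    programs: dict = field(hash=False, compare=False, default_factory=dict)

    def validate(self, horizon: int | None = None) -> None:
        violations = []
        by_py: dict[tuple, set] = {}
        for pid, region, year in self.active:
            prog = self.programs.get(pid)
            if prog is None:
                violations.append(f"unknown program id {pid!r}")
                continue
            if region not in prog.scope:
                violations.append(f"{pid} not deployable in {region}")
            if horizon is not None and not 1 <= year <= horizon:
                violations.append(f"{pid}: year {year} outside 1..{horizon}")
            by_py.setdefault((pid, year), set()).add(region)
        for (pid, year), regions in sorted(by_py.items()):
            prog = self.programs.get(pid)
            if prog is not None and prog.national and regions != set(Region):
                violations.append(
                    f"national program {pid} active in {sorted(r.value for r in regions)} "
                    f"but not all regions in year {year}"
                )
        years_oil44 = {y for p, _, y in self.active if p == "oil44"}
        years_enh = {y for p, _, y in self.active if p == "oil_enhanced"}
        for year in sorted(years_oil44 & years_enh):
            violations.append(f"oil44 and oil_enhanced both active in year {year}")
        if violations:
            raise ScenarioSpecError(violations)

    def active_in(self, region: Region, year: int) -> list:
        return sorted(pid for pid, r, y in self.active if r == region and y == year)


def spec_from_years(programs: dict, years_by_program: dict, horizon: int = 10) -> ScenarioSpec:
    """Build a spec from {program_id: iterable of years}; national programs
    are expanded to all regions, VAS to its own scope."""
    active = set()
    for pid, years in years_by_program.items():
        prog = programs[pid]
        for year in years:
            for region in prog.scope:
                active.add((pid, region, year))
    spec = ScenarioSpec(frozenset(active), programs)
    spec.validate(horizon)
    return spec


def bau_spec(programs: dict, horizon: int = 10) -> ScenarioSpec:
    """Business as usual: 44%-target fortified oil plus VAS everywhere, all years."""
    years = range(1, horizon + 1)
    return spec_from_years(programs, {
        "oil44": years,
        "vas_north": years, "vas_south": years, "vas_cities": years,
    }, horizon)


def added_intake(record, program: Program, year: int, cfg: dict) -> np.ndarray:
    """Additional ug RAE/day a program delivers to a child (or children) in a
    given year.  ``record`` is a survey dataframe or row."""
    df = record if isinstance(record, pd.DataFrame) else pd.DataFrame([record])
    f = program.factor(year)
    kind = program.kind
    if kind in (ProgramKind.OIL_44, ProgramKind.OIL_ENHANCED):
        amounts = df["oil_g_day"].to_numpy(float)
        per_unit = cfg["programs"]["oil_target_ug_per_g"]
    elif kind is ProgramKind.BOUILLON:
        amounts = df["bouillon_g_day"].to_numpy(float)
        per_unit = cfg["programs"]["bouillon_ug_per_g"]
    elif kind is ProgramKind.MAIZE_BIOFORT:
        amounts = df["maize_kcal_day"].to_numpy(float)
        per_unit = cfg["programs"]["maize_ug_per_kcal"]
    else:  # VAS
        out = df["vas_received"].to_numpy(float) * cfg["programs"]["vas_daily_equiv"]
        return out if isinstance(record, pd.DataFrame) else out[0]
    if (amounts < 0).any():
        raise ValueError(f"negative vehicle amounts for {program.id}")
    out = amounts * per_unit * f
    return out if isinstance(record, pd.DataFrame) else out[0]


@dataclass
class RegionData:
    """Per-child arrays the scenario engine needs for one region.

    Two prevalence modes coexist: with only point usual intakes, a child
    counts as inadequate when ``usual + additions < EAR``; when the fitted
    model's conditional (posterior) distributions are attached
    (``cond_mean``/``cond_sd`` on the Box-Cox scale), each child contributes
    the posterior probability of falling short instead.  The posterior mode
    removes the tail compression that point predictions inherit from
    shrinkage, so scenario coverage streams track the generating truth.
    """

    region: Region
    usual: np.ndarray            # usual intake, ug RAE/day
    oil_full: np.ndarray         # oil dose at 100% of target, ug/day
    bouillon_full: np.ndarray
    maize_full: np.ndarray
    vas_dose: np.ndarray         # 167 * received
    ears: np.ndarray
    weights: np.ndarray
    cond_mean: np.ndarray | None = None
    cond_sd: np.ndarray | None = None
    transform_lambda: float = 0.0
    baseline_prev: float = 0.0

    def __post_init__(self):
        if self.baseline_prev == 0.0:
            self.baseline_prev = self._wmean(self.prob_below())

    def _wmean(self, x) -> float:
        return float((self.weights * x).sum() / self.weights.sum())

    def prob_below(self, additions: np.ndarray | float = 0.0) -> np.ndarray:
        """Per-child probability (or indicator) of usual intake plus program
        additions falling below the EAR."""
        if self.cond_mean is None:
            return ((self.usual + additions) < self.ears).astype(float)
        from scipy.special import ndtr
        c = self.ears - additions
        out = np.zeros(len(self.ears))
        pos = c > 0
        lam = self.transform_lambda
        g = np.log(c[pos]) if lam == 0.0 else (np.power(c[pos], lam) - 1.0) / lam
        m, s = self.cond_mean[pos], self.cond_sd[pos]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(s > 0, ndtr((g - m) / np.where(s > 0, s, 1.0)),
                         (g > m).astype(float))
        out[pos] = p
        return out

    @classmethod
    def from_records(cls, region: Region, records: pd.DataFrame, usual: np.ndarray,
                     ear_table: EarTable, cfg: dict, **extra) -> "RegionData":
        pr = cfg["programs"]
        return cls(
            region=region,
            usual=np.asarray(usual, float),
            oil_full=records["oil_g_day"].to_numpy(float) * pr["oil_target_ug_per_g"],
            bouillon_full=records["bouillon_g_day"].to_numpy(float) * pr["bouillon_ug_per_g"],
            maize_full=records["maize_kcal_day"].to_numpy(float) * pr["maize_ug_per_kcal"],
            vas_dose=records["vas_received"].to_numpy(float) * pr["vas_daily_equiv"],
            ears=ear_table.for_records(records),
            weights=records["weight"].to_numpy(float) if "weight" in records
                    else np.ones(len(records)),
            **extra,
        )

    @classmethod
    def from_fit(cls, region: Region, records: pd.DataFrame, fit: UsualIntakeResults,
                 ear_table: EarTable, cfg: dict) -> "RegionData":
        """Scenario state from the fitted usual-intake model (the standard route)."""
        mode = cfg.get("intake", {}).get("prevalence_mode", "posterior")
        extra = {}
        if mode == "posterior":
            extra = {"cond_mean": fit.person_blups, "cond_sd": fit.person_cond_sd,
                     "transform_lambda": fit.transform_lambda}
        return cls.from_records(region, records, fit.person_usual, ear_table, cfg, **extra)


class ScenarioEngine:
    """Evaluates program scenarios on fitted per-child usual intakes.

    Scenario re-estimation shifts each child's usual intake by the active
    programs' deterministic contributions and recomputes prevalence, reusing
    the baseline fit's variance components (the shift approach keeps scenario
    prevalence monotone in the delivered dose, which the pathway logic
    relies on).
    """

    def __init__(self, data: dict[Region, RegionData], programs: dict[str, Program],
                 populations: dict[Region, np.ndarray], cfg: dict):
        self.data = data
        self.programs = programs
        self.populations = populations
        self.cfg = cfg
        self.horizon = cfg["horizon_years"]

    # -- core ------------------------------------------------------------

    def additions(self, region: Region, program_ids, year: int) -> np.ndarray:
        rd = self.data[region]
        add = np.zeros_like(rd.usual)
        for pid in program_ids:
            prog = self.programs[pid]
            if region not in prog.scope:
                continue
            f = prog.factor(year)
            if f == 0.0:
                continue
            kind = prog.kind
            if kind in (ProgramKind.OIL_44, ProgramKind.OIL_ENHANCED):
                add = add + f * rd.oil_full
            elif kind is ProgramKind.BOUILLON:
                add = add + f * rd.bouillon_full
            elif kind is ProgramKind.MAIZE_BIOFORT:
                add = add + f * rd.maize_full
            else:
                add = add + rd.vas_dose
        return add

    def prevalence(self, region: Region, program_ids, year: int) -> float:
        rd = self.data[region]
        add = self.additions(region, program_ids, year)
        return rd._wmean(rd.prob_below(add))

    def region_year(self, region: Region, program_ids, year: int) -> dict:
        rd = self.data[region]
        add = self.additions(region, program_ids, year)
        prev = rd._wmean(rd.prob_below(add))
        ec_frac = max(rd.baseline_prev - prev, 0.0)
        pop = self.populations[region][year - 1]
        return {
            "region": region.value,
            "year": year,
            "prevalence_inadequate": prev,
            "reach_frac": rd._wmean(add > 0),
            "effective_coverage_frac": ec_frac,
            "effective_coverage_cy": ec_frac * pop,
        }

    # -- public API ------------------------------------------------------

    def run_scenario(self, spec: ScenarioSpec, cost_model=None,
                     mortality_profiles=None) -> pd.DataFrame:
        """Tidy per-(region, year) scenario outcome table."""
        spec.validate(self.horizon)
        rows = []
        for region in Region:
            rd = self.data[region]
            for year in range(1, self.horizon + 1):
                pids = spec.active_in(region, year)
                row = self.region_year(region, pids, year)
                if mortality_profiles is not None:
                    prof = mortality_profiles[region]
                    row["deaths_averted"] = prof.deaths_averted(
                        row["effective_coverage_frac"], year, rd.baseline_prev)
                if cost_model is not None:
                    row["cost"] = sum(
                        cost_model.annual_cost(pid, region, year) for pid in pids)
                rows.append(row)
        return pd.DataFrame(rows)

    def combination_table(self, mortality_profiles=None) -> pd.DataFrame:
        """Effective coverage (and deaths averted) of every program
        combination per (region, year).

        Columns: region, year, oil ('none'|'oil44'|'oil_enhanced'),
        bouillon, maize, vas (0/1), ec_frac, ec_cy, and lives when mortality
        profiles are supplied.  Combination coverage is computed through the
        dietary model (doses add per child), never assumed additive across
        programs.
        """
        rows = []
        for region in Region:
            vas_id = f"vas_{region.value.lower()}"
            rd = self.data[region]
            prof = None if mortality_profiles is None else mortality_profiles[region]
            for year in range(1, self.horizon + 1):
                for oil in ("none", "oil44", "oil_enhanced"):
                    for bou in (0, 1):
                        for mz in (0, 1):
                            for vas in (0, 1):
                                pids = []
                                if oil != "none":
                                    pids.append(oil)
                                if bou:
                                    pids.append("bouillon")
                                if mz:
                                    pids.append("maize")
                                if vas:
                                    pids.append(vas_id)
                                out = self.region_year(region, pids, year)
                                row = {
                                    "region": region.value, "year": year,
                                    "oil": oil, "bouillon": bou, "maize": mz, "vas": vas,
                                    "ec_frac": out["effective_coverage_frac"],
                                    "ec_cy": out["effective_coverage_cy"],
                                }
                                if prof is not None:
                                    row["lives"] = prof.deaths_averted(
                                        out["effective_coverage_frac"], year,
                                        rd.baseline_prev)
                                rows.append(row)
        return pd.DataFrame(rows)
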