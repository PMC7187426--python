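"""Macroregions, regional survey profiles, and child population projections.

The analysis stratifies Cameroon into three macroregions: NORTH (Extreme
North, North, Adamawa), SOUTH (the remaining regions except the two largest
cities), and CITIES (Yaounde and Douala).  A :class:`RegionProfile` carries
everything the synthetic survey generator needs for one macroregion: the
usual-intake distribution, within-person variability, fortification-vehicle
consumption patterns, VAS reach, and the child population trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = ["Region", "RegionProfile", "project_child_population", "population_base"]


class Region(str, Enum):
    NORTH = "NORTH"
    SOUTH = "SOUTH"
    CITIES = "CITIES"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


REGIONS = (Region.NORTH, Region.SOUTH, Region.CITIES)


@dataclass(frozen=True)
class RegionProfile:
    """Calibrated generating parameters for one macroregion's child population.

    Medians are in ug RAE/day (intake) or natural vehicle units (g/day for oil
    and bouillon, kcal/day for maize); dispersions are coefficients of
    variation; populations are '000s of children 6-59 months.
    """

    region: Region
    baseline_inadequate_prev: float
    intake_median: float
    between_cv: float
    within_cv: float
    oil_consumer_frac: float
    oil_g_day_dist: tuple[float, float]          # (median, cv) among consumers
    bouillon_consumer_frac: float
    bouillon_g_day_dist: tuple[float, float]
    maize_consumer_frac: float
    maize_kcal_day_dist: tuple[float, float]
    vas_reach: float
    base_child_population: float                 # '000s, year 1
    pop_growth_rate: float = 0.015
    vehicle_intake_correlation: float = 0.0      # amount copula (all vehicles)
    selection_corr: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amount_corr: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amount_max: tuple[float, float, float] = (float("inf"), float("inf"), float("inf"))
    # physiological ceilings on (oil g/d, bouillon g/d, maize kcal/d) amounts
    vas_intake_corr: float = 0.0
    # Gaussian-copula correlation between VAS receipt propensity and usual
    # intake (negative = supplements reach low-intake children more often).
    maize_nested_in_bouillon: bool = False
    # maize consumers drawn as a random subset of bouillon consumers (both
    # indicate access to market foods)
    bouillon_mix: tuple[float, float] = (1.0, 0.1)
    # (substantial-use share among consumers, token-class amount ratio):
    # bouillon amounts are a two-class mixture separating households that
    # season daily dishes with bouillon from occasional token users
    # Gaussian-copula correlations with usual intake for (oil, bouillon,
    # maize): ``selection_corr`` couples the consumption propensity (negative
    # = consumers concentrate among low-intake children), ``amount_corr``
    # couples the log amount among consumers.

    def __post_init__(self) -> None:
        fracs = {
            "baseline_inadequate_prev": self.baseline_inadequate_prev,
            "oil_consumer_frac": self.oil_consumer_frac,
            "bouillon_consumer_frac": self.bouillon_consumer_frac,
            "maize_consumer_frac": self.maize_consumer_frac,
            "vas_reach": self.vas_reach,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {val}")
        if self.intake_median <= 0 or self.between_cv <= 0:
            raise ValueError("intake_median and between_cv must be positive")
        if self.within_cv < 0:
            raise ValueError("within_cv must be nonnegative")
        if self.base_child_population <= 0:
            raise ValueError("base_child_population must be positive")
        for name in ("oil_g_day_dist", "bouillon_g_day_dist", "maize_kcal_day_dist"):
            med, cv = getattr(self, name)
            if med < 0 or cv <= 0:
                raise ValueError(f"{name} must have nonnegative median and positive cv")

    def with_updates(self, **kwargs) -> "RegionProfile":
        return replace(self, **kwargs)


def population_base(ten_year_total: float, growth_rate: float, years: int = 10) -> float:
    """Year-1 population ('000s) whose geometric trajectory sums to a given total."""
    factor = sum((1.0 + growth_rate) ** t for t in range(years))
    return ten_year_total / factor


def project_child_population(profile: RegionProfile, years: int) -> np.ndarray:
    """Geometric child-population projection, '000s per year, years 1..``years``."""
    if years < 1:
        raise ValueError("years must be >= 1")
    t = np.arange(years)
    return profile.base_child_population * (1.0 + profile.pop_growth_rate) ** t
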