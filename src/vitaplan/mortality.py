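"""Linkage from effective coverage to vitamin-A-preventable child deaths.

The source analysis runs effective-coverage estimates through the Lives Saved
Tool with VAS coverage rolled back to zero, so that a region-year carries an
envelope of VA-preventable deaths and program packages avert a share of it.
That machinery is condensed here into the envelope itself (year-1 value
growing with the child population) and a monotone effectiveness map ``g``:

    deaths_averted(year) = envelope(year) * g(EC_frac / baseline_prev)

where ``EC_frac / baseline_prev`` expresses effective coverage as the share
of the resolvable burden.  The default ``g`` is the identity (proportional
scaling), which makes deaths averted hit the envelope exactly when a program
set resolves the whole dietary deficit, and never exceed it otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .regions import Region

__all__ = ["MortalityProfile", "mortality_profiles"]

_EFFECTIVENESS_MAPS = {
    "proportional": lambda x: x,
}


@dataclass(frozen=True)
class MortalityProfile:
    """Envelope of VA-preventable child deaths for one macroregion."""

    region: Region
    va_preventable_deaths: float      # deaths/year in year 1
    growth_rate: float = 0.015
    effectiveness_map: str = "proportional"

    def __post_init__(self):
        if self.va_preventable_deaths < 0:
            raise ValueError("va_preventable_deaths must be nonnegative")
        if self.effectiveness_map not in _EFFECTIVENESS_MAPS:
            raise ValueError(f"unknown effectiveness map {self.effectiveness_map!r}")

    def envelope(self, year: int) -> float:
        return self.va_preventable_deaths * (1.0 + self.growth_rate) ** (year - 1)

    def deaths_averted(self, effective_coverage_frac: float, year: int,
                       baseline_prev: float) -> float:
        """Deaths averted in one year at a given effective-coverage fraction.

        ``baseline_prev`` normalises coverage to the resolvable burden; the
        result is capped by the envelope (the largest number of lives any
        program combination can save).
        """
        if not 0.0 <= effective_coverage_frac <= 1.0:
            raise ValueError(
                f"effective coverage must lie in [0, 1]; got {effective_coverage_frac}")
        if baseline_prev <= 0.0:
            return 0.0
        g = _EFFECTIVENESS_MAPS[self.effectiveness_map]
        share = min(effective_coverage_frac / baseline_prev, 1.0)
        return self.envelope(year) * g(share)


def mortality_profiles(cfg: dict) -> dict[Region, MortalityProfile]:
    mc = cfg["mortality"]
    return {
        region: MortalityProfile(
            region=region,
            va_preventable_deaths=mc["va_preventable_deaths_y1"][region.value],
            growth_rate=mc["growth_rate"],
            effectiveness_map=mc.get("effectiveness_map", "proportional"),
        )
        for region in Region
    }
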