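"""End-to-end assembly of the analysis pipeline.

``Pipeline.from_config(cfg, seed)`` runs the stages lazily and caches them:

1. calibrate regional generating distributions to the printed anchors;
2. generate one synthetic survey per macroregion;
3. fit the usual-intake measurement-error model per region;
4. build the scenario engine on the fitted per-child usual intakes;
5. expose the cost model, mortality profiles, and the optimizer problem.

Every random stage derives its own stream from the single run seed, so a
(config, seed) pair reproduces all outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import RegionCalibration, calibrate_all
from .config import config_hash, default_config
from .costs import CostModel
from .intake import EarTable, UsualIntake, UsualIntakeResults
from .mortality import MortalityProfile, mortality_profiles
from .optimizer import OptimizationProblem, build_problem
from .programs import Program, RegionData, ScenarioEngine, default_programs
from .regions import Region, project_child_population

__all__ = ["Pipeline"]


@dataclass
class Pipeline:
    cfg: dict
    seed: int
    n_children: int | None = None
    _cals: dict | None = field(default=None, repr=False)
    _surveys: dict | None = field(default=None, repr=False)
    _fits: dict | None = field(default=None, repr=False)
    _engine: ScenarioEngine | None = field(default=None, repr=False)
    _cost_model: CostModel | None = field(default=None, repr=False)
    _problem: OptimizationProblem | None = field(default=None, repr=False)

    @classmethod
    def from_config(cls, cfg: dict | None = None, seed: int = 1,
                    n_children: int | None = None) -> "Pipeline":
        return cls(cfg=cfg or default_config(), seed=seed, n_children=n_children)

    # -- shared ingredients ----------------------------------------------

    @property
    def ear_table(self) -> EarTable:
        return EarTable.from_config(self.cfg)

    @property
    def programs(self) -> dict[str, Program]:
        return default_programs(self.cfg)

    @property
    def populations(self) -> dict[Region, np.ndarray]:
        cals = self.calibrations
        return {r: project_child_population(cals[r].profile, self.cfg["horizon_years"])
                for r in Region}

    @property
    def calibrations(self) -> dict[Region, RegionCalibration]:
        if self._cals is None:
            self._cals = calibrate_all(self.cfg)
        return self._cals

    # -- staged artefacts ------------------------------------------------

    @property
    def surveys(self) -> dict[Region, pd.DataFrame]:
        if self._surveys is None:
            from .survey import generate_survey
            n = self.n_children or self.cfg["survey"]["n_children"]
            repeat = self.cfg["intake"]["repeat_frac"]
            self._surveys = {}
            for i, region in enumerate(Region):
                # independent but reproducible stream per region
                seed = (self.seed * 1000003 + i * 7919) % (2 ** 31)
                self._surveys[region] = generate_survey(
                    self.calibrations[region].profile, n, repeat, seed, self.ear_table)
        return self._surveys

    @property
    def fits(self) -> dict[Region, UsualIntakeResults]:
        if self._fits is None:
            self._fits = {r: UsualIntake(df).fit() for r, df in self.surveys.items()}
        return self._fits

    @property
    def engine(self) -> ScenarioEngine:
        if self._engine is None:
            data = {
                r: RegionData.from_fit(r, self.surveys[r], self.fits[r],
                                       self.ear_table, self.cfg)
                for r in Region
            }
            self._engine = ScenarioEngine(data, self.programs, self.populations, self.cfg)
        return self._engine

    @property
    def cost_model(self) -> CostModel:
        if self._cost_model is None:
            self._cost_model = CostModel(self.cfg, self.populations, self.programs)
        return self._cost_model

    @property
    def mortality(self) -> dict[Region, MortalityProfile]:
        return mortality_profiles(self.cfg)

    def bau_outcomes(self) -> dict:
        """The model's own BAU (oil-44 + VAS everywhere) totals: coverage
        ('000s CY), deaths averted, and cost ('000s USD) over the horizon."""
        from .programs import bau_spec
        spec = bau_spec(self.programs, self.cfg["horizon_years"])
        df = self.engine.run_scenario(spec, cost_model=self.cost_model,
                                      mortality_profiles=self.mortality)
        return {
            "coverage_cy": float(df["effective_coverage_cy"].sum()),
            "lives": float(df["deaths_averted"].sum()),
            "cost": float(df["cost"].sum()),
        }

    def problem(self, floor: float | None = None,
                lives_floor: float | str | None = "bau") -> OptimizationProblem:
        """The portfolio optimization problem.

        ``floor`` defaults to the configured BAU coverage; ``lives_floor``
        defaults to the model's own BAU deaths averted ("bau"), may be a
        number, or None to constrain coverage only."""
        if floor is None:
            floor = self.cfg["optimizer"]["coverage_floor"]
        if lives_floor == "bau":
            lives_floor = self.bau_outcomes()["lives"]
        if (self._problem is None or self._problem.floor != floor
                or self._problem.lives_floor != lives_floor):
            table = self.engine.combination_table(self.mortality)
            self._problem = build_problem(table, self.cost_model, self.programs,
                                          floor, self.cfg["horizon_years"],
                                          lives_floor=lives_floor)
        return self._problem

    def manifest(self) -> dict:
        from importlib.metadata import version
        try:
            pkg_version = version("vitaplan")
        except Exception:  # pragma: no cover
            pkg_version = "unknown"
        return {
            "config_hash": config_hash(self.cfg),
            "seed": self.seed,
            "n_children": self.n_children or self.cfg["survey"]["n_children"],
            "package_version": pkg_version,
        }
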