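"""Named, reproducible analysis configurations.

Each scenario bundles engine settings (horizon, starting age, start-state
distribution, discount rate), the replication count, an optional coupling
applied to the sampled draws, and — for the trial-horizon run — calibration
of the baseline-hazard multiplier to the published usual-care life years.

Bundled scenarios
-----------------
trial_1y              1-year horizon, age 68, all patients starting GOLD II,
                      mortality calibrated so usual-care life years = 0.97
trial_1y_mixed_start  as above but with the trial's mixed GOLD II/III/IV
                      baseline distribution (documented exploratory variant)
base_case_30y         30-year horizon from age 60 (life-table fixture)
horizon_5 / horizon_10  5- and 10-year horizons from age 60
horizon_20            20-year horizon from age 68
discount_5pct         base case with a 5%/year discount rate
double_treatment_cost base case with every intervention cost item doubled
idm_utility_floor     base case where each intervention-arm utility draw is
                      floored at the paired usual-care draw
equal_utility         base case with intervention utilities set equal to the
                      usual-care draws (cost-only comparison; CEAC read at 0)
reps_10000            base case at 10,000 replications
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cea import CEAResult, compute_cea
from .engine import EngineSettings
from .mortality import LifeTable, calibrate_multiplier
from .params import STATES, ParameterTable, load_parameters
from .psa import PSASample, run_psa

__all__ = ["ScenarioSpec", "ScenarioResult", "SCENARIOS", "run_scenario"]

TRIAL_UC_LIFE_YEARS = 0.97  # published usual-care life years over the trial year

# GOLD II/III/IV baseline split implied by the trial cell sizes (UC arm)
MIXED_START_UC = (44 / 73, 22 / 73, 7 / 73)


def _double_intervention(draw: dict) -> dict:
    out = dict(draw)
    for k in draw:
        if k.startswith("intervention."):
            out[k] = draw[k] * 2.0
    return out


def _utility_floor(draw: dict) -> dict:
    out = dict(draw)
    for s in STATES:
        out[f"IDM.{s}.utility"] = np.maximum(
            draw[f"IDM.{s}.utility"], draw[f"UC.{s}.utility"]
        )
    return out


def _equal_utility(draw: dict) -> dict:
    out = dict(draw)
    for s in STATES:
        out[f"IDM.{s}.utility"] = draw[f"UC.{s}.utility"]
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    horizon: int
    start_age: int
    start_state_dist: tuple = (1.0, 0.0, 0.0)
    discount_rate: float = 0.015
    n_reps: int = 5000
    calibrate_life_years: float | None = None
    draw_transform: object = None
    ceac_focus_wtp: float = 50000.0

    def settings(self, discount_override=None) -> EngineSettings:
        return EngineSettings(
            horizon=self.horizon,
            start_age=self.start_age,
            start_state_dist=self.start_state_dist,
            discount_rate=(
                self.discount_rate if discount_override is None else discount_override
            ),
        )


SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in (
        ScenarioSpec("trial_1y", horizon=1, start_age=68,
                     calibrate_life_years=TRIAL_UC_LIFE_YEARS),
        ScenarioSpec("trial_1y_mixed_start", horizon=1, start_age=68,
                     start_state_dist=MIXED_START_UC,
                     calibrate_life_years=TRIAL_UC_LIFE_YEARS),
        ScenarioSpec("base_case_30y", horizon=30, start_age=60),
        ScenarioSpec("horizon_5", horizon=5, start_age=60),
        ScenarioSpec("horizon_10", horizon=10, start_age=60),
        ScenarioSpec("horizon_20", horizon=20, start_age=68),
        ScenarioSpec("discount_5pct", horizon=30, start_age=60,
                     discount_rate=0.05),
        ScenarioSpec("double_treatment_cost", horizon=30, start_age=60,
                     draw_transform=_double_intervention),
        ScenarioSpec("idm_utility_floor", horizon=30, start_age=60,
                     draw_transform=_utility_floor),
        ScenarioSpec("equal_utility", horizon=30, start_age=60,
                     draw_transform=_equal_utility, ceac_focus_wtp=0.0),
        ScenarioSpec("reps_10000", horizon=30, start_age=60, n_reps=10000),
    )
}


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    sample: PSASample
    cea: CEAResult
    multiplier: float


def run_scenario(name_or_spec, table: ParameterTable | None = None,
                 n_reps: int | None = None, seed: int = 0,
                 life_table: LifeTable | None = None,
                 wtp: float | None = None) -> ScenarioResult:
    """Run a bundled (or custom) scenario end-to-end: PSA then CEA."""
    if isinstance(name_or_spec, ScenarioSpec):
        spec = name_or_spec
    else:
        if name_or_spec not in SCENARIOS:
            raise KeyError(
                f"unknown scenario {name_or_spec!r}; available: "
                + ", ".join(sorted(SCENARIOS))
            )
        spec = SCENARIOS[name_or_spec]

    if table is None:
        table = load_parameters()
    if life_table is None:
        life_table = LifeTable.default()
    settings = spec.settings()

    multiplier = 1.0
    if spec.calibrate_life_years is not None:
        multiplier = calibrate_multiplier(
            table, settings, life_table, spec.calibrate_life_years
        )

    sample = run_psa(
        table, settings,
        n_reps=n_reps if n_reps is not None else spec.n_reps,
        seed=seed, life_table=life_table, multiplier=multiplier,
        draw_transform=spec.draw_transform,
    )
    sample.meta["scenario"] = spec.name
    cea = compute_cea(sample, wtp=wtp if wtp is not None else table.wtp)
    return ScenarioResult(spec=spec, sample=sample, cea=cea,
                          multiplier=multiplier)
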