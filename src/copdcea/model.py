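"""Top-level modelling interface.

:class:`CostUtilityModel` wraps a parameter table plus a scenario (engine
settings, calibration, couplings); :meth:`CostUtilityModel.fit` runs the
probabilistic sensitivity analysis and returns a
:class:`CostUtilityResults` carrying the incremental estimates, their
Monte-Carlo uncertainty, the acceptability curve and value-of-information
statistics, with a ``summary()`` table.

>>> model = CostUtilityModel(scenario="trial_1y")
>>> res = model.fit(n_reps=5000, seed=1)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cea as _cea
from .mortality import LifeTable
from .params import ParameterTable, load_parameters
from .scenarios import SCENARIOS, ScenarioSpec, run_scenario

__all__ = ["CostUtilityModel", "CostUtilityResults"]


class CostUtilityModel:
    """Markov cohort cost-utility model of intervention vs usual care.

    Parameters
    ----------
    table : ParameterTable, optional
        Model inputs; defaults to the bundled configuration.
    scenario : str or ScenarioSpec
        Analysis configuration (see :mod:`copdcea.scenarios`).
    life_table : LifeTable, optional
        All-cause mortality; defaults to the bundled synthetic fixture.
    """

    def __init__(self, table: ParameterTable | None = None,
                 scenario="trial_1y", life_table: LifeTable | None = None):
        self.table = table if table is not None else load_parameters()
        if isinstance(scenario, str):
            if scenario not in SCENARIOS:
                raise KeyError(
                    f"unknown scenario {scenario!r}; available: "
                    + ", ".join(sorted(SCENARIOS))
                )
            scenario = SCENARIOS[scenario]
        self.scenario: ScenarioSpec = scenario
        self.life_table = life_table if life_table is not None else LifeTable.default()

    @classmethod
    def from_config(cls, config, scenario="trial_1y", life_table=None):
        """Build from a JSON configuration file path or mapping."""
        return cls(load_parameters(config), scenario=scenario,
                   life_table=life_table)

    def fit(self, n_reps: int | None = None, seed: int = 0,
            wtp: float | None = None) -> "CostUtilityResults":
        """Run the PSA and cost-effectiveness analysis."""
        res = run_scenario(self.scenario, table=self.table, n_reps=n_reps,
                           seed=seed, life_table=self.life_table, wtp=wtp)
        return CostUtilityResults(self, res)


class CostUtilityResults:
    """PSA-based estimates and decision statistics for one fitted scenario."""

    def __init__(self, model: CostUtilityModel, scenario_result):
        self.model = model
        self._res = scenario_result
        self.sample = scenario_result.sample
        self.cea = scenario_result.cea
        self.multiplier = scenario_result.multiplier

    # -- point estimates ---------------------------------------------------
    @property
    def incremental_cost(self) -> float:
        return self.cea.dcost_mean

    @property
    def incremental_qalys(self) -> float:
        return self.cea.dqaly_mean

    @property
    def incremental_life_years(self) -> float:
        return self.cea.summary["dly"]["mean"]

    @property
    def icer_(self):
        return self.cea.icer_label

    @property
    def net_benefit_(self) -> float:
        return self.cea.net_benefit

    def ceac_frame(self) -> pd.DataFrame:
        return self.cea.ceac

    def ceac_at(self, wtp: float) -> float:
        return _cea.ceac_at(self.sample, wtp)

    def evpi(self, wtp: float | None = None) -> float:
        return _cea.evpi(self.sample, wtp if wtp is not None else self.cea.wtp)

    def evppi(self, subset_or_group, wtp: float | None = None,
              flexible: bool = False) -> float:
        wtp = wtp if wtp is not None else self.cea.wtp
        groups = _cea.parameter_groups(self.sample)
        if isinstance(subset_or_group, str):
            subset = groups[subset_or_group]
        else:
            subset = subset_or_group
        return _cea.evppi_metamodel(self.sample, subset, wtp,
                                    flexible=flexible).value

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Readable summary of arm-level and incremental results."""
        from statsmodels.iolib.table import SimpleTable

        s = self.cea.summary
        spec = self._res.spec

        def fmt(col, money=False, dp=3):
            m = s[col]
            if money:
                return (f"{m['mean']:,.0f}",
                        f"({m['se_ci'][0]:,.0f}, {m['se_ci'][1]:,.0f})")
            return (f"{m['mean']:.{dp}f}",
                    f"({m['se_ci'][0]:.{dp}f}, {m['se_ci'][1]:.{dp}f})")

        rows = [
            ("Cost UC ($)", *fmt("cost_UC", money=True)),
            ("Cost IDM ($)", *fmt("cost_IDM", money=True)),
            ("QALYs UC", *fmt("qaly_UC")),
            ("QALYs IDM", *fmt("qaly_IDM")),
            ("Life years UC", *fmt("ly_UC")),
            ("Life years IDM", *fmt("ly_IDM")),
            ("Incr. cost ($)", *fmt("dcost", money=True)),
            ("Incr. QALYs", *fmt("dqaly")),
            ("Incr. life years", *fmt("dly")),
        ]
        icer = self.icer_
        icer_txt = icer if isinstance(icer, str) else f"{icer:,.0f}"
        extra = [
            ("ICER/ICUR", icer_txt, ""),
            (f"Net benefit @ ${self.cea.wtp:,.0f}",
             f"{self.net_benefit_:,.0f}", ""),
            (f"P(cost-effective) @ ${self.cea.wtp:,.0f}",
             f"{self.ceac_at(self.cea.wtp):.4f}", ""),
            (f"EVPI/patient @ ${self.cea.wtp:,.0f}",
             f"{self.cea.evpi:,.0f}", ""),
        ]
        title = (
            f"Cost-utility analysis — scenario {spec.name} "
            f"(horizon {spec.horizon} y, start age {spec.start_age}, "
            f"N={self.sample.n_reps}, seed={self.sample.meta['seed']})"
        )
        table = SimpleTable(
            [list(r) for r in rows + extra],
            headers=["", "mean", "95% CI (MC mean)"],
            title=title,
        )
        return table.as_text()

    # -- plots -------------------------------------------------------------
    def plot_ce_plane(self, ax=None, wtp: float | None = None):
        """Incremental cost vs incremental QALYs, one point per replication."""
        import matplotlib.pyplot as plt

        wtp = wtp if wtp is not None else self.cea.wtp
        plane = _cea.ce_plane(self.sample, wtp)
        if ax is None:
            _, ax = plt.subplots()
        pts = plane.points
        ax.scatter(pts["dqaly"], pts["dcost"], s=4, alpha=0.3)
        qgrid = np.linspace(pts["dqaly"].min(), pts["dqaly"].max(), 2)
        ax.plot(qgrid, qgrid * wtp, "k--", lw=1,
                label=f"WTP ${wtp:,.0f}/QALY")
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (CAD)")
        ax.legend()
        return ax

    def plot_ceac(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.cea.ceac
        ax.plot(c["wtp"], c["probability"])
        ax.set_ylim(0, 1)
        ax.set_xlabel("Willingness to pay (CAD/QALY)")
        ax.set_ylabel("P(intervention cost-effective)")
        return ax

    def plot_evpi(self, ax=None, wtp_grid=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = _cea.evpi_curve(self.sample, wtp_grid)
        ax.plot(curve["wtp"], curve["evpi"])
        ax.set_xlabel("Willingness to pay (CAD/QALY)")
        ax.set_ylabel("EVPI per patient (CAD)")
        return ax
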