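"""Annual-cycle Markov cohort engine.

States are GOLD II, III, IV plus absorbing death.  Within each one-year
cycle, in order:

1. disease progression (GII→GIII, GIII→GIV; identical in both arms),
2. death, at the blended age/state probability where hospitalisation
   exposure h = P(exacerbation) × P(hospitalisation | exacerbation) for the
   arm,
3. end-of-cycle survivors accrue one life year, the state/arm utility, and
   the expected annual service cost (intervention arm additionally accrues
   the annual programme cost); decedents accrue nothing.

Cycle t's accruals are discounted by (1 + r)^-(t-1): the first cycle is
undiscounted and no half-cycle correction is applied.  The engine is an
expectation over the cohort (no first-order microsimulation); parameter
values may be scalars or vectors of Monte-Carlo replications, in which case
all accruals are computed replication-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import LifeTable, death_prob
from .params import STATES, UNIT_COST_KEYS, INTERVENTION_ITEMS

__all__ = [
    "EngineSettings",
    "CohortTrace",
    "ArmResult",
    "discount_factor",
    "annual_service_cost",
    "cycle_update",
    "run_cohort",
]

SERVICES = ("urgent", "er", "hosp")


@dataclass(frozen=True)
class EngineSettings:
    """Run configuration for one arm of the cohort model."""

    horizon: int
    start_age: int
    start_state_dist: tuple = (1.0, 0.0, 0.0)  # over (GII, GIII, GIV)
    discount_rate: float = 0.015
    arm: str = "UC"

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if abs(sum(self.start_state_dist) - 1.0) > 1e-12:
            raise ValueError("start_state_dist must sum to 1")
        if self.arm not in ("UC", "IDM"):
            raise ValueError(f"unknown arm {self.arm!r}")


@dataclass
class CohortTrace:
    """Per-cycle expectations; arrays have shape (horizon,) or (horizon, n)."""

    cycles: np.ndarray
    occupancy: np.ndarray        # (horizon, 4[, n]) over (GII, GIII, GIV, dead)
    exac_fraction: np.ndarray
    visits: dict                 # service -> expected visits per person
    cost: np.ndarray
    cost_discounted: np.ndarray
    utility: np.ndarray
    utility_discounted: np.ndarray
    life_years: np.ndarray
    life_years_discounted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (scalar runs only), one row per cycle."""
        if self.cost.ndim != 1:
            raise ValueError("trace export requires a scalar (single-draw) run")
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "occ_GII": self.occupancy[:, 0],
                "occ_GIII": self.occupancy[:, 1],
                "occ_GIV": self.occupancy[:, 2],
                "occ_dead": self.occupancy[:, 3],
                "exac_fraction": self.exac_fraction,
                "visits_urgent": self.visits["urgent"],
                "visits_er": self.visits["er"],
                "visits_hosp": self.visits["hosp"],
                "cost": self.cost,
                "cost_discounted": self.cost_discounted,
                "utility": self.utility,
                "utility_discounted": self.utility_discounted,
                "life_years": self.life_years,
                "life_years_discounted": self.life_years_discounted,
            }
        )


@dataclass
class ArmResult:
    """Discounted totals for one arm under one parameter draw."""

    cost: np.ndarray | float
    qalys: np.ndarray | float
    life_years: np.ndarray | float
    trace: CohortTrace | None = None


def discount_factor(t: int, rate: float) -> float:
    """(1 + rate)^-(t-1) for 1-indexed cycle t; the first cycle is undiscounted."""
    if t < 1:
        raise ValueError("cycles are 1-indexed")
    return (1.0 + rate) ** (-(t - 1))


def _unit_cost(draw, service):
    return sum(draw[f"cost.{service}.{c}"] for c in UNIT_COST_KEYS[service])


def _intervention_total(draw):
    return sum(draw[f"intervention.{k}"] for k in INTERVENTION_ITEMS)


def annual_service_cost(arm: str, state: str, draw: dict):
    """Expected annual cost per alive person in ``state`` for ``arm``.

    P(exacerbation) × Σ_service P(service | exac) × mean visits × unit cost;
    the intervention arm adds the fixed annual programme total per person.
    """
    p_exac = draw[f"{arm}.{state}.p_exacerbation"]
    total = 0.0
    for svc in SERVICES:
        total = total + (
            draw[f"{arm}.{state}.p_{svc}"]
            * draw[f"{arm}.{state}.n_{svc}"]
            * _unit_cost(draw, svc)
        )
    cost = p_exac * total
    if arm == "IDM":
        cost = cost + _intervention_total(draw)
    return cost


def _hr(draw, state):
    return draw["hr.GII"] if state == "GII" else draw["hr.GIII_GIV"]


def cycle_update(occupancy, dead, age, arm, draw, life_table: LifeTable,
                 multiplier: float = 1.0):
    """Advance the cohort one cycle.

    ``occupancy`` holds the alive-state fractions (GII, GIII, GIV), each a
    scalar or replication vector.  Returns the post-cycle occupancy, dead
    fraction and a dict of undiscounted accruals.
    """
    occ_g2, occ_g3, occ_g4 = occupancy

    p23 = draw["transition.GII_GIII"]
    p34 = draw["transition.GIII_GIV"]
    g2 = occ_g2 * (1.0 - p23)
    g3 = occ_g2 * p23 + occ_g3 * (1.0 - p34)
    g4 = occ_g3 * p34 + occ_g4

    p0 = life_table.annual_q(age)
    survivors = []
    died = 0.0
    for occ, state in zip((g2, g3, g4), STATES):
        h = np.clip(
            draw[f"{arm}.{state}.p_exacerbation"] * draw[f"{arm}.{state}.p_hosp"],
            0.0, 1.0,
        )
        rr = draw[f"rr.{state}"]
        p_die = (1.0 - h) * death_prob(p0, rr, multiplier) + h * death_prob(
            p0, rr * _hr(draw, state), multiplier
        )
        survivors.append(occ * (1.0 - p_die))
        died = died + occ * p_die

    alive = survivors[0] + survivors[1] + survivors[2]
    cost = sum(
        s * annual_service_cost(arm, state, draw)
        for s, state in zip(survivors, STATES)
    )
    utility = sum(
        s * draw[f"{arm}.{state}.utility"] for s, state in zip(survivors, STATES)
    )
    exac = sum(
        s * draw[f"{arm}.{state}.p_exacerbation"]
        for s, state in zip(survivors, STATES)
    )
    visits = {
        svc: sum(
            s
            * draw[f"{arm}.{state}.p_exacerbation"]
            * draw[f"{arm}.{state}.p_{svc}"]
            * draw[f"{arm}.{state}.n_{svc}"]
            for s, state in zip(survivors, STATES)
        )
        for svc in SERVICES
    }
    accruals = {
        "life_years": alive,
        "utility": utility,
        "cost": cost,
        "exac_fraction": exac,
        "visits": visits,
    }
    return tuple(survivors), dead + died, accruals


def run_cohort(settings: EngineSettings, draw: dict, life_table: LifeTable,
               multiplier: float = 1.0, keep_trace: bool = True) -> ArmResult:
    """Iterate the cohort over the horizon and return discounted totals."""
    n = max(
        (np.ndim(v) and np.shape(v)[0]) for v in draw.values()
    ) if any(np.ndim(v) for v in draw.values()) else 0
    shape = (n,) if n else ()

    occ = tuple(
        np.broadcast_to(np.asarray(f, dtype=float), shape).copy()
        for f in settings.start_state_dist
    )
    dead = np.zeros(shape)

    total_cost = np.zeros(shape)
    total_qaly = np.zeros(shape)
    total_ly = np.zeros(shape)
    rows = [] if keep_trace else None

    for t in range(1, settings.horizon + 1):
        age = settings.start_age + t - 1
        occ, dead, acc = cycle_update(
            occ, dead, age, settings.arm, draw, life_table, multiplier
        )
        df = discount_factor(t, settings.discount_rate)
        total_cost = total_cost + df * acc["cost"]
        total_qaly = total_qaly + df * acc["utility"]
        total_ly = total_ly + df * acc["life_years"]
        if keep_trace:
            rows.append((t, occ, dead, acc, df))

    trace = None
    if keep_trace:
        def stack(vals):
            return np.stack([np.broadcast_to(v, shape) for v in vals])

        trace = CohortTrace(
            cycles=np.array([r[0] for r in rows]),
            occupancy=np.stack(
                [
                    np.stack(
                        [np.broadcast_to(x, shape) for x in (*r[1], r[2])], axis=0
                    )
                    for r in rows
                ]
            ),
            exac_fraction=stack([r[3]["exac_fraction"] for r in rows]),
            visits={
                svc: stack([r[3]["visits"][svc] for r in rows]) for svc in SERVICES
            },
            cost=stack([r[3]["cost"] for r in rows]),
            cost_discounted=stack([r[4] * r[3]["cost"] for r in rows]),
            utility=stack([r[3]["utility"] for r in rows]),
            utility_discounted=stack([r[4] * r[3]["utility"] for r in rows]),
            life_years=stack([r[3]["life_years"] for r in rows]),
            life_years_discounted=stack(
                [r[4] * r[3]["life_years"] for r in rows]
            ),
        )

    squeeze = (lambda x: float(x)) if not n else (lambda x: x)
    return ArmResult(
        cost=squeeze(total_cost),
        qalys=squeeze(total_qaly),
        life_years=squeeze(total_ly),
        trace=trace,
    )
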