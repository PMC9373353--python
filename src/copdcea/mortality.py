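"""Age- and severity-dependent mortality.

Annual all-cause death probabilities come from a life table; GOLD-state
relative risks (RR) and the hospitalisation death hazard ratio (HR) act
multiplicatively on the hazard (rate) scale: with p0 the life-table
probability and r0 = -ln(1 - p0),

    p_state      = 1 - exp(-r0 * m * RR_state)
    p_state,hosp = 1 - exp(-r0 * m * RR_state * HR_state)

where m is a calibration multiplier on the baseline hazard (default 1).
The per-cycle death probability blends the two by the probability h of
experiencing an exacerbation with hospitalisation in that cycle; the
intervention arm affects mortality only through h.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "LifeTable",
    "MortalityModel",
    "annual_death_prob",
    "hosp_death_prob",
    "blended_death_prob",
    "calibrate_multiplier",
]


@dataclass(frozen=True)
class LifeTable:
    """Map from integer age to annual all-cause death probability."""

    ages: tuple
    qx: tuple

    def __post_init__(self):
        q = np.asarray(self.qx)
        a = np.asarray(self.ages)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("life-table probabilities must lie in [0, 1]")
        if len(a) < 2 or np.any(np.diff(a) != 1):
            raise ValueError("life-table ages must be contiguous integers")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        ages, qx = [], []
        with open(path) as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0] == "age":
                    continue
                ages.append(int(row[0]))
                qx.append(float(row[1]))
        return cls(tuple(ages), tuple(qx))

    @classmethod
    def default(cls) -> "LifeTable":
        """The bundled synthetic life-table fixture (see its file header)."""
        path = Path(resources.files("copdcea.data") / "life_table_synthetic.csv")
        return cls.from_csv(path)

    def annual_q(self, age: int) -> float:
        """Annual death probability at ``age``; ages beyond the last row
        reuse the last row (bounded extrapolation for long horizons)."""
        if age < self.ages[0]:
            raise ValueError(f"age {age} below life-table range ({self.ages[0]})")
        idx = min(int(age) - self.ages[0], len(self.qx) - 1)
        return self.qx[idx]


@dataclass
class MortalityModel:
    """Life table + per-state RR/HR + baseline-hazard calibration multiplier."""

    life_table: LifeTable
    rr_by_state: dict
    hosp_hr_by_state: dict
    multiplier: float = 1.0

    def __post_init__(self):
        for d in (self.rr_by_state, self.hosp_hr_by_state):
            for k, v in d.items():
                if np.any(np.asarray(v) <= 0):
                    raise ValueError(f"non-positive risk ratio for {k}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


def death_prob(p0, rr, multiplier=1.0):
    """Hazard-scale combination 1 - exp(-(-ln(1-p0)) * multiplier * rr)."""
    r0 = -np.log1p(-np.asarray(p0, dtype=float))
    return -np.expm1(-r0 * multiplier * np.asarray(rr, dtype=float))


def annual_death_prob(age, state, model: MortalityModel):
    p0 = model.life_table.annual_q(age)
    return death_prob(p0, model.rr_by_state[state], model.multiplier)


def hosp_death_prob(age, state, model: MortalityModel):
    p0 = model.life_table.annual_q(age)
    rr = np.asarray(model.rr_by_state[state]) * np.asarray(
        model.hosp_hr_by_state[state]
    )
    return death_prob(p0, rr, model.multiplier)


def blended_death_prob(age, state, h, model: MortalityModel):
    """Convex blend by hospitalisation exposure h ∈ [0, 1]."""
    h = np.asarray(h, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hospitalisation exposure h must lie in [0, 1]")
    return (1.0 - h) * annual_death_prob(age, state, model) + h * hosp_death_prob(
        age, state, model
    )


def calibrate_multiplier(table, settings, life_table: LifeTable,
                         target_life_years: float, tol: float = 1e-6) -> float:
    """Bisect the baseline-hazard multiplier so the usual-care cohort's
    deterministic life years over ``settings.horizon`` equal the target.

    Life years are monotone decreasing in the multiplier, so the root is
    unique.  Used to pin trial-horizon runs to the published survival when
    the original life table is unavailable.
    """
    from dataclasses import replace

    from .engine import run_cohort
    from .params import base_draw

    if not (0 < target_life_years <= settings.horizon):
        raise ValueError(
            f"target life years {target_life_years} not in (0, horizon]"
        )
    draw = base_draw(table)
    uc = replace(settings, arm="UC")

    def life_years(m):
        return float(run_cohort(uc, draw, life_table, multiplier=m,
                                keep_trace=False).life_years)

    lo, hi = 1e-6, 1e3
    ly_lo = life_years(lo)
    if ly_lo <= target_life_years:
        import warnings

        warnings.warn(
            "target life years unreachable even at near-zero mortality; "
            "returning the lower multiplier bound"
        )
        return lo
    if life_years(hi) > target_life_years + tol:
        raise ValueError("target life years unreachable within multiplier bounds")
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisect in log space over 9 decades
        if life_years(mid) > target_life_years:
            lo = mid
        else:
            hi = mid
        if abs(life_years(mid) - target_life_years) < tol:
            return float(mid)
    return float(np.sqrt(lo * hi))
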