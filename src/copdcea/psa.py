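"""Probabilistic sensitivity analysis driver.

Each Monte-Carlo replication samples one value per model input from its
distribution and runs both arms of the Markov cohort model with it.
Parameters common to the two arms (transitions, mortality RR/HR, unit
costs) are sampled once per replication and shared — arm differences flow
only through arm-specific parameters — which pairs the arms and sharply
reduces Monte-Carlo variance of the increments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import EngineSettings, run_cohort
from .mortality import LifeTable
from .params import ParameterTable, sample_table

__all__ = ["PSASample", "run_psa", "summarize"]

Z975 = 1.959964

OUTCOME_COLS = (
    "cost_UC", "qaly_UC", "ly_UC",
    "cost_IDM", "qaly_IDM", "ly_IDM",
    "dcost", "dqaly", "dly",
)


@dataclass
class PSASample:
    """Replication-level outcomes plus the retained parameter draws."""

    data: pd.DataFrame   # one row per replication, OUTCOME_COLS
    draws: pd.DataFrame  # realized parameter values (for EVPPI)
    meta: dict           # seed, n_reps, horizon, start_age, discount, ...

    @property
    def n_reps(self) -> int:
        return len(self.data)


def run_psa(table: ParameterTable, settings: EngineSettings, n_reps: int,
            seed: int, life_table: LifeTable | None = None,
            multiplier: float = 1.0, draw_transform=None) -> PSASample:
    """Run the PSA: ``n_reps`` paired cohort evaluations of both arms.

    ``draw_transform``, if given, receives the sampled draw dict (values are
    replication vectors) and returns a possibly modified dict; scenario
    couplings (utility floors, cost doubling) hook in here.  Runs are
    reproducible: the same seed yields bitwise-identical draws.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if life_table is None:
        life_table = LifeTable.default()

    draw = sample_table(table, n_reps, seed)
    if draw_transform is not None:
        draw = draw_transform(draw)

    results = {}
    for arm in ("UC", "IDM"):
        res = run_cohort(
            replace(settings, arm=arm), draw, life_table,
            multiplier=multiplier, keep_trace=False,
        )
        results[arm] = res

    data = pd.DataFrame(
        {
            "cost_UC": np.atleast_1d(results["UC"].cost),
            "qaly_UC": np.atleast_1d(results["UC"].qalys),
            "ly_UC": np.atleast_1d(results["UC"].life_years),
            "cost_IDM": np.atleast_1d(results["IDM"].cost),
            "qaly_IDM": np.atleast_1d(results["IDM"].qalys),
            "ly_IDM": np.atleast_1d(results["IDM"].life_years),
        }
    )
    data["dcost"] = data["cost_IDM"] - data["cost_UC"]
    data["dqaly"] = data["qaly_IDM"] - data["qaly_UC"]
    data["dly"] = data["ly_IDM"] - data["ly_UC"]

    draws = pd.DataFrame({k: np.broadcast_to(v, (n_reps,)) for k, v in draw.items()})
    meta = {
        "seed": int(seed),
        "n_reps": int(n_reps),
        "horizon": settings.horizon,
        "start_age": settings.start_age,
        "discount_rate": settings.discount_rate,
        "multiplier": float(multiplier),
    }
    return PSASample(data=data, draws=draws, meta=meta)


def summarize(sample: PSASample) -> dict:
    """Means with two uncertainty bands per outcome.

    ``se_ci`` is the 95% standard-error band of the Monte-Carlo mean
    (the published increment intervals are of this kind for paired draws);
    ``percentile_ci`` is the 2.5/97.5 percentile of the replications.
    """
    if sample.n_reps < 2:
        raise ValueError("summary requires at least 2 replications")
    out = {}
    n = sample.n_reps
    for col in OUTCOME_COLS:
        x = sample.data[col].to_numpy()
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / np.sqrt(n))
        lo, hi = np.percentile(x, [2.5, 97.5])
        out[col] = {
            "mean": m,
            "se": se,
            "se_ci": (m - Z975 * se, m + Z975 * se),
            "percentile_ci": (float(lo), float(hi)),
        }
    return out
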