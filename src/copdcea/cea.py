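"""Cost-effectiveness statistics over a PSA sample.

Implements the decision-analytic outputs: incremental cost-effectiveness /
cost-utility ratio with dominance labelling, net monetary benefit
(ΔQALY × willingness-to-pay − ΔCost), the cost-effectiveness acceptability
curve, per-patient expected value of perfect information

    EVPI(k) = E[max_a NB_a] - max_a E[NB_a],

and regression-metamodel EVPPI for parameter subsets,

    EVPPI(S) = E[max(0, g_S)] - max(0, E[g_S]),

with g_S the metamodel fit of the incremental net benefit on the subset's
draws (a linear metamodel by default, with an additive cubic alternative,
since linear metamodels can understate EVPPI).  A logistic companion model
of the cost-effectiveness indicator is provided for exploring which
parameters drive the decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psa import PSASample

__all__ = [
    "CEAResult",
    "icer",
    "net_benefit",
    "ceac",
    "evpi",
    "evppi_metamodel",
    "evppi_by_group",
    "logistic_ce_explorer",
    "ce_plane",
    "parameter_groups",
    "compute_cea",
    "default_wtp_grid",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def default_wtp_grid() -> np.ndarray:
    """0 … 100,000 CAD/QALY in 500-dollar steps."""
    return np.arange(0.0, 100000.0 + 1, 500.0)


def icer(dcost: float, dqaly: float):
    """ICER value or a dominance label.

    Cheaper and more effective → "dominant"; costlier and less effective →
    "dominated"; otherwise the ratio (with an "undefined" label at ΔQ = 0).
    """
    if dcost < 0 and dqaly > 0:
        return DOMINANT
    if dcost > 0 and dqaly < 0:
        return DOMINATED
    if dqaly == 0:
        return UNDEFINED
    return dcost / dqaly


def net_benefit(dqaly, dcost, wtp):
    """Incremental net monetary benefit ΔQALY·wtp − ΔCost."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness to pay must be nonnegative")
    return np.asarray(dqaly) * wtp - np.asarray(dcost)


def _increments(sample: PSASample):
    return sample.data["dqaly"].to_numpy(), sample.data["dcost"].to_numpy()


def ceac(sample: PSASample, wtp_grid=None) -> pd.DataFrame:
    """P(intervention cost-effective) across the willingness-to-pay grid.

    The probability at each threshold is the fraction of replications with
    strictly positive incremental net benefit (ties count as not
    cost-effective).
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0 or np.any(wtp_grid < 0):
        raise ValueError("wtp grid must be nonempty and nonnegative")
    dq, dc = _increments(sample)
    nb = dq[:, None] * wtp_grid[None, :] - dc[:, None]
    prob = np.mean(nb > 0, axis=0)
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})


def ceac_at(sample: PSASample, wtp: float) -> float:
    return float(ceac(sample, [wtp])["probability"].iloc[0])


def _arm_nb(sample: PSASample, wtp: float):
    d = sample.data
    nb_uc = d["qaly_UC"].to_numpy() * wtp - d["cost_UC"].to_numpy()
    nb_idm = d["qaly_IDM"].to_numpy() * wtp - d["cost_IDM"].to_numpy()
    return nb_uc, nb_idm


def evpi(sample: PSASample, wtp: float) -> float:
    """Per-patient expected value of perfect information at one threshold."""
    if sample.n_reps < 2:
        raise ValueError("EVPI requires at least 2 replications")
    nb_uc, nb_idm = _arm_nb(sample, wtp)
    return float(
        np.mean(np.maximum(nb_uc, nb_idm)) - max(np.mean(nb_uc), np.mean(nb_idm))
    )


def evpi_curve(sample: PSASample, wtp_grid=None) -> pd.DataFrame:
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    return pd.DataFrame(
        {"wtp": wtp_grid, "evpi": [evpi(sample, k) for k in wtp_grid]}
    )


# ---------------------------------------------------------------------------
# EVPPI metamodels
# ---------------------------------------------------------------------------

@dataclass
class EvppiResult:
    value: float
    r_squared: float
    subset: tuple
    flexible: bool
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)


def _design(X: np.ndarray, flexible: bool) -> np.ndarray:
    # standardize; drop zero-variance (fixed-parameter) columns
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if flexible:
        Xs = np.column_stack([Xs, Xs**2, Xs**3])
    return np.column_stack([np.ones(len(X)), Xs])


def evppi_metamodel(sample: PSASample, subset, wtp: float,
                    flexible: bool = False) -> EvppiResult:
    """Regression-metamodel EVPPI for a subset of retained draw columns."""
    subset = tuple(subset)
    missing = [c for c in subset if c not in sample.draws.columns]
    if missing:
        raise KeyError(f"draw columns not retained: {missing}")
    dq, dc = _increments(sample)
    y = net_benefit(dq, dc, wtp)
    X = sample.draws[list(subset)].to_numpy(dtype=float)
    D = _design(X, flexible)
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ coef
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    value = float(np.mean(np.maximum(0.0, fitted)) - max(0.0, float(np.mean(fitted))))
    return EvppiResult(value=value, r_squared=r2, subset=subset,
                       flexible=flexible, fitted=fitted, residuals=resid)


def parameter_groups(sample: PSASample) -> dict:
    """Named parameter subsets of the retained draws, by model role."""
    cols = list(sample.draws.columns)
    groups = {
        "utilities": [c for c in cols if c.endswith(".utility")],
        "exacerbation_probs": [c for c in cols if c.endswith(".p_exacerbation")],
        "service_probs": [
            c for c in cols
            if c.endswith((".p_urgent", ".p_er", ".p_hosp"))
        ],
        "visit_counts": [
            c for c in cols
            if c.endswith((".n_urgent", ".n_er", ".n_hosp"))
        ],
        "unit_costs": [c for c in cols if c.startswith("cost.")],
        "intervention_costs": [c for c in cols if c.startswith("intervention.")],
        "mortality": [c for c in cols if c.startswith(("rr.", "hr."))],
        "transitions": [c for c in cols if c.startswith("transition.")],
    }
    return {k: v for k, v in groups.items() if v}


def evppi_by_group(sample: PSASample, wtp: float, groups: dict | None = None,
                   flexible: bool = False) -> dict:
    if groups is None:
        groups = parameter_groups(sample)
    return {
        name: evppi_metamodel(sample, cols, wtp, flexible=flexible).value
        for name, cols in groups.items()
    }


def logistic_ce_explorer(sample: PSASample, wtp: float, columns=None):
    """Logistic companion model: which parameters predict cost-effectiveness.

    Fits P(incremental NB > 0) on standardized draws with statsmodels GLM
    (binomial).  This explores decision drivers; it is not the EVPPI
    estimator itself.
    """
    import statsmodels.api as sm

    dq, dc = _increments(sample)
    y = (net_benefit(dq, dc, wtp) > 0).astype(float)
    if columns is None:
        columns = list(sample.draws.columns)
    columns = [c for c in columns if sample.draws[c].std() > 0]
    X = sample.draws[list(columns)].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    exog = sm.add_constant(pd.DataFrame(Xs, columns=list(columns)))
    return sm.GLM(y, exog, family=sm.families.Binomial()).fit()


# ---------------------------------------------------------------------------
# CE plane and bundled result
# ---------------------------------------------------------------------------

@dataclass
class CEPlane:
    points: pd.DataFrame      # dqaly, dcost per replication
    quadrant_counts: dict     # NE / NW / SE / SW
    sustainability_fraction: float
    wtp: float


def ce_plane(sample: PSASample, wtp: float = 50000.0) -> CEPlane:
    """Per-replication incremental (QALY, cost) points with quadrant counts.

    The sustainability fraction (points below the willingness-to-pay line)
    equals the CEAC value at the same threshold by construction.
    """
    dq, dc = _increments(sample)
    quad = {
        "NE": int(np.sum((dq > 0) & (dc >= 0))),
        "NW": int(np.sum((dq <= 0) & (dc >= 0))),
        "SE": int(np.sum((dq > 0) & (dc < 0))),
        "SW": int(np.sum((dq <= 0) & (dc < 0))),
    }
    frac = float(np.mean(net_benefit(dq, dc, wtp) > 0))
    return CEPlane(
        points=pd.DataFrame({"dqaly": dq, "dcost": dc}),
        quadrant_counts=quad,
        sustainability_fraction=frac,
        wtp=wtp,
    )


@dataclass
class CEAResult:
    """Bundled cost-effectiveness outputs at a reference threshold."""

    dcost_mean: float
    dqaly_mean: float
    dcost_ci: tuple
    dqaly_ci: tuple
    icer_label: object
    net_benefit: float
    wtp: float
    ceac: pd.DataFrame
    evpi: float
    evppi: dict
    summary: dict

    def ceac_at(self, wtp: float) -> float:
        row = self.ceac[np.isclose(self.ceac["wtp"], wtp)]
        if len(row):
            return float(row["probability"].iloc[0])
        raise KeyError(f"wtp {wtp} not on the CEAC grid")


def compute_cea(sample: PSASample, wtp: float = 50000.0, wtp_grid=None,
                evppi_groups: dict | None = None,
                flexible_evppi: bool = False) -> CEAResult:
    """All cost-effectiveness outputs for one PSA sample."""
    from .psa import summarize

    summ = summarize(sample)
    dq_m = summ["dqaly"]["mean"]
    dc_m = summ["dcost"]["mean"]
    curve = ceac(sample, wtp_grid)
    return CEAResult(
        dcost_mean=dc_m,
        dqaly_mean=dq_m,
        dcost_ci=summ["dcost"]["se_ci"],
        dqaly_ci=summ["dqaly"]["se_ci"],
        icer_label=icer(dc_m, dq_m),
        net_benefit=float(net_benefit(dq_m, dc_m, wtp)),
        wtp=wtp,
        ceac=curve,
        evpi=evpi(sample, wtp),
        evppi=evppi_by_group(sample, wtp, groups=evppi_groups,
                             flexible=flexible_evppi),
        summary=summ,
    )
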