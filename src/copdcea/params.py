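"""Model-input registry: distribution specifications, validation and sampling.

Every input of the cost-utility model — disease-progression and event
probabilities, visit frequencies, unit costs, intervention costs, mortality
relative risks and hazard ratios, and health-state utilities — is described by
a :class:`DistributionSpec` carrying both a deterministic *base estimate* and
a sampling distribution for probabilistic sensitivity analysis:

* ``beta``          — probabilities, parameterised by (alpha, beta) counts;
* ``lognormal_ci``  — positive quantities specified by the lower/upper limit
  of their 95% confidence interval (visit counts, relative risks, hazard
  ratios);
* ``gamma``         — costs, parameterised by (shape, scale);
* ``resample``      — empirical resampling with replacement from a finite
  utility pool;
* ``fixed``         — point values (e.g. the ER visit fee, the discount rate).

The complete keyed set of inputs is a :class:`ParameterTable`; one Monte-Carlo
realisation of it is a flat ``dict`` of numpy arrays (a *draw*).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from importlib import resources

import numpy as np

__all__ = [
    "DistributionSpec",
    "ParameterTable",
    "ParameterValidationError",
    "lognormal_from_ci",
    "load_parameters",
    "default_config_path",
    "sample_value",
    "sample_table",
    "base_draw",
    "STATES",
    "ARMS",
]

STATES = ("GII", "GIII", "GIV")
ARMS = ("UC", "IDM")

#: Normal 97.5% quantile used to convert a 95% CI to a log-scale sd.
Z975 = 1.959964

FAMILIES = ("beta", "lognormal_ci", "gamma", "resample", "fixed")

# Relative tolerances for base-estimate vs distribution-mean consistency.
BETA_MEAN_ATOL = 0.005   # printed probabilities are rounded to 2 decimals
GAMMA_MEAN_RTOL = 0.02   # one printed cost item deviates by ~1.8%


class ParameterValidationError(ValueError):
    """Raised when a configuration entry is missing or malformed.

    The message lists every offending key path.
    """


def lognormal_from_ci(ci_lower: float, ci_upper: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal specified by its 95% CI bounds.

    mu = (ln lo + ln hi) / 2, sigma = (ln hi - ln lo) / (2 * 1.959964).
    """
    if not (0 < ci_lower < ci_upper):
        raise ValueError(
            f"need 0 < ci_lower < ci_upper, got ({ci_lower}, {ci_upper})"
        )
    llo, lhi = math.log(ci_lower), math.log(ci_upper)
    return (llo + lhi) / 2.0, (lhi - llo) / (2.0 * Z975)


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled model input: a family, its parameters and a base estimate."""

    family: str
    base_estimate: float
    params: dict = field(default_factory=dict)
    pool: tuple = ()  # resample family only

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError(f"beta parameters must be positive, got {p}")
        elif self.family == "gamma":
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValueError(f"gamma parameters must be positive, got {p}")
        elif self.family == "lognormal_ci":
            lognormal_from_ci(p["ci_lower"], p["ci_upper"])  # validates
        elif self.family == "resample":
            if len(self.pool) == 0:
                raise ValueError("resample spec with empty pool")

    # -- constructors ------------------------------------------------------
    @classmethod
    def beta(cls, alpha, beta, base):
        return cls("beta", base, {"alpha": alpha, "beta": beta})

    @classmethod
    def gamma(cls, shape, scale, base):
        return cls("gamma", base, {"shape": shape, "scale": scale})

    @classmethod
    def lognormal_ci(cls, ci_lower, ci_upper, base):
        return cls("lognormal_ci", base, {"ci_lower": ci_lower, "ci_upper": ci_upper})

    @classmethod
    def fixed(cls, value):
        return cls("fixed", value)

    @classmethod
    def resample(cls, pool, base=None):
        pool = tuple(float(v) for v in pool)
        if base is None:
            base = float(np.mean(pool)) if pool else float("nan")
        return cls("resample", base, pool=pool)

    # -- semantics ---------------------------------------------------------
    @property
    def base_value(self) -> float:
        """Deterministic value: the base estimate (pool mean for resample)."""
        if self.family == "resample":
            return float(np.mean(self.pool))
        return float(self.base_estimate)

    def mean(self) -> float:
        """Analytic (or empirical, for resample) mean of the sampling family."""
        p = self.params
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "lognormal_ci":
            mu, sigma = lognormal_from_ci(p["ci_lower"], p["ci_upper"])
            return math.exp(mu + sigma**2 / 2.0)
        if self.family == "resample":
            return float(np.mean(self.pool))
        return float(self.base_estimate)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the spec's family; ``fixed`` returns the value exactly."""
        p = self.params
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=size)
        if self.family == "lognormal_ci":
            mu, sigma = lognormal_from_ci(p["ci_lower"], p["ci_upper"])
            return rng.lognormal(mu, sigma, size=size)
        if self.family == "resample":
            pool = np.asarray(self.pool, dtype=float)
            idx = rng.integers(0, len(pool), size=size)
            return pool[idx]
        # fixed
        if size is None:
            return float(self.base_estimate)
        return np.full(size, float(self.base_estimate))


def sample_value(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Functional alias for :meth:`DistributionSpec.sample`."""
    return spec.sample(rng, size=size)


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

ARM_FIELDS = (
    "p_exacerbation", "p_urgent", "p_er", "p_hosp",
    "n_urgent", "n_er", "n_hosp", "utility",
)
UNIT_COST_KEYS = {
    "urgent": ("physician", "lab", "transport", "medication"),
    "er": ("visit", "transport", "medication"),
    "hosp": ("stay", "lab", "transport"),
}
INTERVENTION_ITEMS = (
    "medical_program_director", "program_coordinator", "cre",
    "spirometry", "computer", "spirometry_filters",
)

#: keys whose sampled values are probabilities and get clamped to [0, 1]
def _is_probability_key(key: str) -> bool:
    return key.startswith("transition.") or ".p_" in key


@dataclass
class ParameterTable:
    """The complete keyed set of model inputs for both arms and all states.

    ``specs`` maps flat dotted keys (e.g. ``"UC.GII.p_exacerbation"``,
    ``"cost.hosp.stay"``, ``"rr.GIII"``, ``"hr.GIII_GIV"``) to
    :class:`DistributionSpec`.  The shared GOLD III/IV hospitalisation death
    hazard ratio is stored once under ``hr.GIII_GIV``.
    """

    specs: dict
    discount_rate: float = 0.015
    wtp: float = 50000.0

    def __getitem__(self, key: str) -> DistributionSpec:
        return self.specs[key]

    def __contains__(self, key):
        return key in self.specs

    def keys(self):
        return self.specs.keys()

    def hr_key(self, state: str) -> str:
        return "hr.GII" if state == "GII" else "hr.GIII_GIV"

    def intervention_total_base(self) -> float:
        return sum(
            self.specs[f"intervention.{k}"].base_value for k in INTERVENTION_ITEMS
        )

    def unit_cost_base(self, service: str) -> float:
        return sum(
            self.specs[f"cost.{service}.{c}"].base_value
            for c in UNIT_COST_KEYS[service]
        )

    def replace(self, **overrides) -> "ParameterTable":
        """New table with some specs replaced (key → DistributionSpec)."""
        specs = dict(self.specs)
        specs.update(overrides)
        return ParameterTable(specs, self.discount_rate, self.wtp)


def default_config_path() -> Path:
    return Path(resources.files("copdcea.data") / "default_config.json")


def _build_spec(entry: dict, key: str, errors: list) -> DistributionSpec | None:
    try:
        fam = entry["family"]
        if fam == "beta":
            return DistributionSpec.beta(entry["alpha"], entry["beta"], entry["base"])
        if fam == "gamma":
            return DistributionSpec.gamma(entry["shape"], entry["scale"], entry["base"])
        if fam == "lognormal_ci":
            return DistributionSpec.lognormal_ci(
                entry["ci_lower"], entry["ci_upper"], entry["base"]
            )
        if fam == "fixed":
            return DistributionSpec.fixed(entry["value"])
        if fam == "resample":
            from .utilities import build_pool  # deferred: avoids import cycle

            pool = build_pool(
                entry["min"], entry["median"], entry["max"], entry["mean"],
                int(entry["n"]),
            )
            return DistributionSpec.resample(pool.values, base=entry["mean"])
        errors.append(f"{key}: unknown family {fam!r}")
    except KeyError as e:
        errors.append(f"{key}: missing field {e}")
    except (ValueError, TypeError) as e:
        errors.append(f"{key}: {e}")
    return None


def _check_mean_consistency(key: str, spec: DistributionSpec, errors: list) -> None:
    if spec.family == "beta":
        if abs(spec.mean() - spec.base_estimate) > BETA_MEAN_ATOL + 1e-12:
            errors.append(
                f"{key}: beta mean {spec.mean():.4f} inconsistent with base "
                f"estimate {spec.base_estimate}"
            )
    elif spec.family == "gamma":
        rel = abs(spec.mean() - spec.base_estimate) / spec.base_estimate
        if rel > GAMMA_MEAN_RTOL:
            errors.append(
                f"{key}: gamma mean {spec.mean():.4f} inconsistent with base "
                f"estimate {spec.base_estimate}"
            )


def load_parameters(config=None) -> ParameterTable:
    """Load and validate a parameter configuration.

    Parameters
    ----------
    config : path-like, dict or None
        JSON file path or an already-parsed mapping.  ``None`` loads the
        bundled default configuration.

    Raises
    ------
    ParameterValidationError
        listing every missing or invalid entry by key path.
    """
    if config is None:
        config = default_config_path()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)

    errors: list[str] = []
    specs: dict[str, DistributionSpec] = {}

    def take(cfg_path: list[str], key: str):
        node = config
        for part in cfg_path:
            if not isinstance(node, dict) or part not in node:
                errors.append(f"{'.'.join(cfg_path)}: missing")
                return
            node = node[part]
        spec = _build_spec(node, key, errors)
        if spec is not None:
            _check_mean_consistency(key, spec, errors)
            specs[key] = spec

    for trans in ("GII_GIII", "GIII_GIV"):
        take(["transition", trans], f"transition.{trans}")
    for s in STATES:
        take(["mortality_rr", s], f"rr.{s}")
    take(["hosp_death_hr", "GII"], "hr.GII")
    take(["hosp_death_hr", "GIII_GIV"], "hr.GIII_GIV")
    for arm in ARMS:
        for s in STATES:
            for f in ARM_FIELDS:
                take(["arms", arm, s, f], f"{arm}.{s}.{f}")
    for service, comps in UNIT_COST_KEYS.items():
        for c in comps:
            take(["unit_costs", service, c], f"cost.{service}.{c}")
    for item in INTERVENTION_ITEMS:
        take(["intervention", item], f"intervention.{item}")

    if errors:
        raise ParameterValidationError(
            "invalid parameter configuration:\n  " + "\n  ".join(errors)
        )

    discount = float(config.get("discount_rate", {}).get("value", 0.015))
    wtp = float(config.get("wtp", {}).get("value", 50000.0))
    return ParameterTable(specs, discount_rate=discount, wtp=wtp)


# ---------------------------------------------------------------------------
# Draws
# ---------------------------------------------------------------------------

def _key_rng(seed: int, key: str) -> np.random.Generator:
    # Independent, order-invariant substream per parameter: scenario overrides
    # of one parameter must not shift the draws of any other.
    return np.random.default_rng([int(seed), zlib.crc32(key.encode())])


def sample_table(table: ParameterTable, n_reps: int, seed: int) -> dict:
    """One vector of ``n_reps`` draws per parameter key.

    Each key gets its own deterministic substream derived from ``seed``, so
    draws for a given key are identical across runs that share the seed,
    regardless of which other keys exist.  Probabilities are clamped to
    [0, 1] (a no-op for beta draws).
    """
    draw: dict[str, np.ndarray] = {}
    for key in sorted(table.keys()):
        spec = table[key]
        vals = np.asarray(spec.sample(_key_rng(seed, key), size=n_reps), dtype=float)
        if _is_probability_key(key):
            vals = np.clip(vals, 0.0, 1.0)
        draw[key] = vals
    return draw


def base_draw(table: ParameterTable) -> dict:
    """Deterministic draw: every entry at its base estimate (pool mean)."""
    return {key: table[key].base_value for key in table.keys()}
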