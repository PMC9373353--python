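"""Health-state utilities: CAT→EQ-5D conversion and empirical resampling pools.

Trial utilities come from four COPD Assessment Test items (chest tightness,
activity, confidence, energy) mapped to EQ-5D through a published linear
regression.  The patient-level utilities are not public, so for each
(arm × GOLD state) cell we reconstruct a finite pool matching the printed
summary (min, median, max, mean); probabilistic runs resample from that pool
with replacement, mirroring the original resampling design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CatItems", "UtilityPool", "cat_to_eq5d", "build_pool", "resample_utility"]

CAT_ITEM_NAMES = ("chest_tightness", "activity", "confidence", "energy")


@dataclass(frozen=True)
class CatItems:
    """The four CAT item scores (each 0–5) used by the EQ-5D mapping."""

    chest_tightness: int
    activity: int
    confidence: int
    energy: int

    def __post_init__(self):
        for name in CAT_ITEM_NAMES:
            v = getattr(self, name)
            if not (0 <= v <= 5):
                raise ValueError(f"CAT item {name}={v} outside 0..5")

    def as_array(self):
        return np.array([getattr(self, n) for n in CAT_ITEM_NAMES], dtype=float)


def cat_to_eq5d(items: CatItems, coefficients: dict) -> float:
    """Linear CAT→EQ-5D mapping, clamped to [0, 1].

    ``coefficients`` must supply ``intercept`` plus one slope per item name.
    The regression coefficients are published in the supplementary material of
    the source trial analysis and are deliberately not bundled: they must be
    provided by the user (any stand-in set used in testing is synthetic).
    """
    if coefficients is None or "intercept" not in coefficients or any(
        n not in coefficients for n in CAT_ITEM_NAMES
    ):
        raise ValueError(
            "CAT->EQ-5D coefficients missing: supply a mapping with keys "
            "'intercept', " + ", ".join(repr(n) for n in CAT_ITEM_NAMES)
            + " (see the published conversion algorithm's supplementary table)"
        )
    pred = coefficients["intercept"] + float(
        np.dot([coefficients[n] for n in CAT_ITEM_NAMES], items.as_array())
    )
    return float(min(1.0, max(0.0, pred)))


@dataclass(frozen=True)
class UtilityPool:
    """Finite utility pool for one (arm × state) cell."""

    values: tuple
    summary: tuple  # (min, median, max, mean)

    def __len__(self):
        return len(self.values)


def _tri_quantile_asc(F, a, b, c):
    # inverse CDF of triangular(a, mode c, max b), ascending branch F<=Fc
    return a + np.sqrt(F * (b - a) * (c - a))


def _tri_quantile_desc(F, a, b, c):
    # descending branch F>=Fc
    return b - np.sqrt((1.0 - F) * (b - a) * (b - c))


def _interior_positions(block, vmin, vmed, vmax, k, gamma):
    """k strictly increasing triangular quantiles inside one block.

    ``block`` is "lo" for (min, median) or "hi" for (median, max); the
    within-block quantile levels are warped by u**gamma (gamma is the
    mean-matching knob: larger gamma pulls points toward the block's lower
    end).
    """
    if k == 0:
        return np.empty(0)
    u = np.arange(1, k + 1) / (k + 1)
    levels = u**gamma
    span = vmax - vmin
    if span <= 0:
        return np.full(k, vmed)
    fc = (vmed - vmin) / span  # CDF mass below the mode
    if block == "lo":
        if vmed <= vmin:
            return np.full(k, vmin)
        return _tri_quantile_asc(levels * fc, vmin, vmax, vmed)
    if vmax <= vmed:
        return np.full(k, vmax)
    return _tri_quantile_desc(fc + levels * (1.0 - fc), vmin, vmax, vmed)


def _pool_values(vmin, vmed, vmax, n, gamma):
    # Sorted pool with exact min/median/max. For even n the median occupies
    # the two central order statistics so the empirical median is exact.
    if n % 2 == 1:
        n_med = 1
        n_lo = (n - 3) // 2
    else:
        n_med = 2
        n_lo = (n - 4) // 2
    n_hi = n - 2 - n_med - n_lo
    lo = _interior_positions("lo", vmin, vmed, vmax, n_lo, gamma)
    hi = _interior_positions("hi", vmin, vmed, vmax, n_hi, gamma)
    return np.concatenate([[vmin], lo, [vmed] * n_med, hi, [vmax]])


def build_pool(vmin: float, vmed: float, vmax: float, mean: float, n: int,
               tol: float = 1e-3) -> UtilityPool:
    """Deterministically construct an ``n``-point pool matching a summary.

    Min, median and max are placed exactly (twice for the median when ``n``
    is even, so the empirical median is exact).  The remaining points sit at
    the quantiles of a triangular distribution with support [min, max] and
    mode at the median — the standard three-point model for a quantity known
    only by its minimum, most-likely and maximum values; an even fill would
    treat the extreme order statistics as typical mass and overstate the
    pool's dispersion.  The within-block quantile levels are then warped by
    a shared power exponent, bisected until the pool mean matches ``mean``
    within ``tol``.  Ordering and the [min, max] support are preserved by
    construction.  The same summary always yields the same pool.
    """
    if not (vmin <= vmed <= vmax):
        raise ValueError(f"need min <= median <= max, got {(vmin, vmed, vmax)}")
    if not (vmin <= mean <= vmax):
        raise ValueError(f"mean {mean} outside [min, max] = [{vmin}, {vmax}]")
    if n < 3:
        raise ValueError(f"pool size must be >= 3, got {n}")

    def pool_mean(gamma):
        return float(np.mean(_pool_values(vmin, vmed, vmax, n, gamma)))

    # mean is monotone decreasing in gamma (u^gamma shrinks as gamma grows)
    g_lo, g_hi = 0.02, 50.0
    m_hi, m_lo = pool_mean(g_lo), pool_mean(g_hi)
    target = float(mean)
    if target >= m_hi:
        gamma = g_lo
    elif target <= m_lo:
        gamma = g_hi
    else:
        for _ in range(200):
            g_mid = 0.5 * (g_lo + g_hi)
            if pool_mean(g_mid) > target:
                g_lo = g_mid
            else:
                g_hi = g_mid
        gamma = 0.5 * (g_lo + g_hi)

    values = _pool_values(vmin, vmed, vmax, n, gamma)
    if abs(float(np.mean(values)) - target) > tol:
        raise ValueError(
            f"pool mean {np.mean(values):.4f} cannot reach target {target} "
            f"within {tol} for summary {(vmin, vmed, vmax)} and n={n}"
        )
    return UtilityPool(tuple(float(v) for v in values),
                       (vmin, vmed, vmax, mean))


def resample_utility(pool: UtilityPool, rng: np.random.Generator, size=None):
    """Uniform draw(s) with replacement from the pool."""
    if len(pool) == 0:
        raise ValueError("empty utility pool")
    vals = np.asarray(pool.values)
    idx = rng.integers(0, len(vals), size=size)
    return vals[idx]
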