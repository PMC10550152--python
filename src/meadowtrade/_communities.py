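"""Inverse construction of community tables with a prescribed Shannon index.

The synthetic-data generator works "indicator first": it draws a target value
for each indicator and then builds raw records that realize it. For diversity
indicators that means constructing an abundance vector whose Shannon entropy
matches a target H. We use a geometric-series abundance model
``p_i ∝ exp(-lam * i)`` — a classic ecological rank-abundance shape — whose
entropy decreases monotonically from ``ln S`` (lam = 0, even community) toward
0 (lam large, one dominant species), and solve for ``lam`` by bisection.

Integer count communities are quantized by largest-remainder apportionment so
column totals are hit exactly; the realized entropy is recomputed from the
final counts downstream, so quantization never introduces silent error.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError

_LAMBDA_MAX = 60.0


def entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def geometric_proportions(n_species: int, lam: float) -> np.ndarray:
    w = np.exp(-lam * np.arange(n_species, dtype=float))
    return w / w.sum()


def proportions_for_entropy(
    target_h: float, n_species: int, fixed: np.ndarray | None = None
) -> np.ndarray:
    """Free-species proportions so total entropy (incl. ``fixed``) matches ``target_h``.

    ``fixed`` are probabilities of categories whose share cannot be adjusted
    (e.g. a bumblebee species whose count is pinned by another indicator).
    Targets outside the achievable entropy range are clamped to the nearest
    achievable value; exactness is restored downstream by storing realized
    rather than intended values.
    """
    if n_species < 1:
        raise ConfigurationError("proportions_for_entropy: need at least one species")
    fixed = np.asarray([] if fixed is None else fixed, dtype=float)
    free_mass = 1.0 - fixed.sum()
    if free_mass <= 0:
        raise ConfigurationError("proportions_for_entropy: fixed categories exhaust all mass")

    def h(lam: float) -> float:
        q = np.concatenate([fixed, free_mass * geometric_proportions(n_species, lam)])
        return entropy(q)

    if n_species == 1 or target_h >= h(0.0):
        lam = 0.0
    elif target_h <= h(_LAMBDA_MAX):
        lam = _LAMBDA_MAX
    else:
        lam = brentq(lambda L: h(L) - target_h, 0.0, _LAMBDA_MAX, xtol=1e-13)
    return free_mass * geometric_proportions(n_species, lam)


def apportion(proportions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of ``proportions * total`` to integers summing to ``total``."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    raw = p * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def species_count_for(target_h: float, minimum: int = 2, cap: int = 300) -> int:
    """Smallest species count that leaves headroom above ``target_h`` (H < ln S)."""
    s = max(minimum, math.ceil(math.exp(max(target_h, 0.0))) + 1)
    return min(s, cap)


def community_counts(
    target_h: float, total: int, fixed_counts: tuple[int, ...] = ()
) -> np.ndarray:
    """Integer counts for free species so the whole community's entropy ≈ ``target_h``.

    Returns counts for the free species only (zeros dropped); the caller
    appends the fixed-count categories itself. The community totals exactly
    ``total`` individuals including the fixed counts.
    """
    fixed_counts = tuple(int(c) for c in fixed_counts if c > 0)
    free_total = total - sum(fixed_counts)
    if free_total <= 0:
        return np.array([], dtype=int)
    fixed_p = np.asarray(fixed_counts, dtype=float) / total
    s = min(species_count_for(target_h), free_total)
    # grow the species pool until the even community has enough entropy
    while s < min(free_total, 300):
        q = np.concatenate([fixed_p, (1 - fixed_p.sum()) * geometric_proportions(s, 0.0)])
        if entropy(q) >= target_h:
            break
        s += 1
    p_free = proportions_for_entropy(target_h, s, fixed_p)
    counts = apportion(p_free, free_total)
    return counts[counts > 0]
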