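"""Standardization, 50/25/25 weighting and composite treatment scores.

The canonical transform chain standardizes every indicator column to z-scores
(subtract the column mean, divide by the column SD) and then min-max rescales
each column to [0, 1]. Both steps are affine and order-preserving per column,
so treatment rankings and permutation p-values on any single indicator are
identical on the raw, standardized and rescaled scales; the rescaled scale is
what composite scores are reported on.

Weighting: forage indicators jointly carry 50 % of the composite, plant
community indicators 25 % and insect community indicators 25 %, with equal
weights within a group. A treatment's composite is the weighted mean of its
twelve per-indicator means; its trade-off spread is the weighted SD of the
same twelve means — a regime is "optimal" when it maximizes the weighted
mean while minimizing the weighted SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError, MeadowTradeError
from .indicators import GROUPS, INDICATORS

_GROUP_SHARES = {"forage": 0.5, "plant": 0.25, "insect": 0.25}


@dataclass(frozen=True)
class WeightScheme:
    """Per-indicator weights grouped into forage / plant / insect.

    ``weights`` maps each indicator to ``(group, weight)``. Invariants
    (checked on construction): all weights sum to 1, group sums are
    0.5 / 0.25 / 0.25, and weights are equal within a group.
    """

    weights: Mapping[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tol = 1e-12
        total = sum(w for _, w in self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"weights sum to {total}, expected 1")
        for group, share in _GROUP_SHARES.items():
            ws = [w for g, w in self.weights.values() if g == group]
            if not ws:
                raise ConfigurationError(f"weight scheme has no {group} indicators")
            if abs(sum(ws) - share) > 1e-9:
                raise ConfigurationError(
                    f"{group} weights sum to {sum(ws)}, expected {share}"
                )
            if max(ws) - min(ws) > tol:
                raise ConfigurationError(f"{group} weights are not equal within the group")

    @property
    def indicators(self) -> list[str]:
        return list(self.weights)

    def vector(self, order: list[str] | tuple[str, ...] = INDICATORS) -> np.ndarray:
        """Weights as an array aligned with ``order``."""
        missing = set(order) - set(self.weights)
        if missing:
            raise ConfigurationError(f"weight scheme missing indicators {sorted(missing)}")
        return np.array([self.weights[k][1] for k in order], dtype=float)

    def group_of(self, indicator: str) -> str:
        return self.weights[indicator][0]

    def to_yaml(self, path) -> None:
        data = {k: {"group": g, "weight": float(w)} for k, (g, w) in self.weights.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WeightScheme":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({k: (v["group"], float(v["weight"])) for k, v in data.items()})


def default_weights() -> WeightScheme:
    """The 50/25/25 scheme with equal weights inside each group.

    Four forage indicators at 0.125 each, three plant indicators at 1/12
    each, five insect indicators at 0.05 each.
    """
    weights: dict[str, tuple[str, float]] = {}
    for group, members in GROUPS.items():
        share = _GROUP_SHARES[group] / len(members)
        for m in members:
            weights[m] = (group, share)
    return WeightScheme({k: weights[k] for k in INDICATORS})


def _indicator_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in INDICATORS if c in matrix.columns]


def zscore_columns(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each indicator column to mean 0, SD 1.

    ``ddof=1`` (sample SD) by convention. Metadata columns pass through
    unchanged; a zero-variance column raises an error naming the indicator.
    """
    out = matrix.copy()
    for col in _indicator_columns(matrix):
        x = out[col].astype(float)
        sd = x.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise DomainError(f"zscore_columns: indicator {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out


def minmax_rescale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each indicator column linearly onto [0, 1]."""
    out = matrix.copy()
    for col in _indicator_columns(matrix):
        x = out[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise DomainError(f"minmax_rescale: indicator {col!r} is degenerate (max <= min)")
        out[col] = (x - lo) / (hi - lo)
    return out


def standardize_and_rescale(matrix: pd.DataFrame) -> pd.DataFrame:
    """The canonical transform chain: z-score, then min-max to [0, 1]."""
    return minmax_rescale(zscore_columns(matrix))


def _aligned(values: pd.Series | Mapping[str, float], scheme: WeightScheme) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(values, pd.Series):
        values = pd.Series(values)
    if set(values.index) != set(scheme.indicators):
        raise MeadowTradeError(
            "weighted statistic: value labels do not match the weight scheme "
            f"(extra {sorted(set(values.index) - set(scheme.indicators))}, "
            f"missing {sorted(set(scheme.indicators) - set(values.index))})"
        )
    order = list(values.index)
    return values.to_numpy(dtype=float), scheme.vector(order)


def weighted_mean(values: pd.Series | Mapping[str, float], scheme: WeightScheme) -> float:
    """Weighted mean ``sum(w_i x_i)`` with weights summing to 1."""
    x, w = _aligned(values, scheme)
    return float(x @ w)


def weighted_sd(
    values: pd.Series | Mapping[str, float],
    scheme: WeightScheme,
    unbiased: bool = False,
) -> float:
    """Weighted standard deviation around the weighted mean.

    Default is the population form ``sqrt(sum(w_i (x_i - xbar_w)^2))`` with
    weights summing to 1; ``unbiased=True`` applies the reliability-weights
    correction ``1 / (1 - sum(w_i^2))``.
    """
    x, w = _aligned(values, scheme)
    mu = x @ w
    var = float(w @ (x - mu) ** 2)
    if unbiased:
        denom = 1.0 - float(w @ w)
        if denom <= 0:
            raise DomainError("weighted_sd: unbiased correction undefined for these weights")
        var /= denom
    return float(np.sqrt(var))


def treatment_indicator_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean of every indicator (treatments x indicators)."""
    cols = _indicator_columns(matrix)
    return matrix.groupby("treatment", sort=False)[cols].mean()


def treatment_composites(
    matrix: pd.DataFrame,
    scheme: WeightScheme | None = None,
    method: str = "treatment_means",
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Composite weighted mean, weighted SD and group means per treatment.

    Parameters
    ----------
    matrix
        Indicator matrix on the rescaled [0, 1] scale
        (:func:`standardize_and_rescale`).
    scheme
        Weight scheme; defaults to the 50/25/25 scheme.
    method
        ``"treatment_means"`` (default): the composite is computed over the
        treatment's twelve per-indicator means. ``"plot_composites"``:
        per-plot composites are computed first and averaged per treatment
        (the weighted SD is then also averaged over plots).
    treatments
        Treatments that must be present; any listed treatment with no plots
        raises an error. Defaults to the treatments found in the matrix.

    Returns
    -------
    pandas.DataFrame
        Indexed by treatment with columns ``weighted_mean, weighted_sd,
        group_mean_forage, group_mean_plant, group_mean_insect``.
    """
    scheme = scheme or default_weights()
    if treatments is None:
        treatments = list(dict.fromkeys(matrix["treatment"]))
    counts = matrix["treatment"].value_counts()
    empty = [t for t in treatments if counts.get(t, 0) == 0]
    if empty:
        raise MeadowTradeError(f"treatment_composites: treatments with no plots: {empty}")
    if method not in ("treatment_means", "plot_composites"):
        raise MeadowTradeError(f"unknown composite method {method!r}")

    cols = _indicator_columns(matrix)
    rows = {}
    for t in treatments:
        sub = matrix[matrix["treatment"] == t]
        if method == "treatment_means":
            means = sub[cols].mean()
            wm = weighted_mean(means, scheme)
            wsd = weighted_sd(means, scheme)
        else:
            wm = float(np.mean([weighted_mean(r[cols], scheme) for _, r in sub.iterrows()]))
            wsd = float(np.mean([weighted_sd(r[cols], scheme) for _, r in sub.iterrows()]))
        row = {"weighted_mean": wm, "weighted_sd": wsd}
        for group, members in GROUPS.items():
            row[f"group_mean_{group}"] = float(sub[list(members)].mean(axis=0).mean())
        rows[t] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "treatment"
    return out
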