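"""Fertilizer nutrient-load accounting and livestock feed budgets.

Nutrient loads: a regime combines farmyard manure (rate in t/ha/yr with a
per-tonne N / P2O5 / K2O composition, of which only a fraction — 20 % by
default — becomes plant-available after application) and mineral fertilizer
(kg/ha/yr applied directly, fully available). Totals and available amounts
are reported per nutrient in kg/ha/yr.

Feed budgets: plot dry-matter yields (g/m^2) extrapolate to kg DM/ha
(x 10), and the number of animals supportable per hectare over a feeding
period is ``floor(yield x utilization / (allowance x days))``. Daily
allowances (e.g. 9.2 kg DM/d for a 600 kg spring-calving suckler cow,
1.4 kg DM/d for mixed-age ewes) and nutrient-adequacy thresholds are
caller-supplied parameters, never built-in biology; the feeding-period
length in particular has no default and must be chosen explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import MeadowTradeError


@dataclass(frozen=True)
class FertilizerRegime:
    """One fertilizer treatment's inputs.

    ``manure_composition`` gives kg of N, P2O5 (phosphate) and K2O (potash)
    per tonne of manure; mineral inputs are in kg/ha/yr.
    """

    name: str
    manure_rate: float = 0.0  # t/ha/yr
    manure_composition: dict[str, float] = field(
        default_factory=lambda: {"N": 0.0, "P2O5": 0.0, "K2O": 0.0}
    )
    mineral_N: float = 0.0
    mineral_P2O5: float = 0.0
    mineral_K2O: float = 0.0
    plant_availability_fraction: float = 0.20

    def __post_init__(self) -> None:
        rates = [self.manure_rate, self.mineral_N, self.mineral_P2O5, self.mineral_K2O,
                 *self.manure_composition.values()]
        if any(r < 0 for r in rates):
            raise MeadowTradeError(f"regime {self.name!r}: rates must be non-negative")
        if not (0.0 <= self.plant_availability_fraction <= 1.0):
            raise MeadowTradeError(
                f"regime {self.name!r}: availability fraction must lie in [0, 1]"
            )


@dataclass(frozen=True)
class NutrientLoad:
    """Total and plant-available N / P2O5 / K2O in kg/ha/yr."""

    total_N: float
    total_P2O5: float
    total_K2O: float
    available_N: float
    available_P2O5: float
    available_K2O: float


@dataclass(frozen=True)
class FeedParams:
    """Feed-budget parameters for one livestock type.

    ``allowance`` is the daily dry-matter allowance (kg DM/animal/day),
    ``feeding_days`` the length of the (winter) feeding period,
    ``utilization`` the fraction of harvested DM actually usable, and
    ``cp_requirement`` / ``me_requirement`` optional adequacy thresholds
    (% crude protein; MJ ME per kg DM).
    """

    species: str
    allowance: float
    feeding_days: int
    utilization: float = 1.0
    cp_requirement: float | None = None
    me_requirement: float | None = None

    def __post_init__(self) -> None:
        if self.allowance <= 0:
            raise MeadowTradeError("FeedParams: allowance must be positive")
        if self.feeding_days <= 0:
            raise MeadowTradeError("FeedParams: feeding_days must be positive")
        if not (0 < self.utilization <= 1):
            raise MeadowTradeError("FeedParams: utilization must lie in (0, 1]")


def nutrient_loads(regime: FertilizerRegime) -> NutrientLoad:
    """Total and available nutrient loads of a regime, kg/ha/yr per nutrient.

    total = manure_rate x per-tonne composition + mineral input;
    available = availability_fraction x manure part + full mineral part.
    """
    comp = regime.manure_composition
    manure = {k: regime.manure_rate * comp.get(k, 0.0) for k in ("N", "P2O5", "K2O")}
    mineral = {"N": regime.mineral_N, "P2O5": regime.mineral_P2O5, "K2O": regime.mineral_K2O}
    f = regime.plant_availability_fraction
    return NutrientLoad(
        total_N=manure["N"] + mineral["N"],
        total_P2O5=manure["P2O5"] + mineral["P2O5"],
        total_K2O=manure["K2O"] + mineral["K2O"],
        available_N=f * manure["N"] + mineral["N"],
        available_P2O5=f * manure["P2O5"] + mineral["P2O5"],
        available_K2O=f * manure["K2O"] + mineral["K2O"],
    )


def standard_regimes() -> dict[str, FertilizerRegime]:
    """The four trial regimes: no fertilizer; 12 t/ha/yr manure with
    6 / 3.5 / 8 kg of N / P2O5 / K2O per tonne (20 % plant-available);
    20:10:10 mineral fertilizer at 25 / 12.5 / 12.5 kg/ha/yr; and both."""
    manure_comp = {"N": 6.0, "P2O5": 3.5, "K2O": 8.0}
    return {
        "NoFert": FertilizerRegime(name="NoFert"),
        "FYM": FertilizerRegime(name="FYM", manure_rate=12.0, manure_composition=manure_comp),
        "NPK": FertilizerRegime(
            name="NPK", mineral_N=25.0, mineral_P2O5=12.5, mineral_K2O=12.5
        ),
        "FYM+NPK": FertilizerRegime(
            name="FYM+NPK", manure_rate=12.0, manure_composition=manure_comp,
            mineral_N=25.0, mineral_P2O5=12.5, mineral_K2O=12.5,
        ),
    }


def plot_to_hectare(yield_g_per_m2: float) -> float:
    """Convert a plot yield in g DM/m^2 to kg DM/ha (x 10)."""
    if yield_g_per_m2 < 0:
        raise MeadowTradeError("plot_to_hectare: yield must be non-negative")
    return yield_g_per_m2 * 10.0


def hectare_to_plot(yield_kg_per_ha: float) -> float:
    """Inverse of :func:`plot_to_hectare`."""
    if yield_kg_per_ha < 0:
        raise MeadowTradeError("hectare_to_plot: yield must be non-negative")
    return yield_kg_per_ha / 10.0


def animals_supported(yield_kg_dm_per_ha: float, params: FeedParams) -> int:
    """Whole animals supportable per hectare over the feeding period.

    ``floor(yield x utilization / (allowance x feeding_days))`` — a fraction
    of an animal cannot be fed. The exact quotient is available via
    :func:`animals_supported_exact`.
    """
    if yield_kg_dm_per_ha < 0:
        raise MeadowTradeError("animals_supported: yield must be non-negative")
    return int(math.floor(animals_supported_exact(yield_kg_dm_per_ha, params)))


def animals_supported_exact(yield_kg_dm_per_ha: float, params: FeedParams) -> float:
    """Exact (fractional) animals per hectare before rounding down."""
    return yield_kg_dm_per_ha * params.utilization / (params.allowance * params.feeding_days)


def adequacy_check(
    cp_percent: float | None,
    me_mj_per_kg: float | None,
    params: FeedParams,
) -> dict[str, bool]:
    """Nutrient-adequacy flags for forage against the parameters' thresholds.

    Returns ``{"cp_adequate": ..., "me_adequate": ...}`` for whichever
    thresholds are configured (>= convention at the boundary). Requesting a
    flag whose threshold is missing is an error, never a silent pass.
    """
    flags: dict[str, bool] = {}
    if cp_percent is not None:
        if params.cp_requirement is None:
            raise MeadowTradeError(
                f"adequacy_check: no crude-protein threshold configured for {params.species!r}"
            )
        flags["cp_adequate"] = cp_percent >= params.cp_requirement
    if me_mj_per_kg is not None:
        if params.me_requirement is None:
            raise MeadowTradeError(
                f"adequacy_check: no metabolizable-energy threshold configured for {params.species!r}"
            )
        flags["me_adequate"] = me_mj_per_kg >= params.me_requirement
    return flags


def feed_budget_table(
    matrix: pd.DataFrame, params_list: list[FeedParams]
) -> pd.DataFrame:
    """Per-treatment, per-livestock feed budgets from an indicator matrix.

    Uses each treatment's mean dry-matter yield (g/m^2, extrapolated to
    kg DM/ha) and mean crude protein / metabolizable energy for adequacy
    flags (only for thresholds configured on the ``FeedParams``).
    """
    needed = {"treatment", "mean_dry_matter", "crude_protein", "metabolizable_energy"}
    missing = needed - set(matrix.columns)
    if missing:
        raise MeadowTradeError(f"feed_budget_table: matrix missing columns {sorted(missing)}")
    means = matrix.groupby("treatment", sort=False)[
        ["mean_dry_matter", "crude_protein", "metabolizable_energy"]
    ].mean()
    rows = []
    for treatment, rec in means.iterrows():
        yield_ha = plot_to_hectare(float(rec["mean_dry_matter"]))
        for p in params_list:
            row = {
                "treatment": treatment,
                "species": p.species,
                "yield_kg_dm_ha": yield_ha,
                "animals_per_ha": animals_supported(yield_ha, p),
                "animals_per_ha_exact": animals_supported_exact(yield_ha, p),
                "feeding_days": p.feeding_days,
            }
            flags = adequacy_check(
                float(rec["crude_protein"]) if p.cp_requirement is not None else None,
                float(rec["metabolizable_energy"]) if p.me_requirement is not None else None,
                p,
            )
            row["cp_adequate"] = flags.get("cp_adequate")
            row["me_adequate"] = flags.get("me_adequate")
            rows.append(row)
    return pd.DataFrame(rows)
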