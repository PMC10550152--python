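"""The twelve plot-level indicators and the plots x indicators matrix.

The analysis scores each plot of a blocked fertilizer experiment on twelve
indicators spanning three groups:

* plant community — Shannon diversity of plants (from percent cover), forb
  species richness, and nectar productivity (flower counts x per-flower
  nectar volumes from a literature reference table);
* insect community — bumblebee abundance, Shannon diversity of pollinators,
  leaf-mining herbivores and their parasitoids (from rearing records), and
  percent parasitism;
* forage — ash content, crude protein, ruminant metabolizable energy
  (all % or MJ/kg of dry matter) and mean annual dry-matter yield (g/m^2).

:func:`assemble_indicator_matrix` turns the raw plot tables (schemas in
:mod:`meadowtrade.io`) into a tidy plots x 12 matrix carrying block and
treatment labels, the single in-memory container every downstream stage
(composite scoring, randomization inference, feed budgeting) consumes.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, MeadowTradeError

logger = logging.getLogger(__name__)

#: Canonical indicator column order of the indicator matrix.
INDICATORS: tuple[str, ...] = (
    "diversity_plants",
    "forb_richness",
    "nectar_productivity",
    "bumblebee_abundance",
    "diversity_herbivores",
    "diversity_parasitoids",
    "diversity_pollinators",
    "percent_parasitism",
    "ash",
    "crude_protein",
    "metabolizable_energy",
    "mean_dry_matter",
)

#: Indicator group membership used for weighting and group-average tests.
GROUPS: dict[str, tuple[str, ...]] = {
    "forage": ("ash", "crude_protein", "metabolizable_energy", "mean_dry_matter"),
    "plant": ("diversity_plants", "forb_richness", "nectar_productivity"),
    "insect": (
        "bumblebee_abundance",
        "diversity_herbivores",
        "diversity_parasitoids",
        "diversity_pollinators",
        "percent_parasitism",
    ),
}

#: Non-indicator metadata columns of the indicator matrix.
META_COLUMNS: tuple[str, ...] = ("plot", "block", "treatment")


def shannon_index(abundances: Iterable[float]) -> float:
    """Shannon–Weiner diversity index in nats.

    Parameters
    ----------
    abundances
        Non-negative abundances (counts or percent cover). Zeros are ignored.

    Returns
    -------
    float
        ``H = -sum(p_i * ln(p_i))`` with ``p_i = a_i / sum(a)``; lies in
        ``[0, ln S]`` for ``S`` species with positive abundance.

    Raises
    ------
    DomainError
        If the vector is empty, all zero, or contains negative entries.
    """
    a = np.asarray(list(abundances), dtype=float)
    if a.size and np.any(a < 0):
        raise DomainError("shannon_index: abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise DomainError("shannon_index: needs at least one positive abundance")
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def forb_richness(plant_records: pd.DataFrame) -> int:
    """Number of distinct forb species with positive cover in one plot.

    ``plant_records`` needs columns ``species``, ``percent_cover`` and
    ``is_forb``; an empty table yields 0 and duplicate cover records for one
    species count once.
    """
    if len(plant_records) == 0:
        return 0
    forbs = plant_records[
        plant_records["is_forb"].astype(bool) & (plant_records["percent_cover"] > 0)
    ]
    return int(forbs["species"].nunique())


def nectar_productivity(
    flower_counts: Mapping[str, float] | pd.DataFrame,
    reference: Mapping[str, float] | pd.DataFrame,
    on_missing: str = "error",
) -> float:
    """Total nectar supply of a plot in microlitres.

    Each species' flower count is multiplied by its per-flower nectar volume
    (from a literature reference table) and the products are summed.

    Parameters
    ----------
    flower_counts
        ``species -> number of flowers`` for one plot, or a DataFrame with
        ``species`` and ``flowers`` columns.
    reference
        ``species -> microlitres of nectar per flower``, or a DataFrame with
        ``species`` and ``ul_per_flower`` columns.
    on_missing
        ``"error"`` (default) raises :class:`DomainError` for a flower species
        absent from the reference; ``"skip"`` drops it with a warning. The
        permissive mode exists for exploratory use only — silently treating
        missing species as zero would bias the indicator downward.
    """
    if isinstance(flower_counts, pd.DataFrame):
        flower_counts = dict(
            zip(flower_counts["species"], flower_counts["flowers"].astype(float))
        )
    if isinstance(reference, pd.DataFrame):
        reference = dict(zip(reference["species"], reference["ul_per_flower"]))
    if on_missing not in ("error", "skip"):
        raise MeadowTradeError(f"unknown on_missing policy {on_missing!r}")
    total = 0.0
    for species, flowers in flower_counts.items():
        if flowers < 0:
            raise DomainError(f"nectar_productivity: negative flower count for {species!r}")
        if species not in reference:
            if on_missing == "error":
                raise DomainError(
                    f"nectar_productivity: species {species!r} missing from nectar reference"
                )
            logger.warning("nectar reference missing species %r; skipped", species)
            continue
        total += float(flowers) * float(reference[species])
    return total


def percent_parasitism(
    outcomes: pd.DataFrame, denominator: str = "total_emergences"
) -> float:
    """Percentage of rearing emergences that were parasitoids.

    Leaf miners are reared individually until either an adult miner or a
    parasitoid emerges, so each record of ``outcomes`` is one emergence with
    ``outcome`` in ``{"miner_adult", "parasitoid"}``.

    ``denominator`` selects what the parasitoid count is divided by:
    ``"total_emergences"`` (default; all emergences, giving a value in
    [0, 100]) or ``"miner_adults_only"`` (can exceed 100). Both conventions
    appear in the literature, so the choice is explicit rather than implied.

    Raises
    ------
    DomainError
        If there are no emergences (the indicator is undefined — distinct
        from an observed 0 %) or the chosen denominator is zero.
    """
    if len(outcomes) == 0:
        raise DomainError("percent_parasitism: no emergences; indicator undefined")
    counts = outcomes["outcome"].value_counts()
    bad = set(counts.index) - {"miner_adult", "parasitoid"}
    if bad:
        raise DomainError(f"percent_parasitism: unknown outcome labels {sorted(bad)}")
    n_para = int(counts.get("parasitoid", 0))
    n_miner = int(counts.get("miner_adult", 0))
    if denominator == "total_emergences":
        denom = n_para + n_miner
    elif denominator == "miner_adults_only":
        denom = n_miner
    else:
        raise MeadowTradeError(f"unknown parasitism denominator {denominator!r}")
    if denom == 0:
        raise DomainError("percent_parasitism: zero denominator; indicator undefined")
    return 100.0 * n_para / denom


def bumblebee_abundance(pollinator_records: pd.DataFrame) -> int:
    """Total bumblebee observations in one plot (rows flagged ``is_bumblebee``)."""
    if len(pollinator_records) == 0:
        return 0
    bb = pollinator_records[pollinator_records["is_bumblebee"].astype(bool)]
    return int(bb["count"].sum())


def mean_dry_matter(yearly_yields: Mapping[int, float], expected_years: int | None = None) -> float:
    """Arithmetic mean dry-matter yield (g/m^2) over the available years.

    Missing years are never imputed; if ``expected_years`` is given and fewer
    years are present, a warning is logged and the mean is taken over what is
    there. An empty map raises :class:`DomainError`.
    """
    if len(yearly_yields) == 0:
        raise DomainError("mean_dry_matter: no yearly yields provided")
    if expected_years is not None and len(yearly_yields) < expected_years:
        logger.warning(
            "mean_dry_matter: only %d of %d expected years present; mean over available years",
            len(yearly_yields),
            expected_years,
        )
    return float(np.mean(list(yearly_yields.values())))


def assemble_indicator_matrix(
    tables: Mapping[str, pd.DataFrame],
    parasitism_denominator: str = "total_emergences",
    nectar_policy: str = "error",
) -> pd.DataFrame:
    """Build the plots x 12 indicator matrix from the raw plot tables.

    Parameters
    ----------
    tables
        Dict with keys ``plots``, ``plant_community``, ``pollinators``,
        ``rearing``, ``flowers``, ``nectar_ref``, ``forage`` (schemas in
        :mod:`meadowtrade.io`). Every plot in the ``plots`` registry must be
        resolvable in every indicator's source table; a plot legitimately
        without flowers contributes 0 nectar, but a plot with no plant,
        pollinator, rearing or forage records makes the corresponding
        indicator undefined and raises an error naming plot and indicator.

    Returns
    -------
    pandas.DataFrame
        One row per plot with columns ``plot, block, treatment`` followed by
        the twelve indicators in canonical order. No missing cells.
    """
    required = {"plots", "plant_community", "pollinators", "rearing", "flowers",
                "nectar_ref", "forage"}
    missing = required - set(tables)
    if missing:
        raise MeadowTradeError(f"assemble_indicator_matrix: missing tables {sorted(missing)}")

    plots = tables["plots"]
    ref = tables["nectar_ref"]
    rows = []
    for rec in plots.itertuples(index=False):
        plot = rec.plot
        row: dict[str, object] = {"plot": plot, "block": rec.block, "treatment": rec.treatment}

        plant = tables["plant_community"][tables["plant_community"]["plot"] == plot]
        if len(plant) == 0:
            raise MeadowTradeError(
                f"plot {plot!r}: no plant community records (diversity_plants undefined)"
            )
        row["diversity_plants"] = shannon_index(plant["percent_cover"])
        row["forb_richness"] = forb_richness(plant)

        flowers = tables["flowers"][tables["flowers"]["plot"] == plot]
        row["nectar_productivity"] = nectar_productivity(flowers, ref, on_missing=nectar_policy)

        poll = tables["pollinators"][tables["pollinators"]["plot"] == plot]
        if len(poll) == 0:
            raise MeadowTradeError(
                f"plot {plot!r}: no pollinator records (diversity_pollinators undefined)"
            )
        row["bumblebee_abundance"] = bumblebee_abundance(poll)
        row["diversity_pollinators"] = shannon_index(
            poll.groupby("species")["count"].sum()
        )

        rearing = tables["rearing"][tables["rearing"]["plot"] == plot]
        if len(rearing) == 0:
            raise MeadowTradeError(
                f"plot {plot!r}: no rearing records (percent_parasitism undefined)"
            )
        row["percent_parasitism"] = percent_parasitism(
            rearing, denominator=parasitism_denominator
        )
        miners = rearing[rearing["outcome"] == "miner_adult"]
        paras = rearing[rearing["outcome"] == "parasitoid"]
        for name, sub in (("diversity_herbivores", miners), ("diversity_parasitoids", paras)):
            if len(sub) == 0:
                raise MeadowTradeError(f"plot {plot!r}: no emergences for {name}")
            row[name] = shannon_index(sub.groupby("species").size())

        forage = tables["forage"][tables["forage"]["plot"] == plot]
        if len(forage) == 0:
            raise MeadowTradeError(f"plot {plot!r}: no forage assays (forage indicators undefined)")
        row["ash"] = float(forage["ash"].mean())
        row["crude_protein"] = float(forage["crude_protein"].mean())
        row["metabolizable_energy"] = float(forage["me"].mean())
        row["mean_dry_matter"] = mean_dry_matter(
            dict(zip(forage["year"], forage["dm_g_m2"]))
        )
        rows.append(row)

    matrix = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(INDICATORS))
    return matrix


def correlation_screen(matrix: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """Flag indicator pairs whose absolute Pearson correlation meets ``threshold``.

    The composite analysis treats the indicators as (sufficiently)
    independent signals; this screen flags unordered pairs with
    ``|r| >= threshold`` (default 0.90). An empty result means the matrix
    passes. Constant columns have undefined correlations; their pairs are
    skipped with a warning.
    """
    if len(matrix) < 3:
        raise DomainError("correlation_screen: need at least 3 rows")
    cols = [c for c in INDICATORS if c in matrix.columns]
    values = matrix[cols].astype(float)
    constant = [c for c in cols if values[c].std() == 0]
    for c in constant:
        logger.warning("correlation_screen: column %r is constant; its pairs are skipped", c)
    usable = [c for c in cols if c not in constant]
    out = []
    corr = values[usable].corr()
    for a, b in itertools.combinations(usable, 2):
        r = float(corr.loc[a, b])
        if abs(r) >= threshold:
            out.append({"indicator_a": a, "indicator_b": b, "pearson_r": r})
    return pd.DataFrame(out, columns=["indicator_a", "indicator_b", "pearson_r"])
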