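"""Synthetic plot-level data with the blocked fertilizer-trial structure.

Generates raw plot tables (plant covers, pollinator counts, rearing outcomes,
flower counts with a nectar reference, forage assays) for a randomized block
design — by default 3 blocks x 4 treatments x 2 replicates = 24 plots under
no-fertilizer, farmyard manure (FYM), mineral NPK and FYM+NPK — with known
ground truth, so the whole analysis pipeline is testable without field data.

The generative model is "indicator first": each plot's target value for each
of the twelve indicators is

    target = baseline + treatment_effect + block_effect + residual

with additive Gaussian block effects (SD ``block_sd`` per indicator, shared
within a block) and residual noise (SD ``residual_sd``), truncated to each
indicator's physical range. Raw tables are then constructed to realize those
targets: Shannon targets via geometric rank-abundance communities solved by
bisection (:mod:`meadowtrade._communities`), count-valued indicators by
rounding, continuous assays directly. Count data forces quantization, so the
dataset stores both the intended targets and the *realized* indicator values
(recomputed from the final tables); with all noise at zero the realized
matrix is constant within treatment and downstream assembly reproduces it
exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _communities as comm
from .errors import ConfigurationError
from .indicators import INDICATORS, assemble_indicator_matrix

DEFAULT_TREATMENTS: tuple[str, ...] = ("NoFert", "FYM", "NPK", "FYM+NPK")

#: Indicators realized as integer counts (quantized by rounding).
INTEGER_INDICATORS = frozenset({"forb_richness", "bumblebee_abundance"})

#: Physical truncation bounds applied to indicator targets.
BOUNDS: dict[str, tuple[float, float]] = {
    "diversity_plants": (0.0, math.inf),
    "forb_richness": (0.0, math.inf),
    "nectar_productivity": (0.0, math.inf),
    "bumblebee_abundance": (0.0, math.inf),
    "diversity_herbivores": (0.0, math.inf),
    "diversity_parasitoids": (0.0, math.inf),
    "diversity_pollinators": (0.0, math.inf),
    "percent_parasitism": (0.0, 100.0),
    "ash": (0.0, 100.0),
    "crude_protein": (0.0, 100.0),
    "metabolizable_energy": (0.0, math.inf),
    "mean_dry_matter": (0.0, math.inf),
}

_DM_YEAR_PATTERN = {2011: 0.94, 2012: 1.02, 2013: 1.04, 2014: 1.00}  # mean-preserving

#: Synthetic flower species used to realize nectar targets (coarse + fine unit).
NECTAR_REFERENCE = {"flor_major": 1.0, "flor_minor": 0.01}


@dataclass(frozen=True)
class DesignSpec:
    """Blocked experimental layout: ``n_blocks x |treatments| x reps`` plots."""

    n_blocks: int = 3
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    reps_per_block_per_treatment: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.reps_per_block_per_treatment < 1:
            raise ConfigurationError("DesignSpec: block and replicate counts must be positive")
        if len(self.treatments) < 2:
            raise ConfigurationError("DesignSpec: need at least two treatments")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigurationError("DesignSpec: duplicate treatment labels")
        if self.seed < 0:
            raise ConfigurationError("DesignSpec: seed must be non-negative")

    @property
    def n_plots(self) -> int:
        return self.n_blocks * len(self.treatments) * self.reps_per_block_per_treatment

    def plot_registry(self) -> pd.DataFrame:
        """Plot ids with block and treatment labels; every block holds every
        treatment exactly ``reps_per_block_per_treatment`` times."""
        rows = []
        i = 1
        for b in range(1, self.n_blocks + 1):
            for t in self.treatments:
                for _ in range(self.reps_per_block_per_treatment):
                    rows.append({"plot": f"p{i:02d}", "block": f"B{b}", "treatment": t})
                    i += 1
        return pd.DataFrame(rows)


def _default_effect_table() -> dict[str, dict[str, float]]:
    # Additive shifts relative to the unfertilized baseline, in each
    # indicator's natural units. Signs follow the qualitative pattern of
    # long-term nutrient addition in hay meadows: fertilization boosts yield
    # and forage nitrogen while eroding forbs, nectar and bumblebees, with
    # the combined FYM+NPK regime hitting the plant community hardest.
    return {
        "NoFert": {k: 0.0 for k in INDICATORS},
        "FYM": {
            "diversity_plants": -0.10, "forb_richness": -2.0,
            "nectar_productivity": -600.0, "bumblebee_abundance": -0.5,
            "diversity_herbivores": 0.10, "diversity_parasitoids": 0.10,
            "diversity_pollinators": -0.05, "percent_parasitism": 8.0,
            "ash": 0.2, "crude_protein": 2.5,
            "metabolizable_energy": 0.6, "mean_dry_matter": 130.0,
        },
        "NPK": {
            "diversity_plants": -0.05, "forb_richness": -1.0,
            "nectar_productivity": -400.0, "bumblebee_abundance": -1.0,
            "diversity_herbivores": 0.05, "diversity_parasitoids": 0.05,
            "diversity_pollinators": -0.05, "percent_parasitism": -2.0,
            "ash": 0.1, "crude_protein": 1.5,
            "metabolizable_energy": 0.2, "mean_dry_matter": 90.0,
        },
        "FYM+NPK": {
            "diversity_plants": -0.25, "forb_richness": -5.0,
            "nectar_productivity": -2000.0, "bumblebee_abundance": -1.8,
            "diversity_herbivores": 0.10, "diversity_parasitoids": 0.10,
            "diversity_pollinators": -0.10, "percent_parasitism": 4.0,
            "ash": 0.3, "crude_protein": 3.0,
            "metabolizable_energy": 0.5, "mean_dry_matter": 160.0,
        },
    }


_DEFAULT_BASELINE = {
    "diversity_plants": 2.2, "forb_richness": 12.0, "nectar_productivity": 3000.0,
    "bumblebee_abundance": 2.0, "diversity_herbivores": 1.8,
    "diversity_parasitoids": 1.5, "diversity_pollinators": 2.0,
    "percent_parasitism": 20.0, "ash": 7.5, "crude_protein": 8.0,
    "metabolizable_energy": 8.2, "mean_dry_matter": 300.0,
}

_DEFAULT_BLOCK_SD = {
    "diversity_plants": 0.08, "forb_richness": 1.0, "nectar_productivity": 250.0,
    "bumblebee_abundance": 0.3, "diversity_herbivores": 0.08,
    "diversity_parasitoids": 0.08, "diversity_pollinators": 0.08,
    "percent_parasitism": 2.0, "ash": 0.2, "crude_protein": 0.3,
    "metabolizable_energy": 0.1, "mean_dry_matter": 15.0,
}

_DEFAULT_RESIDUAL_SD = {
    "diversity_plants": 0.15, "forb_richness": 1.5, "nectar_productivity": 500.0,
    "bumblebee_abundance": 0.7, "diversity_herbivores": 0.20,
    "diversity_parasitoids": 0.20, "diversity_pollinators": 0.20,
    "percent_parasitism": 4.0, "ash": 0.5, "crude_protein": 0.8,
    "metabolizable_energy": 0.25, "mean_dry_matter": 30.0,
}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect model: baseline + treatment shifts + block/residual SDs."""

    baseline: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    treatment_effect: dict[str, dict[str, float]] = field(default_factory=_default_effect_table)
    block_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BLOCK_SD))
    residual_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RESIDUAL_SD))
    indicator_names: tuple[str, ...] = INDICATORS

    def __post_init__(self) -> None:
        names = set(self.indicator_names)
        for label, mapping in (
            ("baseline", self.baseline),
            ("block_sd", self.block_sd),
            ("residual_sd", self.residual_sd),
        ):
            if set(mapping) != names:
                raise ConfigurationError(f"EffectSpec: {label} keys do not match indicators")
        for sd_map in (self.block_sd, self.residual_sd):
            if any(v < 0 for v in sd_map.values()):
                raise ConfigurationError("EffectSpec: standard deviations must be >= 0")
        for t, eff in self.treatment_effect.items():
            if set(eff) != names:
                raise ConfigurationError(
                    f"EffectSpec: treatment {t!r} effects do not cover all indicators"
                )

    def validate_against(self, design: DesignSpec) -> None:
        if set(self.treatment_effect) != set(design.treatments):
            raise ConfigurationError(
                "EffectSpec treatments do not match DesignSpec: "
                f"{sorted(self.treatment_effect)} vs {sorted(design.treatments)}"
            )

    # -- convenience constructors used by calibration / power studies -------

    def zero_treatment_effects(self) -> "EffectSpec":
        """Same noise structure, all treatment effects zero (exchangeable data)."""
        zeros = {t: {k: 0.0 for k in self.indicator_names} for t in self.treatment_effect}
        return dataclasses.replace(self, treatment_effect=zeros)

    def noise_free(self) -> "EffectSpec":
        """Same means, block and residual SDs all zero."""
        z = {k: 0.0 for k in self.indicator_names}
        return dataclasses.replace(self, block_sd=dict(z), residual_sd=dict(z))

    def with_effect(self, treatment: str, shifts: dict[str, float]) -> "EffectSpec":
        """Copy with the given treatment's shifts overridden for some indicators."""
        if treatment not in self.treatment_effect:
            raise ConfigurationError(f"unknown treatment {treatment!r}")
        eff = {t: dict(m) for t, m in self.treatment_effect.items()}
        eff[treatment].update(shifts)
        return dataclasses.replace(self, treatment_effect=eff)

    def to_dict(self) -> dict:
        return {
            "baseline": dict(self.baseline),
            "treatment_effect": {t: dict(m) for t, m in self.treatment_effect.items()},
            "block_sd": dict(self.block_sd),
            "residual_sd": dict(self.residual_sd),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EffectSpec":
        return cls(
            baseline=dict(data["baseline"]),
            treatment_effect={t: dict(m) for t, m in data["treatment_effect"].items()},
            block_sd=dict(data["block_sd"]),
            residual_sd=dict(data["residual_sd"]),
        )


@dataclass
class SyntheticDataset:
    """Raw plot tables plus the ground truth that generated them.

    ``truth_targets`` holds the intended indicator values (baseline +
    treatment + block + residual, truncated); ``truth_indicators`` holds the
    values actually realized by the constructed tables (identical up to count
    quantization), which is what tests compare against.
    """

    design: DesignSpec
    effects: EffectSpec
    plots: pd.DataFrame
    plant_community: pd.DataFrame
    pollinator_records: pd.DataFrame
    rearing_outcomes: pd.DataFrame
    flower_counts: pd.DataFrame
    nectar_reference: pd.DataFrame
    forage_assays: pd.DataFrame
    truth_targets: pd.DataFrame
    truth_indicators: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        """The seven raw tables keyed by their CSV schema names."""
        return {
            "plots": self.plots,
            "plant_community": self.plant_community,
            "pollinators": self.pollinator_records,
            "rearing": self.rearing_outcomes,
            "flowers": self.flower_counts,
            "nectar_ref": self.nectar_reference,
            "forage": self.forage_assays,
        }


def _target_matrix(design: DesignSpec, effects: EffectSpec, rng: np.random.Generator) -> pd.DataFrame:
    registry = design.plot_registry()
    n = len(registry)
    block_ids = sorted(registry["block"].unique())
    out = registry.copy()
    for ind in INDICATORS:
        beff = dict(zip(block_ids, rng.normal(0.0, effects.block_sd[ind], len(block_ids))))
        resid = rng.normal(0.0, effects.residual_sd[ind], n)
        vals = np.array(
            [
                effects.baseline[ind]
                + effects.treatment_effect[row.treatment][ind]
                + beff[row.block]
                for row in registry.itertuples(index=False)
            ]
        ) + resid
        lo, hi = BOUNDS[ind]
        vals = np.clip(vals, lo, hi)
        if ind in INTEGER_INDICATORS:
            vals = np.round(vals)
        out[ind] = vals
    return out


def _plant_rows(plot: str, h_target: float, n_forbs: int) -> list[dict]:
    s = max(n_forbs, comm.species_count_for(h_target))
    props = comm.proportions_for_entropy(h_target, s)
    n_grass = s - n_forbs
    names = [f"grass_sp_{i:02d}" for i in range(1, n_grass + 1)] + [
        f"forb_sp_{i:02d}" for i in range(1, n_forbs + 1)
    ]
    flags = [False] * n_grass + [True] * n_forbs
    return [
        {"plot": plot, "species": sp, "percent_cover": 100.0 * p, "is_forb": fl}
        for sp, p, fl in zip(names, props, flags)
    ]


def _flower_rows(plot: str, nectar_target: float) -> list[dict]:
    coarse = int(math.floor(nectar_target))
    fine = int(round((nectar_target - coarse) / 0.01))
    if fine >= 100:
        coarse, fine = coarse + 1, 0
    rows = []
    if coarse > 0:
        rows.append({"plot": plot, "species": "flor_major", "flowers": coarse})
    if fine > 0:
        rows.append({"plot": plot, "species": "flor_minor", "flowers": fine})
    return rows


def _pollinator_rows(plot: str, h_target: float, n_bumble: int, total: int) -> list[dict]:
    total = max(total, 5 * n_bumble + 20)
    rows = []
    if n_bumble > 0:
        rows.append(
            {"plot": plot, "species": "Bombus_synth", "count": n_bumble, "is_bumblebee": True}
        )
    counts = comm.community_counts(h_target, total, fixed_counts=(n_bumble,))
    rows.extend(
        {"plot": plot, "species": f"pol_sp_{i:02d}", "count": int(c), "is_bumblebee": False}
        for i, c in enumerate(counts, start=1)
    )
    return rows


def _rearing_rows(
    plot: str, h_herb: float, h_para: float, pct_parasitism: float, total: int
) -> list[dict]:
    if total < 2:
        raise ConfigurationError(
            f"plot {plot!r}: rearing total {total} < 2 cannot hold both a miner "
            "and a parasitoid emergence"
        )
    # Truncate at the physical bound of a finite rearing sample: both
    # emergence classes need at least one individual or the corresponding
    # diversity indicator is undefined.
    n_para = int(round(total * pct_parasitism / 100.0))
    n_para = min(max(n_para, 1), total - 1)
    n_miner = total - n_para
    rows = []
    for c_i, count in enumerate(comm.community_counts(h_herb, n_miner), start=1):
        rows.extend(
            {"plot": plot, "outcome": "miner_adult", "species": f"min_sp_{c_i:02d}"}
            for _ in range(int(count))
        )
    for c_i, count in enumerate(comm.community_counts(h_para, n_para), start=1):
        rows.extend(
            {"plot": plot, "outcome": "parasitoid", "species": f"par_sp_{c_i:02d}"}
            for _ in range(int(count))
        )
    return rows


def generate_dataset(
    design: DesignSpec | None = None,
    effects: EffectSpec | None = None,
    rearing_total: int = 80,
    pollinator_total: int = 400,
) -> SyntheticDataset:
    """Generate a full synthetic dataset with known ground truth.

    Deterministic given ``design.seed``: the same (design, effects, seed)
    yields byte-identical exports. ``rearing_total`` and ``pollinator_total``
    set the per-plot number of rearing emergences and pollinator individuals,
    which bound the quantization of the parasitism and diversity targets.
    """
    design = design or DesignSpec()
    effects = effects or EffectSpec()
    effects.validate_against(design)
    rng = np.random.default_rng(design.seed)

    targets = _target_matrix(design, effects, rng)

    plant_rows: list[dict] = []
    flower_rows: list[dict] = []
    poll_rows: list[dict] = []
    rear_rows: list[dict] = []
    forage_rows: list[dict] = []
    for row in targets.itertuples(index=False):
        plant_rows.extend(_plant_rows(row.plot, row.diversity_plants, int(row.forb_richness)))
        flower_rows.extend(_flower_rows(row.plot, row.nectar_productivity))
        poll_rows.extend(
            _pollinator_rows(
                row.plot, row.diversity_pollinators, int(row.bumblebee_abundance),
                pollinator_total,
            )
        )
        rear_rows.extend(
            _rearing_rows(
                row.plot, row.diversity_herbivores, row.diversity_parasitoids,
                row.percent_parasitism, rearing_total,
            )
        )
        for year, mult in _DM_YEAR_PATTERN.items():
            forage_rows.append(
                {
                    "plot": row.plot, "year": year, "ash": row.ash,
                    "crude_protein": row.crude_protein, "me": row.metabolizable_energy,
                    "dm_g_m2": row.mean_dry_matter * mult,
                }
            )

    nectar_ref = pd.DataFrame(
        [{"species": sp, "ul_per_flower": ul} for sp, ul in NECTAR_REFERENCE.items()]
    )
    tables = {
        "plots": design.plot_registry(),
        "plant_community": pd.DataFrame(
            plant_rows, columns=["plot", "species", "percent_cover", "is_forb"]
        ),
        "pollinators": pd.DataFrame(
            poll_rows, columns=["plot", "species", "count", "is_bumblebee"]
        ),
        "rearing": pd.DataFrame(rear_rows, columns=["plot", "outcome", "species"]),
        "flowers": pd.DataFrame(flower_rows, columns=["plot", "species", "flowers"]),
        "nectar_ref": nectar_ref,
        "forage": pd.DataFrame(
            forage_rows,
            columns=["plot", "year", "ash", "crude_protein", "me", "dm_g_m2"],
        ),
    }
    realized = assemble_indicator_matrix(tables)
    return SyntheticDataset(
        design=design,
        effects=effects,
        plots=tables["plots"],
        plant_community=tables["plant_community"],
        pollinator_records=tables["pollinators"],
        rearing_outcomes=tables["rearing"],
        flower_counts=tables["flowers"],
        nectar_reference=tables["nectar_ref"],
        forage_assays=tables["forage"],
        truth_targets=targets,
        truth_indicators=realized,
    )


def export_dataset(dataset: SyntheticDataset, directory: str | Path) -> list[Path]:
    """Write the seven CSV tables plus a YAML echo of design, effects and seed.

    Round-trips losslessly through :func:`meadowtrade.io.read_tables`.
    """
    from .io import write_tables  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_tables(dataset.tables(), directory)
    echo = {
        "design": {
            "n_blocks": dataset.design.n_blocks,
            "treatments": list(dataset.design.treatments),
            "reps_per_block_per_treatment": dataset.design.reps_per_block_per_treatment,
            "seed": dataset.design.seed,
        },
        "effects": dataset.effects.to_dict(),
    }
    cfg = directory / "config.yaml"
    with open(cfg, "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
    return paths + [cfg]
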