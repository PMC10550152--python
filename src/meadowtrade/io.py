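"""CSV schemas, validated readers/writers and the run manifest.

Plot-level data travels as plain CSV with documented headers:

====================  =======================================================
file                  columns
====================  =======================================================
plots.csv             plot, block, treatment
plant_community.csv   plot, species, percent_cover, is_forb
pollinators.csv       plot, species, count, is_bumblebee
rearing.csv           plot, outcome, species
flowers.csv           plot, species, flowers
nectar_ref.csv        species, ul_per_flower
forage.csv            plot, year, ash, crude_protein, me, dm_g_m2
====================  =======================================================

Readers reject missing columns and un-coercible values with errors naming
file and column; unknown extra columns are accepted with a warning. Lines
starting with ``#`` are comments (output files carry a manifest reference
that way).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: table name -> (required columns, numeric columns, boolean columns)
SCHEMAS: dict[str, tuple[list[str], list[str], list[str]]] = {
    "plots": (["plot", "block", "treatment"], [], []),
    "plant_community": (
        ["plot", "species", "percent_cover", "is_forb"], ["percent_cover"], ["is_forb"],
    ),
    "pollinators": (
        ["plot", "species", "count", "is_bumblebee"], ["count"], ["is_bumblebee"],
    ),
    "rearing": (["plot", "outcome", "species"], [], []),
    "flowers": (["plot", "species", "flowers"], ["flowers"], []),
    "nectar_ref": (["species", "ul_per_flower"], ["ul_per_flower"], []),
    "forage": (
        ["plot", "year", "ash", "crude_protein", "me", "dm_g_m2"],
        ["year", "ash", "crude_protein", "me", "dm_g_m2"], [],
    ),
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _coerce_bool(series: pd.Series, fname: str, col: str) -> pd.Series:
    if series.dtype == bool:
        return series
    try:
        return series.astype(str).str.strip().str.lower().map(_BOOL_MAP).astype(bool)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{fname}: column {col!r} is not boolean") from exc


def read_table(path: str | Path, name: str) -> pd.DataFrame:
    """Read and validate one table against its documented schema."""
    if name not in SCHEMAS:
        raise SchemaError(f"unknown table name {name!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"missing input file {path}")
    required, numeric, boolean = SCHEMAS[name]
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path.name, extra)
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path.name}: column {col!r} is not numeric") from exc
        if df[col].isna().any():
            raise SchemaError(f"{path.name}: column {col!r} has missing values")
    for col in boolean:
        if df[col].isna().any():
            raise SchemaError(f"{path.name}: column {col!r} has missing values")
        df[col] = _coerce_bool(df[col], path.name, col)
    return df[required]


def read_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read the full table set from ``directory`` and cross-validate plot ids."""
    directory = Path(directory)
    tables = {name: read_table(directory / f"{name}.csv", name) for name in SCHEMAS}
    known = set(tables["plots"]["plot"])
    if len(known) != len(tables["plots"]):
        raise SchemaError("plots.csv: duplicate plot ids")
    for name, df in tables.items():
        if "plot" not in df.columns or name == "plots":
            continue
        unknown = set(df["plot"]) - known
        if unknown:
            raise SchemaError(
                f"{name}.csv: plot id(s) not in plots.csv: {sorted(unknown)[:5]}"
            )
        logger.info("%s.csv: %d rows", name, len(df))
    return tables


def write_tables(
    tables: dict[str, pd.DataFrame], directory: str | Path, manifest_note: str | None = None
) -> list[Path]:
    """Write tables as ``<name>.csv``; optional ``# manifest`` comment header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        if name not in SCHEMAS:
            raise SchemaError(f"unknown table name {name!r}")
        p = directory / f"{name}.csv"
        with open(p, "w") as fh:
            if manifest_note:
                fh.write(f"# {manifest_note}\n")
            df.to_csv(fh, index=False)
        paths.append(p)
    return paths


def write_matrix(matrix: pd.DataFrame, path: str | Path, manifest_note: str | None = None) -> Path:
    """Write an indicator matrix (wide form) to CSV."""
    path = Path(path)
    with open(path, "w") as fh:
        if manifest_note:
            fh.write(f"# {manifest_note}\n")
        matrix.to_csv(fh, index=False)
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide indicator matrix written by :func:`write_matrix`."""
    from .indicators import INDICATORS, META_COLUMNS

    df = pd.read_csv(path, comment="#")
    missing = [c for c in (*META_COLUMNS, *INDICATORS) if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing indicator-matrix column(s) {missing}")
    return df


def matrix_to_tidy(matrix: pd.DataFrame) -> pd.DataFrame:
    """Wide plots x indicators matrix -> tidy (plot, block, treatment, indicator, value)."""
    from .indicators import INDICATORS, META_COLUMNS

    cols = [c for c in INDICATORS if c in matrix.columns]
    return matrix.melt(
        id_vars=list(META_COLUMNS), value_vars=cols,
        var_name="indicator", value_name="value",
    )


def write_manifest(path: str | Path, seed: int, config_echo: dict, counts: dict[str, int],
                   outputs: list[str]) -> Path:
    """Run manifest: seed, package/library versions, config echo, table sizes.

    Deliberately carries no timestamps so identical runs produce identical
    manifests.
    """
    from . import __version__

    manifest = {
        "meadowtrade_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": config_echo,
        "table_rows": counts,
        "outputs": outputs,
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
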