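"""Thin adapter for an already-scored indicator workbook (XLSX).

The original study distributes its plot-level indicator values as a
supplementary spreadsheet whose internal layout is not machine-documented,
so this importer deliberately takes the column mapping from the caller
instead of guessing: you say which workbook column holds each indicator and
which hold the plot / block / treatment labels, and you get back a standard
indicator matrix ready for the composite and randomization stages. The
adapter lives outside the core pipeline; nothing else imports it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import SchemaError
from .indicators import INDICATORS, META_COLUMNS


def load_indicator_workbook(
    path: str | Path,
    column_mapping: Mapping[str, str],
    sheet: int | str = 0,
    plot_col: str = "plot",
    block_col: str = "block",
    treatment_col: str = "treatment",
    treatment_mapping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load a plots x indicators matrix from a spreadsheet.

    Parameters
    ----------
    column_mapping
        ``indicator name -> workbook column`` for all twelve indicators
        (:data:`meadowtrade.indicators.INDICATORS`).
    plot_col, block_col, treatment_col
        Workbook columns holding the plot id, block and treatment labels.
    treatment_mapping
        Optional relabelling of the workbook's treatment names onto the
        labels used downstream (e.g. ``{"control": "NoFert"}``).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"workbook not found: {path}")
    missing = set(INDICATORS) - set(column_mapping)
    if missing:
        raise SchemaError(f"column_mapping missing indicator(s) {sorted(missing)}")
    raw = pd.read_excel(path, sheet_name=sheet)
    needed = [plot_col, block_col, treatment_col, *column_mapping.values()]
    absent = [c for c in needed if c not in raw.columns]
    if absent:
        raise SchemaError(f"{path.name}: missing workbook column(s) {absent}")

    matrix = pd.DataFrame(
        {
            "plot": raw[plot_col].astype(str),
            "block": raw[block_col].astype(str),
            "treatment": raw[treatment_col].astype(str),
        }
    )
    for indicator in INDICATORS:
        col = column_mapping[indicator]
        values = pd.to_numeric(raw[col], errors="coerce")
        if values.isna().any():
            raise SchemaError(
                f"{path.name}: column {col!r} ({indicator}) has non-numeric or missing values"
            )
        matrix[indicator] = values
    if treatment_mapping:
        matrix["treatment"] = matrix["treatment"].map(
            lambda t: treatment_mapping.get(t, t)
        )
    return matrix[list(META_COLUMNS) + list(INDICATORS)]
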