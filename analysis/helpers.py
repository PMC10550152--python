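"""Shared paths and settings for the numbered analysis scripts."""

from pathlib import Path

import meadowtrade as mt

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA_DIR = RESULTS / "synthetic_dataset"


def ensure_dataset() -> dict:
    """Load the study dataset, generating and exporting it if missing."""
    if not (DATA_DIR / "plots.csv").exists():
        dataset = mt.generate_dataset(mt.DesignSpec(seed=SEED))
        mt.export_dataset(dataset, DATA_DIR)
    from meadowtrade.io import read_tables

    return read_tables(DATA_DIR)
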