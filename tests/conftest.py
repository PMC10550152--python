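import numpy as np
import pandas as pd
import pytest

import meadowtrade as mt


@pytest.fixture(scope="session")
def default_dataset() -> mt.SyntheticDataset:
    """24-plot synthetic dataset under the default effect model, seed 0."""
    return mt.generate_dataset(mt.DesignSpec(seed=0))


@pytest.fixture(scope="session")
def default_matrix(default_dataset) -> pd.DataFrame:
    return mt.assemble_indicator_matrix(default_dataset.tables())


@pytest.fixture()
def tiny_matrix() -> pd.DataFrame:
    """2 blocks x 2 treatments x 2 reps with one continuous indicator."""
    rng = np.random.default_rng(5)
    reg = mt.DesignSpec(
        n_blocks=2, treatments=("A", "B"), reps_per_block_per_treatment=2, seed=1
    ).plot_registry()
    reg["diversity_plants"] = rng.normal(size=len(reg))
    return reg
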