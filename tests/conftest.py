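import numpy as np
import pytest

from formucomet.encoders import FormulationTokenizer
from formucomet.formulation import Formulation
from formucomet.grids import campaign_grid
from formucomet.model import CometConfig, CometModel
from formucomet.synthetic import (
    EfficacyOracle,
    OracleConfig,
    generate_dataset,
    sample_catalogue,
)


@pytest.fixture(scope="session")
def catalogue():
    return sample_catalogue(seed=0)


@pytest.fixture(scope="session")
def tokenizer(catalogue):
    return FormulationTokenizer(catalogue)


@pytest.fixture(scope="session")
def base_formulation():
    return Formulation(
        components=(
            ("IL-MC3", 35.0),
            ("HL-DOPE", 16.0),
            ("ST-CHOL", 46.5),
            ("PEG-C14", 2.5),
        ),
        np_ratio=6.0,
        id="BASE",
    )


@pytest.fixture(scope="session")
def dual_formulation():
    return Formulation(
        components=(
            ("IL-CKK-E12", 21.0),
            ("IL-L319", 14.0),
            ("HL-DOPE", 16.0),
            ("ST-CHOL", 46.5),
            ("PEG-C14", 2.5),
        ),
        np_ratio=6.0,
        id="DUAL",
    )


@pytest.fixture(scope="session")
def small_model(tokenizer):
    return CometModel(CometConfig(tasks=["dc24", "b16"], n_blocks=1, seed=7), tokenizer)


@pytest.fixture(scope="session")
def wide_grid():
    """Campaign grid widened with N/P and phase variation."""
    grid = campaign_grid()
    grid.np_ratios = [3.0, 6.0, 12.0, 20.0]
    grid.aq_org_ratios = ["3:1", "1:1"]
    return grid


@pytest.fixture(scope="session")
def labelled_dataset(wide_grid, catalogue):
    oracle = EfficacyOracle(catalogue, OracleConfig(seed=0))
    data, hidden = generate_dataset(wide_grid, catalogue, oracle, n=300, seed=0)
    return data, hidden["efficacy"], oracle


@pytest.fixture(scope="session")
def noiseless_dataset(wide_grid, catalogue):
    oracle = EfficacyOracle(catalogue, OracleConfig(seed=1, noise_sd=0.0))
    data, hidden = generate_dataset(wide_grid, catalogue, oracle, n=200, seed=1)
    return data, hidden["efficacy"], oracle
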