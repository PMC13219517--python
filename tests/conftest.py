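import numpy as np
import pytest

from soluboost.data_model import (Corpus, SolubilityRecord, packaged_solutes,
                                  packaged_solvents)
from soluboost.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def solutes():
    return packaged_solutes()


@pytest.fixture(scope="session")
def solvents():
    return packaged_solvents()


@pytest.fixture(scope="session")
def small_corpus(solutes, solvents):
    """Two (solute, solvent) pairs × 3 temperatures, fixed values."""
    records = [
        SolubilityRecord("butyl paraben", "methanol", T, x)
        for T, x in [(283.0, 0.08), (298.0, 0.15), (313.0, 0.30)]
    ] + [
        SolubilityRecord("risperidone", "toluene", T, x)
        for T, x in [(283.0, 0.001), (298.0, 0.003), (313.0, 0.008)]
    ]
    return Corpus(records, solutes, solvents)


@pytest.fixture(scope="session")
def default_corpus():
    """The default study conditions: 30 systems × 8 temperatures, σ = 0.1."""
    return generate_corpus(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_corpus():
    return generate_corpus(GeneratorConfig(sigma=0.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
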