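import numpy as np
import pytest
from rdkit import Chem

from gutshield.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Medium synthetic dataset with the default planted sulfonamide alert."""
    dataset, truth = generate_dataset(SynthConfig(n_molecules=300, seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def sample_molecules():
    smiles = [
        "CCO",
        "c1ccccc1",
        "CC(=O)Nc1ccc(O)cc1",
        "CCOc1ccc(S(=O)(=O)N)cc1",
        "Cn1ccnc1",
        "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
        "O=C(O)c1ccccc1OC(C)=O",
        "ClC(Cl)c1ccc(Cl)cc1",
    ]
    return [Chem.MolFromSmiles(s) for s in smiles]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
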