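import numpy as np
import pytest
from rdkit import Chem

from logfm import gen_fixture_molecules, gen_reference_table
from logfm.hqsar import fingerprint_matrix, morgan_fingerprint, preselect_bits


@pytest.fixture(scope="session")
def panel():
    return gen_fixture_molecules("functional-group-panel")


@pytest.fixture(scope="session")
def panel_mols(panel):
    return [Chem.MolFromSmiles(m.smiles) for m in panel]


@pytest.fixture(scope="session")
def panel_fps(panel, panel_mols):
    records = [morgan_fingerprint(mol, m.compound_id)
               for m, mol in zip(panel, panel_mols)]
    B = fingerprint_matrix(records)
    keep = preselect_bits(B)
    return records, B, keep


@pytest.fixture(scope="session")
def study():
    return gen_reference_table(n=55, sigma=0.18, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(17)
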