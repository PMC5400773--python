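from __future__ import annotations

import pytest
from rdkit import Chem

from scaffold_profiler.library_io import LibrarySet, library_from_smiles


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, f"fixture SMILES failed to parse: {smiles}"
    return m


def canon(smiles: str) -> str:
    return Chem.MolToSmiles(mol(smiles))


@pytest.fixture
def tiny_library() -> LibrarySet:
    return library_from_smiles(
        [
            ("c1ccccc1", "benzene"),
            ("Cc1ccccc1", "toluene"),
            ("CCc1ccccc1", "ethylbenzene"),
            ("c1ccc2ccccc2c1", "naphthalene"),
            ("CCCCCC", "hexane"),
            ("C1CC2CCC1C2", "norbornane"),
        ],
        name="tiny",
    )
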