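"""Hand-worked decomposition oracle plus structural invariants.

Every expectation below was derived by hand on paper from the definitions:
SSSR rings; ring assemblies as atom-connected ring systems; bridge
assemblies as systems with >= 2 shared bonds between two SSSR rings; chain
assemblies as acyclic components with marked attachments; Murcko frameworks
as rings + linkers; RECAP fragments from the eleven retrosynthetic bond
classes.
"""

from __future__ import annotations

from collections import Counter

import pytest
from rdkit import Chem

import scaffold_profiler as sp
from scaffold_profiler.fragmentation import (
    bridge_assemblies,
    chain_assemblies,
    fragment_molecule,
    inventory,
    murcko_framework,
    recap_fragments,
    ring_assemblies,
    rings,
)

from conftest import canon, mol

BZ = "c1ccccc1"
CP = "C1CCCC1"
CH = "C1CCCCC1"

# name, smiles, rings, assemblies, bridges, chains, murcko, recap
# (None = not asserted for that molecule/kind; rings/chains/recap as multisets)
CASES = [
    ("benzene", BZ, [BZ], [BZ], [], [], BZ, [BZ]),
    ("toluene", "Cc1ccccc1", [BZ], [BZ], [], ["*C"], BZ, ["Cc1ccccc1"]),
    ("ethylbenzene", "CCc1ccccc1", [BZ], [BZ], [], ["*CC"], BZ, ["CCc1ccccc1"]),
    ("hexane", "CCCCCC", [], [], [], ["CCCCCC"], None, ["CCCCCC"]),
    ("cyclohexane", CH, [CH], [CH], [], [], CH, [CH]),
    ("pyridine", "c1ccncc1", ["c1ccncc1"], ["c1ccncc1"], [], [], "c1ccncc1", ["c1ccncc1"]),
    ("morpholine", "C1COCCN1", ["C1COCCN1"], ["C1COCCN1"], [], [], "C1COCCN1", ["C1COCCN1"]),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1", [BZ, BZ], [BZ, BZ], [], [],
     "c1ccc(-c2ccccc2)cc1", ["*c1ccccc1", "*c1ccccc1"]),
    ("diphenylmethane", "C(c1ccccc1)c1ccccc1", [BZ, BZ], [BZ, BZ], [], ["*C*"],
     "C(c1ccccc1)c1ccccc1", ["C(c1ccccc1)c1ccccc1"]),
    ("bibenzyl", "C(Cc1ccccc1)c1ccccc1", [BZ, BZ], [BZ, BZ], [], ["*CC*"],
     "C(Cc1ccccc1)c1ccccc1", ["C(Cc1ccccc1)c1ccccc1"]),
    ("diphenyl ether", "O(c1ccccc1)c1ccccc1", [BZ, BZ], [BZ, BZ], [], ["*O*"],
     "O(c1ccccc1)c1ccccc1", ["O(c1ccccc1)c1ccccc1"]),
    ("naphthalene", "c1ccc2ccccc2c1", [BZ, BZ], ["c1ccc2ccccc2c1"], [], [],
     "c1ccc2ccccc2c1", ["c1ccc2ccccc2c1"]),
    ("indole", "c1ccc2[nH]ccc2c1", [BZ, "c1cc[nH]c1"], ["c1ccc2[nH]ccc2c1"], [], [],
     "c1ccc2[nH]ccc2c1", ["c1ccc2[nH]ccc2c1"]),
    ("quinoline", "c1ccc2ncccc2c1", [BZ, "c1ccncc1"], ["c1ccc2ncccc2c1"], [], [],
     "c1ccc2ncccc2c1", ["c1ccc2ncccc2c1"]),
    ("norbornane", "C1CC2CCC1C2", [CP, CP], ["C1CC2CCC1C2"], ["C1CC2CCC1C2"], [],
     "C1CC2CCC1C2", ["C1CC2CCC1C2"]),
    ("bicyclo[2.2.2]octane", "C1CC2CCC1CC2", [CH, CH], ["C1CC2CCC1CC2"], ["C1CC2CCC1CC2"],
     [], "C1CC2CCC1CC2", ["C1CC2CCC1CC2"]),
    ("DABCO", "C1CN2CCN1CC2", None, ["C1CN2CCN1CC2"], ["C1CN2CCN1CC2"], [],
     "C1CN2CCN1CC2", ["C1CN2CCN1CC2"]),
    ("spiro[4.5]decane", "C1CCC2(C1)CCCCC2", [CP, CH], ["C1CCC2(C1)CCCCC2"], [], [],
     "C1CCC2(C1)CCCCC2", ["C1CCC2(C1)CCCCC2"]),
    ("N-methylacetamide", "CNC(C)=O", [], [], [], ["CNC(C)=O"], None,
     ["*NC", "*C(C)=O"]),
    ("benzamide", "NC(=O)c1ccccc1", [BZ], [BZ], [], ["*C(N)=O"], BZ,
     ["NC(=O)c1ccccc1"]),
    ("N-phenylbenzamide", "O=C(Nc1ccccc1)c1ccccc1", [BZ, BZ], [BZ, BZ], [],
     ["*NC(*)=O"], "C(Nc1ccccc1)c1ccccc1", ["*C(=O)c1ccccc1", "*Nc1ccccc1"]),
    ("phenyl benzoate", "O=C(Oc1ccccc1)c1ccccc1", [BZ, BZ], [BZ, BZ], [],
     ["*OC(*)=O"], "C(Oc1ccccc1)c1ccccc1", ["*C(=O)c1ccccc1", "*Oc1ccccc1"]),
    ("anisole", "COc1ccccc1", [BZ], [BZ], [], ["*OC"], BZ, ["*C", "*Oc1ccccc1"]),
    ("N-benzylpiperidine", "C1CCN(Cc2ccccc2)CC1", [BZ, "C1CCNCC1"],
     [BZ, "C1CCNCC1"], [], ["*C*"], "C1CCN(Cc2ccccc2)CC1",
     ["*N1CCCCC1", "*Cc1ccccc1"]),
    ("4-phenylpiperidine", "C1CC(c2ccccc2)CCN1", [BZ, "C1CCNCC1"],
     [BZ, "C1CCNCC1"], [], [], "C1CC(c2ccccc2)CCN1", ["C1CC(c2ccccc2)CCN1"]),
    ("stilbene", "C(=Cc1ccccc1)c1ccccc1", [BZ, BZ], [BZ, BZ], [], ["*C=C*"],
     "C(=Cc1ccccc1)c1ccccc1", ["*=Cc1ccccc1", "*=Cc1ccccc1"]),
    ("N-methylbenzenesulfonamide", "CNS(=O)(=O)c1ccccc1", [BZ], [BZ], [],
     ["*S(=O)(=O)NC"], BZ, ["*NC", "*S(=O)(=O)c1ccccc1"]),
    ("diphenylurea", "O=C(Nc1ccccc1)Nc1ccccc1", [BZ, BZ], [BZ, BZ], [],
     ["*NC(=O)N*"], "C(Nc1ccccc1)Nc1ccccc1", None),
    ("N-methylpyrrolidinone", "CN1CCCC1=O", ["C1CCNC1"], ["C1CCNC1"], [],
     ["*C", "*=O"], "C1CCNC1", ["*C", "*N1CCCC1=O"]),
    ("4,4'-bipyridine", "c1cc(-c2ccncc2)ccn1", ["c1ccncc1", "c1ccncc1"],
     ["c1ccncc1", "c1ccncc1"], [], [], "c1cc(-c2ccncc2)ccn1",
     ["*c1ccncc1", "*c1ccncc1"]),
]


def _multiset(expected: list[str]) -> Counter:
    return Counter(canon(s) for s in expected)


@pytest.mark.parametrize("name,smi,r,ra,b,c,mk,rc", CASES, ids=[c[0] for c in CASES])
def test_hand_worked_decompositions(name, smi, r, ra, b, c, mk, rc):
    m = mol(smi)
    if r is not None:
        assert Counter(f.canonical_smiles for f in rings(m)) == _multiset(r), "rings"
    assert Counter(f.canonical_smiles for f in ring_assemblies(m)) == _multiset(ra), "assemblies"
    assert Counter(f.canonical_smiles for f in bridge_assemblies(m)) == _multiset(b), "bridges"
    if c is not None:
        assert Counter(f.canonical_smiles for f in chain_assemblies(m)) == _multiset(c), "chains"
    fr = murcko_framework(m)
    if mk is None:
        assert fr is None
    else:
        assert fr is not None and fr.canonical_smiles == canon(mk), "murcko"
    if rc is not None:
        assert Counter(f.canonical_smiles for f in recap_fragments(m)) == _multiset(rc), "recap"


def test_diphenylurea_recap_three_leaves():
    """Both urea N–C(=O) bonds cleave, leaving two anilines and the carbonyl."""
    frs = recap_fragments(mol("O=C(Nc1ccccc1)Nc1ccccc1"))
    got = Counter(f.canonical_smiles for f in frs)
    assert sum(got.values()) == 3
    assert got[canon("*Nc1ccccc1")] == 2


def test_fluorene_counts_only():
    """Fluorene: 3 SSSR rings, one assembly, no bridge, biaryl bond is cyclic."""
    m = mol("C1c2ccccc2-c2ccccc21")
    assert len(rings(m)) == 3
    assert len(ring_assemblies(m)) == 1
    assert bridge_assemblies(m) == []
    assert len(recap_fragments(m)) == 1  # ring bonds are never cleaved


def test_adamantane_is_bridge_assembly():
    m = mol("C1C2CC3CC1CC(C2)C3")
    assert len(ring_assemblies(m)) == 1
    assert len(bridge_assemblies(m)) == 1


@pytest.mark.parametrize(
    "smi",
    ["Cc1ccccc1", "C1CC2CCC1C2", "CCc1ccc(N2CCN(C)CC2)cc1", "O=C(Oc1ccccc1)c1ccccc1",
     "C1CCC2(C1)CCCCC2", "c1ccc2ccccc2c1", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"],
)
def test_count_hierarchy_and_atom_conservation(smi):
    """rings >= assemblies >= bridges; ring + chain atoms partition heavy atoms."""
    m = mol(smi)
    assert len(rings(m)) >= len(ring_assemblies(m)) >= len(bridge_assemblies(m))
    ring_atoms = sum(1 for a in m.GetAtoms() if a.IsInRing())
    chain_heavy = 0
    for f in chain_assemblies(m):
        fm = Chem.MolFromSmiles(f.canonical_smiles)
        assert fm is not None
        chain_heavy += sum(1 for a in fm.GetAtoms() if a.GetAtomicNum() > 0)
    assert ring_atoms + chain_heavy == m.GetNumHeavyAtoms()
    # every bridge assembly is one of the molecule's ring assemblies
    ras = {f.canonical_smiles for f in ring_assemblies(m)}
    assert {f.canonical_smiles for f in bridge_assemblies(m)} <= ras


@pytest.mark.parametrize(
    "smi", ["Cc1ccccc1", "O=C(Nc1ccccc1)c1ccccc1", "CCC(=O)N1CCN(c2ccccc2)CC1"]
)
def test_murcko_idempotent(smi):
    fr = murcko_framework(mol(smi))
    again = murcko_framework(mol(fr.canonical_smiles))
    assert again.canonical_smiles == fr.canonical_smiles


@pytest.mark.parametrize(
    "smi",
    ["CNC(C)=O", "O=C(Oc1ccccc1)c1ccccc1", "CNS(=O)(=O)c1ccccc1",
     "C1CCN(Cc2ccccc2)CC1", "COc1ccccc1", "O=C(Nc1ccccc1)Nc1ccccc1"],
)
def test_recap_reassembly_conserves_heavy_atoms(smi):
    """RECAP leaves partition the parent: heavy atoms (minus dummies) add up."""
    m = mol(smi)
    frs = recap_fragments(m)
    total = 0
    for f in frs:
        fm = Chem.MolFromSmiles(f.canonical_smiles)
        total += sum(1 for a in fm.GetAtoms() if a.GetAtomicNum() > 0)
    assert total == m.GetNumHeavyAtoms()


@pytest.mark.parametrize(
    "smi", ["CNC(C)=O", "CCOC(C)=O", "C1CCN(Cc2ccccc2)CC1", "CNS(=O)(=O)c1ccccc1"]
)
def test_recap_agrees_with_independent_decomposition(smi):
    """On single-cut molecules our fragments equal RDKit's RECAP leaves."""
    from rdkit.Chem import Recap

    ours = {f.canonical_smiles for f in recap_fragments(mol(smi))}
    leaves = set()
    for leaf in Recap.RecapDecompose(mol(smi)).GetLeaves():
        lm = Chem.MolFromSmiles(leaf)
        for a in lm.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetIsotope(0)
        leaves.add(Chem.MolToSmiles(lm))
    assert ours == leaves


def test_inventory_totals_uniques_and_acyclic(tiny_library):
    inv = inventory(tiny_library)
    assert inv.n_molecules == 6
    assert inv.n_acyclic == 1  # hexane
    assert inv.acyclic_pct == pytest.approx(100.0 / 6)
    for k in inv.totals:
        assert inv.uniques[k] <= inv.totals[k]
    # benzene appears as the murcko framework of benzene/toluene/ethylbenzene
    murcko_counts = inv.unique_counter("murcko")
    assert murcko_counts[canon("c1ccccc1")] == 3


def test_inventory_murcko_merges_homologs():
    lib = sp.library_from_smiles(["Cc1ccccc1", "CCc1ccccc1"], name="pair")
    inv = inventory(lib, kinds=("murcko",))
    assert inv.totals["murcko"] == 2
    assert inv.uniques["murcko"] == 1
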