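"""Non-hierarchical fragment decompositions of a molecule.

Six representations are produced, each as canonical-SMILES fragments:

* ``ring`` — every SSSR ring, one fragment per ring.
* ``ring_assembly`` — connected components of the ring subgraph; fused and
  spiro rings (sharing at least one atom) form one assembly, assemblies
  joined only by acyclic linkers stay separate.
* ``bridge_assembly`` — the ring assemblies containing a bridged polycyclic
  system, i.e. two SSSR rings sharing two or more bonds (norbornane), which
  excludes simple ortho-fusion (naphthalene, one shared bond) and spiro.
* ``chain_assembly`` — connected acyclic components after deleting all ring
  atoms, with ring attachment positions marked by dummy atoms; a fully
  acyclic molecule is one chain (itself).
* ``murcko`` — the Bemis–Murcko framework: ring systems plus the linkers
  between them, side chains pruned; empty for acyclic molecules.
* ``recap`` — fragments from cutting every acyclic bond matching the eleven
  RECAP retrosynthetic bond classes simultaneously, attachment points
  marked; a molecule with no cleavable bond is its own single fragment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem

from .library_io import LibrarySet, MoleculeRecord

KINDS = ("ring", "ring_assembly", "bridge_assembly", "chain_assembly", "murcko", "recap")


@dataclass(frozen=True)
class FragmentRecord:
    kind: str
    canonical_smiles: str
    parent_id: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        if not self.canonical_smiles:
            raise ValueError("empty fragment SMILES")


# --------------------------------------------------------------------------
# helpers

def _canonical_fragment_smiles(mol: Chem.Mol, atoms: Sequence[int], bonds: Sequence[int]) -> str:
    """Canonical SMILES of the induced subgraph (atoms + explicit bond list).

    The raw fragment SMILES is re-parsed to normalise it; fragments whose
    aromaticity cannot stand alone (e.g. one ring cut out of a fused aromatic
    where kekulization fails) fall back to the raw fragment string, which is
    still canonical for identical inputs.
    """
    smi = Chem.MolFragmentToSmiles(mol, atomsToUse=list(atoms), bondsToUse=list(bonds), canonical=True)
    reparsed = Chem.MolFromSmiles(smi)
    if reparsed is not None:
        return Chem.MolToSmiles(reparsed)
    return smi


def _canonical_mol_smiles(mol: Chem.Mol) -> str:
    smi = Chem.MolToSmiles(mol)
    reparsed = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(reparsed) if reparsed is not None else smi


def _sssr(mol: Chem.Mol) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """(atom rings, bond rings) of the true (non-symmetrized) SSSR.

    RDKit's default ring perception keeps symmetry-equivalent extra rings
    (bicyclo[2.2.2]octane would report three six-rings); diversity counts
    need the minimal set, so the SSSR is re-perceived explicitly.
    """
    atom_rings = [tuple(r) for r in Chem.GetSSSR(mol)]
    bond_rings = []
    for ring in atom_rings:
        bonds = []
        for i, a in enumerate(ring):
            b = ring[(i + 1) % len(ring)]
            bond = mol.GetBondBetweenAtoms(a, b)
            assert bond is not None, "SSSR ring atoms not consecutive"
            bonds.append(bond.GetIdx())
        bond_rings.append(tuple(bonds))
    return atom_rings, bond_rings


def _ring_atom_components(mol: Chem.Mol) -> list[set[int]]:
    """Connected components of ring atoms under ring bonds (assemblies)."""
    parent: dict[int, int] = {a.GetIdx(): a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for bond in mol.GetBonds():
        if bond.IsInRing():
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            parent[find(a)] = find(b)
    comps: dict[int, set[int]] = {}
    for a in parent:
        comps.setdefault(find(a), set()).add(a)
    return sorted(comps.values(), key=min)


# --------------------------------------------------------------------------
# ring-system representations

def rings(mol: Chem.Mol, parent_id: str = "") -> list[FragmentRecord]:
    """One fragment per SSSR ring; empty for acyclic molecules."""
    atom_rings, bond_rings = _sssr(mol)
    out = []
    for atoms, bonds in zip(atom_rings, bond_rings):
        out.append(FragmentRecord("ring", _canonical_fragment_smiles(mol, atoms, bonds), parent_id))
    return out


def ring_assemblies(mol: Chem.Mol, parent_id: str = "") -> list[FragmentRecord]:
    """Connected ring systems (fused or spiro) as single fragments."""
    out = []
    for comp in _ring_atom_components(mol):
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in comp and b.GetEndAtomIdx() in comp
        ]
        out.append(
            FragmentRecord("ring_assembly", _canonical_fragment_smiles(mol, sorted(comp), bonds), parent_id)
        )
    return out


def bridge_assemblies(mol: Chem.Mol, parent_id: str = "") -> list[FragmentRecord]:
    """Ring assemblies containing two SSSR rings sharing >= 2 bonds."""
    atom_rings, bond_rings = _sssr(mol)
    out = []
    for comp in _ring_atom_components(mol):
        member = [
            set(br) for ar, br in zip(atom_rings, bond_rings) if set(ar) <= comp
        ]
        bridged = any(
            len(member[i] & member[j]) >= 2
            for i in range(len(member))
            for j in range(i + 1, len(member))
        )
        if not bridged:
            continue
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in comp and b.GetEndAtomIdx() in comp
        ]
        out.append(
            FragmentRecord("bridge_assembly", _canonical_fragment_smiles(mol, sorted(comp), bonds), parent_id)
        )
    return out


# --------------------------------------------------------------------------
# chains

def chain_assemblies(mol: Chem.Mol, parent_id: str = "") -> list[FragmentRecord]:
    """Acyclic components left after deleting ring atoms, attachments marked.

    Each bond from a chain atom to a ring atom is replaced by a bond to a
    dummy atom (``*``) of the same order, so a methyl side chain and an
    ethylene linker with two attachments canonicalise to distinct fragments.
    """
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    if not ring_atoms:
        return [FragmentRecord("chain_assembly", _canonical_mol_smiles(mol), parent_id)]
    chain_atoms = set(range(mol.GetNumAtoms())) - ring_atoms
    if not chain_atoms:
        return []

    rw = Chem.RWMol(mol)
    # attach dummies in place of ring neighbours
    for bond in list(mol.GetBonds()):
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in chain_atoms) == (b in chain_atoms):
            continue
        chain_end = a if a in chain_atoms else b
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(chain_end, dummy, bond.GetBondType())
    for idx in sorted(ring_atoms, reverse=True):
        rw.RemoveAtom(idx)
    frag_mol = rw.GetMol()
    out = []
    for frag in Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False):
        try:
            Chem.SanitizeMol(frag)
        except Chem.rdchem.MolSanitizeException:
            pass
        out.append(FragmentRecord("chain_assembly", _canonical_mol_smiles(frag), parent_id))
    return out


# --------------------------------------------------------------------------
# Murcko framework

def _prune_side_chains(mol: Chem.Mol) -> Chem.Mol | None:
    """Iteratively strip terminal non-ring atoms; None for acyclic input.

    What remains after the fixed point is the union of ring systems and the
    linker atoms lying on paths between them — the Bemis–Murcko framework.
    Exocyclic terminal atoms are pruned regardless of bond order, so a
    carbonyl O hanging off a ring is removed like any side chain.
    """
    if not any(a.IsInRing() for a in mol.GetAtoms()):
        return None
    rw = Chem.RWMol(mol)
    while True:
        terminal = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetDegree() <= 1 and not a.IsInRing()
        ]
        if not terminal:
            break
        for idx in sorted(terminal, reverse=True):
            rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Chem.rdchem.MolSanitizeException:
        return None
    return out


def murcko_framework(
    mol: Chem.Mol, parent_id: str = "", keep_exocyclic: bool = False
) -> FragmentRecord | None:
    """Bemis–Murcko framework; ``None`` for acyclic molecules.

    ``keep_exocyclic=True`` retains atoms double-bonded to the framework
    (the convention of some toolkits); the default prunes them.
    """
    if keep_exocyclic:
        from rdkit.Chem.Scaffolds import MurckoScaffold

        if not any(a.IsInRing() for a in mol.GetAtoms()):
            return None
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
        if scaffold.GetNumAtoms() == 0:
            return None
        return FragmentRecord("murcko", _canonical_mol_smiles(scaffold), parent_id)
    scaffold = _prune_side_chains(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return FragmentRecord("murcko", _canonical_mol_smiles(scaffold), parent_id)


def murcko_framework_mol(mol: Chem.Mol) -> Chem.Mol | None:
    """The framework as an RDKit mol (used by the scaffold-tree builder)."""
    return _prune_side_chains(mol)


# --------------------------------------------------------------------------
# RECAP

#: The eleven RECAP retrosynthetic bond classes, as SMARTS whose first two
#: mapped atoms delimit the acyclic bond to cut.  Authored against the
#: published rule list (amide, ester, amine, urea, ether, olefin, quaternary
#: N, aromatic N–aliphatic C, lactam N–aliphatic C, biaryl C–C, sulfonamide).
RECAP_BOND_SMARTS: dict[str, str] = {
    "urea": "[#7;+0;!D1:1]!@[C;$(C=O);$(C([#7])[#7]):2]",
    "amide": "[C;$(C=O);!$(C([#7])[#7]):1]!@[#7;+0;!D1;!$([#7]=*):2]",
    "ester": "[C;$(C=O);!$(C(=O)([#8])[#8]):1](=O)!@[O;D2;+0:2]",
    "amine": "[N;X3;+0;!$(N=*);!$(N[C,S]=[O,S,N]);!$(N[#7,#8,#16]):1]!@[C;X4:2]",
    "ether": "[O;D2;+0;!$(O[C,S]=[O,S,N]);$(O([#6])[#6]):1]!@[C;X4:2]",
    "olefin": "[C;D2,D3;!$(C=[O,N,S]):1]=!@[C;D2,D3;!$(C=[O,N,S]):2]",
    "quaternary_n": "[N;+1;D4:1]!@[C;X4:2]",
    "aromatic_n_aliphatic_c": "[n;+0:1]!@[C;X4:2]",
    "lactam_n_aliphatic_c": "[N;+0;R;$(N(@[C;R]=O)):1]!@[C;X4:2]",
    "aromatic_c_aromatic_c": "[c:1]-!@[c:2]",
    "sulfonamide": "[#7;+0;!D1:1]!@[S;$(S(=O)=O):2]",
}

def _compile_recap() -> list[tuple[Chem.Mol, int, int]]:
    """(pattern, idx of map-1 atom, idx of map-2 atom) per bond class."""
    out = []
    for smarts in RECAP_BOND_SMARTS.values():
        patt = Chem.MolFromSmarts(smarts)
        by_map = {a.GetAtomMapNum(): a.GetIdx() for a in patt.GetAtoms() if a.GetAtomMapNum()}
        out.append((patt, by_map[1], by_map[2]))
    return out


_RECAP_PATTERNS = _compile_recap()


def recap_cleavable_bonds(mol: Chem.Mol) -> set[int]:
    """Indices of acyclic bonds matching any RECAP bond class."""
    bonds: set[int] = set()
    for patt, i1, i2 in _RECAP_PATTERNS:
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[i1], match[i2])
            if bond is not None and not bond.IsInRing():
                bonds.add(bond.GetIdx())
    return bonds


def recap_fragments(mol: Chem.Mol, parent_id: str = "") -> list[FragmentRecord]:
    """Cut all RECAP-cleavable bonds at once; attachment points marked.

    The fragments partition the parent's heavy atoms, so reassembly at the
    dummy atoms conserves heavy-atom count.  A molecule with no cleavable
    bond yields itself as its single fragment.
    """
    bonds = recap_cleavable_bonds(mol)
    if not bonds:
        return [FragmentRecord("recap", _canonical_mol_smiles(mol), parent_id)]
    pieces = Chem.FragmentOnBonds(mol, sorted(bonds), addDummies=True)
    out = []
    for frag in Chem.GetMolFrags(pieces, asMols=True, sanitizeFrags=False):
        try:
            Chem.SanitizeMol(frag)
        except Chem.rdchem.MolSanitizeException:
            pass
        # strip the isotope labels FragmentOnBonds puts on dummies, so that
        # chemically identical leaves from different cut sites unify
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetIsotope(0)
        out.append(FragmentRecord("recap", _canonical_mol_smiles(frag), parent_id))
    return out


# --------------------------------------------------------------------------
# library-level inventory

_FRAGMENTERS = {
    "ring": rings,
    "ring_assembly": ring_assemblies,
    "bridge_assembly": bridge_assemblies,
    "chain_assembly": chain_assemblies,
    "recap": recap_fragments,
}


def fragment_molecule(rec: MoleculeRecord, kinds: Iterable[str] = KINDS) -> list[FragmentRecord]:
    """All requested fragment records for one molecule."""
    out: list[FragmentRecord] = []
    for kind in kinds:
        if kind == "murcko":
            fr = murcko_framework(rec.mol, rec.mol_id)
            if fr is not None:
                out.append(fr)
        else:
            out.extend(_FRAGMENTERS[kind](rec.mol, rec.mol_id))
    return out


@dataclass
class FragmentInventory:
    """Per-kind fragment multisets and counts for a whole library."""

    library: str
    records: dict[str, list[FragmentRecord]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    uniques: dict[str, int] = field(default_factory=dict)
    n_molecules: int = 0
    n_acyclic: int = 0

    @property
    def acyclic_pct(self) -> float:
        return 100.0 * self.n_acyclic / self.n_molecules if self.n_molecules else 0.0

    def unique_counter(self, kind: str) -> Counter:
        return Counter(fr.canonical_smiles for fr in self.records.get(kind, []))


def inventory(lib: LibrarySet | Iterable[MoleculeRecord], kinds: Iterable[str] = KINDS,
              name: str | None = None) -> FragmentInventory:
    """Fragment every molecule and tally totals/uniques per kind."""
    kinds = tuple(kinds)
    recs = lib.records if isinstance(lib, LibrarySet) else list(lib)
    label = name or (lib.name if isinstance(lib, LibrarySet) else "library")
    inv = FragmentInventory(library=label, records={k: [] for k in kinds})
    for rec in recs:
        inv.n_molecules += 1
        if not any(a.IsInRing() for a in rec.mol.GetAtoms()):
            inv.n_acyclic += 1
        for fr in fragment_molecule(rec, kinds):
            inv.records[fr.kind].append(fr)
    for k in kinds:
        inv.totals[k] = len(inv.records[k])
        inv.uniques[k] = len({fr.canonical_smiles for fr in inv.records[k]})
    return inv
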