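"""Hierarchical scaffold trees by iterative ring pruning.

Starting from a molecule's Bemis–Murcko framework, one peripheral SSSR ring
is removed per step until a single ring remains.  Levels are numbered from
Level 0 (the last remaining ring) up to Level n (the original molecule);
Level n−1 is the framework whenever the molecule carries side chains.

Which ring to remove at each step is decided by the "ST-rules v1" chain, an
ordered list of tie-breaking filters applied to the set of *valid* removals
(those that keep the scaffold connected, chemically sane, and reduce the
SSSR ring count by exactly one):

1. prefer removals whose resulting scaffold is linker-free (no acyclic
   bonds remain);
2. retain bridged and spiro systems: prefer removing rings that share no
   atoms-only (spiro) or multi-bond (bridged) fusion with another ring;
3. prefer removing larger rings;
4. retain heteroatom-rich rings: prefer removing the ring with the fewest
   heteroatoms;
5. finally, the removal whose resulting scaffold has the lexicographically
   smallest canonical SMILES wins.

The chain is total, so the tree is deterministic for any input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from rdkit import Chem

from .fragmentation import murcko_framework_mol, _prune_side_chains
from .library_io import LibrarySet, MoleculeRecord


@dataclass
class ScaffoldTreeResult:
    """Ordered scaffold levels for one molecule.

    ``levels[0]`` is the single remaining ring, ``levels[n]`` the original
    molecule.  When the molecule *is* its own framework (no side chains) the
    framework level coincides with ``n``; otherwise it is ``n - 1``.
    ``complete`` is False when no valid ring removal existed before reaching
    a single ring (rare pathological ring systems).
    """

    parent_id: str
    levels: list[str]
    framework_level: int = 0
    complete: bool = True

    @property
    def n(self) -> int:
        return len(self.levels) - 1

    def level(self, k: int) -> str | None:
        return self.levels[k] if 0 <= k <= self.n else None

    def level1_scaffold(self) -> str:
        """The Level 1 scaffold (Level 0 for a bare single-ring molecule)."""
        return self.levels[min(1, self.n)]


def _skeleton(smiles: str) -> Chem.Mol:
    """Element-labelled graph with all bonds single and aromaticity erased."""
    mol = Chem.MolFromSmiles(smiles)
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetIsAromatic(False)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    out.UpdatePropertyCache(strict=False)
    return out


def is_subscaffold(sub_smiles: str, sup_smiles: str) -> bool:
    """Whether one scaffold's graph is contained in another's.

    Ring pruning can demote aromatic atoms (the benzo ring of indane leaves
    a partially unsaturated carbocycle), so the comparison is made on the
    element-labelled skeletons, ignoring bond orders and aromaticity.
    """
    return _skeleton(sup_smiles).HasSubstructMatch(_skeleton(sub_smiles))


def _ring_count(mol: Chem.Mol) -> int:
    return len(Chem.GetSSSR(mol))  # true SSSR, not the symmetrized set


def _roundtrip(mol: Chem.Mol) -> tuple[Chem.Mol | None, str]:
    """Re-parse through SMILES to get a cleanly sanitized scaffold."""
    smi = Chem.MolToSmiles(mol)
    reparsed = Chem.MolFromSmiles(smi)
    if reparsed is None:
        return None, smi
    return reparsed, Chem.MolToSmiles(reparsed)


def _remove_ring(scaffold: Chem.Mol, ring_atoms: set[int], other_atoms: set[int]) -> Chem.Mol | None:
    """Remove one SSSR ring's exclusive atoms and re-prune dangling linkers.

    Returns the new scaffold, or None when the removal is invalid (ring has
    no exclusive atoms, scaffold disconnects, sanitization fails, or the
    ring count does not drop by exactly one).
    """
    exclusive = ring_atoms - other_atoms
    if not exclusive:
        return None
    rw = Chem.RWMol(scaffold)
    for idx in sorted(exclusive, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Chem.rdchem.MolSanitizeException:
        return None
    out = _prune_side_chains(out)
    if out is None:
        return None
    out, _ = _roundtrip(out)
    if out is None:
        return None
    if len(Chem.GetMolFrags(out)) != 1:
        return None
    if _ring_count(out) != _ring_count(scaffold) - 1:
        return None
    return out


def _candidate_removals(scaffold: Chem.Mol) -> list[dict]:
    from .fragmentation import _sssr

    raw_atom_rings, raw_bond_rings = _sssr(scaffold)
    atom_rings = [set(r) for r in raw_atom_rings]
    bond_rings = [set(r) for r in raw_bond_rings]
    cands = []
    for i, ring in enumerate(atom_rings):
        others = set().union(*(r for j, r in enumerate(atom_rings) if j != i)) if len(atom_rings) > 1 else set()
        result = _remove_ring(scaffold, ring, others)
        if result is None:
            continue
        fused_bonds = max(
            (len(bond_rings[i] & bond_rings[j]) for j in range(len(bond_rings)) if j != i),
            default=0,
        )
        shares_atom = any(ring & atom_rings[j] for j in range(len(atom_rings)) if j != i)
        is_bridged = fused_bonds >= 2
        is_spiro = shares_atom and fused_bonds == 0
        result_smiles = Chem.MolToSmiles(result)
        has_linker = any(not b.IsInRing() for b in result.GetBonds())
        heteroatoms = sum(1 for a in scaffold.GetAtoms() if a.GetIdx() in ring and a.GetAtomicNum() != 6)
        cands.append(
            {
                "result": result,
                "result_smiles": result_smiles,
                "linker_free_result": not has_linker,
                "fusion_plain": not (is_bridged or is_spiro),
                "ring_size": len(ring),
                "heteroatoms": heteroatoms,
            }
        )
    return cands


def _select_removal(cands: list[dict]) -> dict:
    """Apply the ST-rules v1 filter chain; ``cands`` must be non-empty."""

    def narrow(pool: list[dict], key, best) -> list[dict]:
        target = best(key(c) for c in pool)
        return [c for c in pool if key(c) == target]

    pool = cands
    pool = narrow(pool, lambda c: c["linker_free_result"], max)   # rule 1
    pool = narrow(pool, lambda c: c["fusion_plain"], max)         # rule 2
    pool = narrow(pool, lambda c: c["ring_size"], max)            # rule 3
    pool = narrow(pool, lambda c: c["heteroatoms"], min)          # rule 4
    pool = narrow(pool, lambda c: c["result_smiles"], min)        # rule 5
    return pool[0]


def scaffold_tree(rec: MoleculeRecord | Chem.Mol, parent_id: str | None = None) -> ScaffoldTreeResult | None:
    """Scaffold tree of one molecule; ``None`` for acyclic input."""
    if isinstance(rec, MoleculeRecord):
        mol, pid = rec.mol, rec.mol_id
    else:
        mol, pid = rec, parent_id or ""
    framework = murcko_framework_mol(mol)
    if framework is None:
        return None
    framework, fw_smiles = _roundtrip(framework)
    if framework is None:
        return None
    mol_smiles = Chem.MolToSmiles(mol)

    descend = [fw_smiles]
    scaffold = framework
    complete = True
    while _ring_count(scaffold) > 1:
        cands = _candidate_removals(scaffold)
        if not cands:
            complete = False
            break
        chosen = _select_removal(cands)
        scaffold = chosen["result"]
        descend.append(chosen["result_smiles"])

    levels = list(reversed(descend))
    framework_level = len(levels) - 1
    if mol_smiles != fw_smiles:
        levels.append(mol_smiles)
    return ScaffoldTreeResult(
        parent_id=pid, levels=levels, framework_level=framework_level, complete=complete
    )


@dataclass
class LevelInventory:
    """Per-level scaffold counts across a library (rose-map table basis)."""

    library: str
    totals: dict[int, int] = field(default_factory=dict)
    uniques: dict[int, int] = field(default_factory=dict)
    n_molecules: int = 0
    n_acyclic: int = 0

    @property
    def max_level(self) -> int:
        return max(self.totals) if self.totals else -1

    def as_table(self) -> list[dict]:
        return [
            {"level": L, "total": self.totals[L], "unique": self.uniques[L]}
            for L in sorted(self.totals)
        ]


def level_inventory(
    lib: LibrarySet | Iterable[MoleculeRecord],
    trees: Iterable[ScaffoldTreeResult] | None = None,
    name: str | None = None,
) -> LevelInventory:
    """Tally total and unique scaffolds per tree level over a library.

    ``totals[L]`` counts molecules whose tree reaches level L; ``uniques[L]``
    counts distinct canonical scaffolds at that level.  Acyclic molecules
    contribute to no level and are reported separately.
    """
    recs = lib.records if isinstance(lib, LibrarySet) else list(lib)
    label = name or (lib.name if isinstance(lib, LibrarySet) else "library")
    inv = LevelInventory(library=label)
    per_level: dict[int, set[str]] = {}
    if trees is None:
        trees = []
        for rec in recs:
            inv.n_molecules += 1
            t = scaffold_tree(rec)
            if t is None:
                inv.n_acyclic += 1
            else:
                trees.append(t)
    else:
        trees = list(trees)
        inv.n_molecules = len(recs)
        inv.n_acyclic = inv.n_molecules - len(trees)
    for t in trees:
        for L, smi in enumerate(t.levels):
            inv.totals[L] = inv.totals.get(L, 0) + 1
            per_level.setdefault(L, set()).add(smi)
    inv.uniques = {L: len(s) for L, s in per_level.items()}
    return inv


def rose_map_table(inventories: list[LevelInventory]) -> dict:
    """Levels × libraries table of totals and uniques, JSON-ready."""
    max_level = max((inv.max_level for inv in inventories), default=-1)
    return {
        "levels": list(range(max_level + 1)),
        "libraries": [inv.library for inv in inventories],
        "totals": {
            inv.library: [inv.totals.get(L, 0) for L in range(max_level + 1)]
            for inv in inventories
        },
        "uniques": {
            inv.library: [inv.uniques.get(L, 0) for L in range(max_level + 1)]
            for inv in inventories
        },
    }
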