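"""Reading, preprocessing and writing of molecule libraries.

A *library* is an ordered collection of :class:`MoleculeRecord` objects, one
per compound, parsed from an SDF (V2000) or SMILES file.  Preprocessing
mirrors the cleanup a screening-library comparison needs before any scaffold
statistics make sense: drop records with elements outside a configurable
organic subset, strip counter-ions (keep the largest covalent component),
normalise implicit hydrogens via sanitization, and deduplicate on canonical
SMILES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

logger = logging.getLogger("scaffold_profiler")

# RDKit is chatty about every unparseable record; we count and report instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: Default element whitelist used by the "inorganic" filter.  Anything with an
#: atom outside this set is treated as inorganic/organometallic and removed.
ORGANIC_ELEMENTS: frozenset[str] = frozenset(
    {"H", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
)


class LibraryError(RuntimeError):
    """Fatal library-level failure (missing file, nothing parseable, ...)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One parsed molecule.

    Attributes
    ----------
    mol_id:
        Identifier carried over from the source file (SDF title line or the
        second whitespace-separated token of a SMILES line).
    mol:
        The sanitized RDKit molecule.
    canonical_smiles:
        RDKit canonical isomeric SMILES; identical for any two records that
        describe the same molecular graph.
    mw:
        Average molecular weight in Da of the hydrogen-complete structure.
    library:
        Name of the library the record belongs to.
    """

    mol_id: str
    mol: Chem.Mol
    canonical_smiles: str
    mw: float
    library: str

    def __post_init__(self) -> None:
        if self.mol.GetNumAtoms() == 0:
            raise ValueError(f"record {self.mol_id}: structure has no atoms")


@dataclass
class LibrarySet:
    """An ordered, named collection of molecule records."""

    name: str
    records: list[MoleculeRecord]
    provenance: str = "unknown"
    skipped_count: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def smiles(self) -> list[str]:
        return [r.canonical_smiles for r in self.records]


@dataclass
class PreprocessReport:
    """Accounting of what :func:`preprocess` removed and why."""

    input_count: int = 0
    inorganic_removed: int = 0
    sanitize_failed: int = 0
    mw_capped: int = 0
    duplicates_removed: int = 0
    salts_stripped: int = 0  # records trimmed to largest component (kept)
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def record_from_mol(
    mol: Chem.Mol, mol_id: str, library: str, sanitize: bool = True
) -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from an RDKit mol.

    Raises ``ValueError`` if sanitization fails (bad valence etc.).
    """
    if sanitize:
        Chem.SanitizeMol(mol)
    return MoleculeRecord(
        mol_id=mol_id,
        mol=mol,
        canonical_smiles=Chem.MolToSmiles(mol),
        mw=Descriptors.MolWt(mol),
        library=library,
    )


def _iter_sdf(path: Path) -> Iterator[tuple[Chem.Mol | None, str]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield None, f"record-{i}"
        else:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            yield mol, name.strip() or f"record-{i}"


def _iter_smiles(path: Path) -> Iterator[tuple[Chem.Mol | None, str]]:
    with open(path) as fh:
        i = -1
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i += 1
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            name = parts[1].strip() if len(parts) > 1 else ""
            yield mol, name or f"record-{i}"


def read_library(path: str | Path, fmt: str, name: str | None = None) -> LibrarySet:
    """Read a molecule library from an SDF (V2000) or SMILES file.

    Unparseable records are skipped and counted (``skipped_count``); a file
    with no parseable record at all is a fatal :class:`LibraryError`.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")
    if fmt not in ("sdf", "smiles"):
        raise ValueError(f"unknown format {fmt!r}; expected 'sdf' or 'smiles'")
    name = name or path.stem

    records: list[MoleculeRecord] = []
    skipped = 0
    it = _iter_sdf(path) if fmt == "sdf" else _iter_smiles(path)
    for mol, mol_id in it:
        if mol is None:
            skipped += 1
            continue
        try:
            records.append(record_from_mol(mol, mol_id, name, sanitize=False))
        except ValueError:
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d unparseable record(s)", path, skipped)
    if not records:
        raise LibraryError(f"{path}: no parseable records")
    return LibrarySet(name=name, records=records, provenance=str(path), skipped_count=skipped)


def _largest_component(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Return the largest covalent component; flag whether anything was cut."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, False
    # largest by heavy atoms, ties by MW then canonical SMILES for determinism
    best = max(
        frags,
        key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m), Chem.MolToSmiles(m)),
    )
    return best, True


def preprocess(
    lib: LibrarySet,
    allowed_elements: Iterable[str] = ORGANIC_ELEMENTS,
    max_mw: float | None = None,
) -> tuple[LibrarySet, PreprocessReport]:
    """Clean a library: inorganic filter, salt stripping, sanitization, dedup.

    Order of operations per record: strip to largest covalent component,
    remove if any atom's element is outside ``allowed_elements``, re-sanitize
    (records that fail are dropped, not repaired), then deduplicate on
    canonical SMILES keeping the first occurrence.  ``max_mw`` optionally
    drops molecules at or above a weight ceiling (off by default).
    """
    if not lib.records:
        raise LibraryError(f"{lib.name}: cannot preprocess an empty library")
    allowed = frozenset(allowed_elements)
    report = PreprocessReport(input_count=len(lib.records))
    seen: set[str] = set()
    kept: list[MoleculeRecord] = []
    for rec in lib.records:
        mol, stripped = _largest_component(rec.mol)
        if any(a.GetSymbol() not in allowed for a in mol.GetAtoms()):
            report.inorganic_removed += 1
            continue
        try:
            new = record_from_mol(Chem.Mol(mol), rec.mol_id, lib.name, sanitize=True)
        except (ValueError, Chem.rdchem.MolSanitizeException):
            report.sanitize_failed += 1
            continue
        if max_mw is not None and new.mw >= max_mw:
            report.mw_capped += 1
            continue
        if stripped:
            report.salts_stripped += 1
        if new.canonical_smiles in seen:
            report.duplicates_removed += 1
            continue
        seen.add(new.canonical_smiles)
        kept.append(new)
    report.retained = len(kept)
    if not kept:
        raise LibraryError(f"{lib.name}: empty after preprocessing ({report.as_dict()})")
    return (
        LibrarySet(name=lib.name, records=kept, provenance=lib.provenance),
        report,
    )


def write_library(lib: LibrarySet, path: str | Path, fmt: str) -> Path:
    """Write a library as SDF (V2000) or SMILES; returns the path written."""
    path = Path(path)
    if not lib.records:
        raise LibraryError(f"{lib.name}: refusing to write an empty library")
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rec in lib.records:
                mol = Chem.Mol(rec.mol)
                mol.SetProp("_Name", rec.mol_id)
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "smiles":
        with open(path, "w") as fh:
            for rec in lib.records:
                fh.write(f"{rec.canonical_smiles} {rec.mol_id}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def library_from_smiles(
    pairs: Sequence[tuple[str, str]] | Sequence[str], name: str
) -> LibrarySet:
    """Convenience constructor from in-memory SMILES (tests, synthetic data).

    ``pairs`` is either a list of SMILES strings or of ``(smiles, id)``.
    """
    records = []
    for i, item in enumerate(pairs):
        smi, mol_id = (item, f"{name}-{i}") if isinstance(item, str) else item
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        records.append(record_from_mol(mol, mol_id, name, sanitize=False))
    return LibrarySet(name=name, records=records, provenance="in-memory")
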