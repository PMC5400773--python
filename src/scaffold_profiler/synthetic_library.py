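"""Synthetic compound libraries with known scaffold ground truth.

Real vendor catalogs differ in how many distinct scaffolds they contain, how
skewed the molecule-per-scaffold distribution is, how many acyclic compounds
they carry, and how their molecular weights spread.  This generator controls
all four knobs directly: each ring-bearing molecule is one scaffold template
(a pure Bemis–Murcko framework from a curated pool spanning 1–5 ring
systems, including fused, spiro and bridged exemplars) decorated with random
acyclic substituents chosen to land the MW inside a requested window.
Because the default substituents are ring-free, the Murcko framework of
every generated molecule is *exactly* its template, so frequency tables,
unique-scaffold counts and PC50C computed downstream have exact expected
values.  A ``hard_mode`` flag admits ring-bearing substituents to
stress-test the fragmenter, forfeiting the ground-truth guarantee.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .diversity_metrics import FrequencyTable, frequency_table, pc50c
from .fragmentation import murcko_framework
from .library_io import LibrarySet, record_from_mol

# --------------------------------------------------------------------------
# fixture pools

#: Curated scaffold templates: every entry is its own Murcko framework
#: (rings + linkers only, no side chains), 1–5 ring systems, including
#: fused, spiro and bridged polycyclics.  Entries failing that contract are
#: rejected at pool-build time.
TEMPLATE_POOL: tuple[str, ...] = (
    # single rings
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1cnccn1", "c1ccnnc1",
    "c1cc[nH]c1", "c1ccoc1", "c1ccsc1", "c1c[nH]cn1", "c1cc[nH]n1",
    "c1cscn1", "c1ocnc1",
    "C1CCCCC1", "C1CCCC1", "C1CCNCC1", "C1CNCCN1", "C1COCCN1",
    "C1CCOCC1", "C1CCOC1", "C1CCNC1", "C1CCCCCC1", "C1CC1", "C1CCC1",
    "C1COC1", "C1CNC1",
    # fused bicyclics
    "c1ccc2ccccc2c1", "c1ccc2ncccc2c1", "c1ccc2cnccc2c1",
    "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "c1ccc2[nH]cnc2c1", "c1ccc2nccnc2c1", "c1ccc2ncncc2c1",
    "C1Cc2ccccc2C1", "C1CCc2ccccc2C1", "C1CCC2CCCCC2C1",
    "C1COc2ccccc2C1", "C1CNc2ccccc2C1",
    # spiro
    "C1CCC2(C1)CCCCC2", "C1CCC2(CC1)CCCCC2", "C1CCC2(C1)CCOCC2",
    "C1CC2(C1)CCNCC2",
    # bridged
    "C1CC2CCC1C2", "C1CC2CCC1CC2", "C1CN2CCN1CC2", "C1CC2CCC(C1)O2",
    "C1C2CC3CC1CC(C2)C3",
    # linked two-ring systems
    "c1ccc(-c2ccccc2)cc1", "C(c1ccccc1)c1ccccc1", "C(Cc1ccccc1)c1ccccc1",
    "O(c1ccccc1)c1ccccc1", "C1CCN(c2ccccc2)CC1", "C1CN(Cc2ccccc2)CCN1",
    "C1CCC(c2ccccc2)CC1", "c1ccc(-c2ccccn2)cc1", "C(Oc1ccccc1)c1ccccc1",
    "c1ccc(Nc2ccccc2)cc1", "C1CCN(Cc2ccccc2)CC1", "c1ccc(Oc2ccncc2)cc1",
    # three-ring systems
    "c1ccc2cc3ccccc3cc2c1", "c1ccc2nc3ccccc3cc2c1",
    "C1c2ccccc2-c2ccccc21", "c1ccc(-c2cccc3ccccc23)cc1",
    "c1ccc(N2CCN(c3ccccc3)CC2)cc1", "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
    "C(c1ccccc1)(c1ccccc1)c1ccccc1", "c1ccc(-c2ccc3ccccc3c2)cc1",
    "C1CCC(CC2CCC(c3ccccc3)CC2)CC1",
    # four- and five-ring systems
    "c1cc2ccc3cccc4ccc(c1)c2c34",
    "c1ccc(-c2ccc(-c3cccc4ccccc34)cc2)cc1",
    "c1ccc(-c2ccc(-c3ccc(-c4ccccc4)cc3)cc2)cc1",
    "C1CCC(N2CCN(c3ccc4ccccc4c3)CC2)CC1",
    "c1ccc(-c2ccc(-c3ccc(-c4ccc(-c5ccccc5)cc4)cc3)cc2)cc1",
    "C(c1ccc2ccccc2c1)N1CCN(Cc2ccccc2)CC1",
)

#: Acyclic substituents; atom 0 is the attachment point.
SUBSTITUENT_POOL: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C", "CCCCC", "CCCCCC",
    "CCCCCCCC", "F", "Cl", "Br", "O", "OC", "OCC", "OCCC", "OCCOC",
    "N", "NC", "N(C)C", "C#N", "C(F)(F)F", "CO", "CN", "COC", "CCO",
    "C(=O)C", "C(=O)OC", "C(=O)OCC", "C(=O)NC", "NC(=O)C",
    "S(=O)(=O)C", "SC",
)

#: Ring-bearing substituents admitted only in ``hard_mode``.
HARD_SUBSTITUENT_POOL: tuple[str, ...] = ("c1ccccc1", "C1CCCCC1", "N1CCOCC1")

#: Acyclic base skeletons for the ring-free fraction of a library.
ACYCLIC_BASE_POOL: tuple[str, ...] = (
    "CCO", "CCCC", "CCOCC", "CCNCC", "CCC(C)C", "CC(=O)NCC", "CCOC(C)=O",
    "CCCCO", "CCSCC", "CC(C)CO",
)


#: Acyclic linkers used to combine base templates into larger frameworks
#: when more distinct scaffolds are requested than the curated pool holds.
#: Atom 0 and the last atom are the two attachment ends ("" = direct bond).
LINKER_POOL: tuple[str, ...] = ("", "C", "CC", "CCC", "O", "N", "CO", "CN", "COC")


class GeneratorError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of one synthetic library.

    ``freq_model`` is ``zipf`` (rank weights 1/k**alpha), ``uniform``, or
    ``explicit`` with ``explicit_freqs`` giving the molecule count of each
    scaffold directly.  ``mw_range`` is a half-open Da window; every emitted
    molecule lands inside it.
    """

    n_molecules: int = 1000
    n_scaffolds: int = 50
    freq_model: str = "zipf"
    alpha: float = 1.5
    explicit_freqs: tuple[int, ...] | None = None
    acyclic_fraction: float = 0.0
    mw_range: tuple[float, float] = (100.0, 700.0)
    seed: int = 0
    hard_mode: bool = False
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.freq_model not in ("zipf", "uniform", "explicit"):
            raise ValueError(f"unknown freq_model {self.freq_model!r}")
        if not 0 <= self.acyclic_fraction < 1:
            raise ValueError("acyclic_fraction must be in [0, 1)")
        if self.mw_range[0] >= self.mw_range[1]:
            raise ValueError("mw_range must be (low, high) with low < high")


@dataclass
class GroundTruth:
    """What the generator actually emitted, for downstream recovery checks."""

    labels: list[str | None]             # per-molecule scaffold (None = acyclic)
    templates: list[str]                 # the K canonical templates used
    true_frequencies: FrequencyTable
    expected_pc50c: float
    n_acyclic: int
    config: GeneratorConfig


from functools import lru_cache


@lru_cache(maxsize=8)
def _validated_pool_cached(mw_high: float) -> tuple[tuple[str, Chem.Mol, float], ...]:
    return tuple(_validated_pool(mw_high))


def _validated_pool(mw_high: float) -> list[tuple[str, Chem.Mol, float]]:
    pool = []
    seen: set[str] = set()
    for smi in TEMPLATE_POOL:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise GeneratorError(f"template does not parse: {smi!r}")
        canon = Chem.MolToSmiles(mol)
        fr = murcko_framework(mol)
        if fr is None or fr.canonical_smiles != canon:
            raise GeneratorError(f"template is not a pure framework: {smi!r}")
        if canon in seen:
            raise GeneratorError(f"duplicate template: {smi!r}")
        seen.add(canon)
        mw = Descriptors.MolWt(mol)
        if mw < mw_high - 15.0:  # must leave room for at least one substituent
            pool.append((canon, mol, mw))
    return pool


def _substituent_deltas(subs: Sequence[str]) -> list[tuple[str, float]]:
    """MW added by grafting each substituent onto an existing molecule."""
    out = []
    for smi in subs:
        m = Chem.MolFromSmiles(smi)
        if m is None or any(a.IsInRing() for a in m.GetAtoms()) and smi not in HARD_SUBSTITUENT_POOL:
            raise GeneratorError(f"bad substituent: {smi!r}")
        m = Chem.AddHs(m)
        out.append((smi, Descriptors.MolWt(m) - 2 * 1.008))
    return out


@lru_cache(maxsize=128)
def _sub_mol(sub_smiles: str) -> Chem.Mol:
    return Chem.MolFromSmiles(sub_smiles)


def _link(a: Chem.Mol, b: Chem.Mol, linker: str) -> Chem.Mol | None:
    """Join two frameworks through an unbranched acyclic linker.

    Attaches at the canonically-first open site of each piece, so the result
    is deterministic.  The product is again a pure Murcko framework: every
    linker atom lies on the path between the two ring systems.
    """
    sa = _open_sites(a)
    sb = _open_sites(b)
    if not sa or not sb:
        return None
    rw = Chem.RWMol(Chem.CombineMols(a, b))
    off = a.GetNumAtoms()
    if not linker:
        rw.AddBond(sa[0], off + sb[0], Chem.BondType.SINGLE)
    else:
        lm = _sub_mol(linker)
        loff = rw.GetMol().GetNumAtoms()
        rw = Chem.RWMol(Chem.CombineMols(rw.GetMol(), lm))
        rw.AddBond(sa[0], loff, Chem.BondType.SINGLE)
        rw.AddBond(off + sb[0], loff + lm.GetNumAtoms() - 1, Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Chem.rdchem.MolSanitizeException:
        return None
    return out


@lru_cache(maxsize=8)
def _extended_pool(mw_high: float, cap: int = 4000) -> tuple[tuple[str, Chem.Mol, float], ...]:
    """Base pool plus deterministic pairwise-linked frameworks, up to ``cap``."""
    base = list(_validated_pool_cached(mw_high))
    pool = list(base)
    seen = {c for c, _, _ in pool}
    for i, (_, ma, mwa) in enumerate(base):
        if len(pool) >= cap:
            break
        for j in range(i, len(base)):
            _, mb, mwb = base[j]
            if mwa + mwb > mw_high - 30.0:
                continue
            for linker in LINKER_POOL:
                combined = _link(ma, Chem.Mol(mb), linker)
                if combined is None:
                    continue
                mw = Descriptors.MolWt(combined)
                if mw >= mw_high - 15.0:
                    continue
                canon = Chem.MolToSmiles(combined)
                if canon in seen:
                    continue
                fr = murcko_framework(combined)
                if fr is None or fr.canonical_smiles != canon:
                    continue
                seen.add(canon)
                pool.append((canon, Chem.MolFromSmiles(canon), mw))
    return tuple(pool)


def _attach(mol: Chem.Mol, sub_smiles: str, site: int) -> Chem.Mol:
    sub = _sub_mol(sub_smiles)
    combined = Chem.RWMol(Chem.CombineMols(mol, sub))
    combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combined.GetMol()
    out.UpdatePropertyCache(strict=False)  # full sanitize deferred to re-parse
    return out


def _open_sites(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1 and a.GetAtomicNum() > 1]


def _decorate(
    base: Chem.Mol,
    base_mw: float,
    target: float,
    low: float,
    high: float,
    deltas: list[tuple[str, float]],
    rng: np.random.Generator,
    max_subs: int = 14,
) -> Chem.Mol | None:
    """Graft random substituents until MW sits in [low, high) near target.

    MW is tracked incrementally via the precomputed per-substituent deltas
    (exact: average molecular weight is additive once hydrogens are
    accounted for); a bad attachment can only fail at the final re-parse,
    handled by the caller's retry loop.
    """
    mol, mw = base, base_mw
    for _ in range(max_subs):
        if mw >= low and mw >= target - 25.0:
            break
        feasible = [
            (s, d) for s, d in deltas if mw + d < high - 0.5 and d < target - mw + 40.0
        ]
        sites = _open_sites(mol)
        if not feasible or not sites:
            break
        s, d = feasible[int(rng.integers(len(feasible)))]
        site = int(sites[int(rng.integers(len(sites)))])
        mol = _attach(mol, s, site)
        mw += d
    if low <= mw < high:
        return mol
    return None


def _allocate(n: int, weights: np.ndarray) -> list[int]:
    """Largest-remainder apportionment of n among len(weights), each >= 1."""
    k = len(weights)
    if n < k:
        raise GeneratorError(f"cannot give {k} scaffolds at least one of {n} molecules")
    raw = n * weights / weights.sum()
    counts = np.maximum(1, np.floor(raw).astype(int))
    remainders = raw - np.floor(raw)
    diff = n - int(counts.sum())
    order = sorted(range(k), key=lambda i: (-remainders[i], i))
    i = 0
    while diff > 0:
        counts[order[i % k]] += 1
        diff -= 1
        i += 1
    order_drop = sorted(range(k), key=lambda i: (remainders[i], -i))
    i = 0
    while diff < 0:
        j = order_drop[i % k]
        if counts[j] > 1:
            counts[j] -= 1
            diff += 1
        i += 1
    return [int(c) for c in counts]


def realized_frequencies(cfg: GeneratorConfig, n_ring: int) -> list[int]:
    """Molecule count per scaffold rank under the configured frequency model."""
    k = cfg.n_scaffolds
    if cfg.freq_model == "explicit":
        if cfg.explicit_freqs is None or len(cfg.explicit_freqs) != k:
            raise GeneratorError("explicit freq_model needs explicit_freqs of length n_scaffolds")
        if sum(cfg.explicit_freqs) != n_ring:
            raise GeneratorError("explicit_freqs must sum to the ring-bearing molecule count")
        return list(cfg.explicit_freqs)
    if cfg.freq_model == "uniform":
        weights = np.ones(k)
    else:
        weights = 1.0 / np.arange(1, k + 1, dtype=float) ** cfg.alpha
    return _allocate(n_ring, weights)


def expected_pc50c(freqs: Sequence[int]) -> float:
    """PC50C of the generating frequencies (labels are immaterial)."""
    ft = frequency_table(Counter({f"s{i:06d}": int(c) for i, c in enumerate(freqs)}))
    return pc50c(ft)


def generate(cfg: GeneratorConfig) -> tuple[LibrarySet, GroundTruth]:
    """Emit one synthetic library plus its ground truth.

    Deterministic: the same config (including seed) reproduces the same
    SMILES byte-for-byte.
    """
    rng = np.random.default_rng(cfg.seed)
    low, high = cfg.mw_range
    pool = list(_validated_pool_cached(high))
    if cfg.n_scaffolds > len(pool):
        pool = list(_extended_pool(high))
    if cfg.n_scaffolds > len(pool):
        raise GeneratorError(
            f"requested {cfg.n_scaffolds} scaffolds but only {len(pool)} templates fit MW < {high}"
        )
    if min(mw for _, _, mw in pool) >= high:
        raise GeneratorError("MW range infeasible for the template pool")

    n_acyclic = int(round(cfg.acyclic_fraction * cfg.n_molecules))
    n_ring = cfg.n_molecules - n_acyclic
    if n_ring < cfg.n_scaffolds:
        raise GeneratorError("too few ring-bearing molecules for the requested scaffold count")

    template_idx = rng.choice(len(pool), size=cfg.n_scaffolds, replace=False)
    templates = [pool[int(i)] for i in template_idx]
    freqs = realized_frequencies(cfg, n_ring)

    sub_pool = SUBSTITUENT_POOL + (HARD_SUBSTITUENT_POOL if cfg.hard_mode else ())
    deltas = _substituent_deltas(sub_pool)

    entries: list[tuple[str, str | None]] = []  # (smiles, label)
    for (canon, tmpl, tmpl_mw), count in zip(templates, freqs):
        if tmpl_mw >= high:
            raise GeneratorError(f"template {canon!r} already exceeds the MW ceiling")
        for _ in range(count):
            smi = None
            for _attempt in range(25):
                target = float(rng.uniform(low, high))
                target = max(target, tmpl_mw)
                mol = _decorate(tmpl, tmpl_mw, target, low, high, deltas, rng)
                if mol is None:
                    continue
                candidate = Chem.MolToSmiles(mol)
                parsed = Chem.MolFromSmiles(candidate)
                if parsed is not None and low <= Descriptors.MolWt(parsed) < high:
                    smi = Chem.MolToSmiles(parsed)
                    break
            if smi is None:
                raise GeneratorError(f"could not place template {canon!r} in MW range")
            entries.append((smi, canon))

    acyclic_deltas = _substituent_deltas(SUBSTITUENT_POOL)
    for _ in range(n_acyclic):
        smi = None
        for _attempt in range(25):
            base = _sub_mol(ACYCLIC_BASE_POOL[int(rng.integers(len(ACYCLIC_BASE_POOL)))])
            target = float(rng.uniform(low, min(high, 450.0)))
            mol = _decorate(base, Descriptors.MolWt(base), target, low, high, acyclic_deltas, rng)
            if mol is None:
                continue
            candidate = Chem.MolToSmiles(mol)
            parsed = Chem.MolFromSmiles(candidate)
            if parsed is not None and low <= Descriptors.MolWt(parsed) < high:
                smi = Chem.MolToSmiles(parsed)
                break
        if smi is None:
            raise GeneratorError("could not build an acyclic molecule in MW range")
        entries.append((smi, None))

    perm = rng.permutation(len(entries))
    entries = [entries[int(i)] for i in perm]

    records = []
    labels: list[str | None] = []
    for i, (smi, label) in enumerate(entries):
        mol = Chem.MolFromSmiles(smi)
        records.append(record_from_mol(mol, f"{cfg.name}-{i:06d}", cfg.name, sanitize=False))
        labels.append(label)

    lib = LibrarySet(name=cfg.name, records=records, provenance="synthetic")
    true_ft = frequency_table(Counter(l for l in labels if l is not None))
    truth = GroundTruth(
        labels=labels,
        templates=[t[0] for t in templates],
        true_frequencies=true_ft,
        expected_pc50c=pc50c(true_ft),
        n_acyclic=n_acyclic,
        config=cfg,
    )
    return lib, truth
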