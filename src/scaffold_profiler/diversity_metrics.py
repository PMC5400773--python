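"""Scaffold-frequency diversity statistics.

Given the multiset of scaffolds observed in a library, three related views
quantify how evenly molecules spread over scaffolds:

* the rank-sorted :class:`FrequencyTable` (scaffold -> occurrence count);
* the cumulative scaffold frequency plot (CSFP, a.k.a. cyclic system
  retrieval curve): cumulative percent of molecules covered (y) versus the
  percent — or count — of unique scaffolds consumed most-frequent-first (x);
* PC50C: the percentage of unique scaffolds needed to cover 50% of the
  molecules.  A perfectly even library (every scaffold once) scores 50;
  heavily skewed libraries score far lower.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class FrequencyTable:
    """Scaffold counts sorted by count descending, canonical form ascending."""

    entries: tuple[tuple[str, int], ...]
    n_molecules: int
    n_unique: int

    def counts(self) -> list[int]:
        return [c for _, c in self.entries]

    def scaffolds(self) -> list[str]:
        return [s for s, _ in self.entries]

    def top(self, k: int) -> list[tuple[str, int]]:
        return list(self.entries[:k])


@dataclass(frozen=True)
class CsfpCurve:
    """CSFP points; ``x`` per ``mode`` (percent of uniques, or rank count)."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    mode: str
    truncated: bool = False


def frequency_table(scaffolds: Iterable[str] | Counter) -> FrequencyTable:
    """Rank-sorted frequency table of a scaffold multiset."""
    counter = scaffolds if isinstance(scaffolds, Counter) else Counter(scaffolds)
    if not counter:
        raise ValueError("cannot build a frequency table from an empty multiset")
    entries = tuple(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))
    n_mol = sum(counter.values())
    return FrequencyTable(entries=entries, n_molecules=n_mol, n_unique=len(entries))


def csfp(ft: FrequencyTable, mode: str = "percent", truncate_at_singletons: bool = False) -> CsfpCurve:
    """Cumulative scaffold frequency curve.

    Point k (1-based) has x = 100*k/n_unique (``percent`` mode) or x = k
    (``count`` mode) and y = cumulative molecule coverage percent.  With
    ``truncate_at_singletons`` the curve stops where scaffold frequency
    drops from >= 2 to 1, the truncation used to de-clutter the long
    singleton tail.
    """
    if mode not in ("percent", "count"):
        raise ValueError(f"unknown CSFP mode {mode!r}")
    xs: list[float] = []
    ys: list[float] = []
    cum = 0
    truncated = False
    for k, (_, count) in enumerate(ft.entries, start=1):
        if truncate_at_singletons and count == 1 and k > 1:
            truncated = True
            break
        cum += count
        xs.append(100.0 * k / ft.n_unique if mode == "percent" else float(k))
        ys.append(100.0 * cum / ft.n_molecules)
    return CsfpCurve(x=tuple(xs), y=tuple(ys), mode=mode, truncated=truncated)


def pc50c(ft: FrequencyTable) -> float:
    """Percent of unique scaffolds covering 50% of the molecules.

    The smallest k whose cumulative coverage reaches >= 50% (no
    interpolation), expressed as 100*k/n_unique.  Degenerate single-scaffold
    tables return 100, outside the statistic's intended regime.
    """
    half = ft.n_molecules / 2.0
    cum = 0
    for k, (_, count) in enumerate(ft.entries, start=1):
        cum += count
        if cum >= half:
            return 100.0 * k / ft.n_unique
    return 100.0  # unreachable for a valid table; defensive


def top_k_coverage(ft: FrequencyTable, k: int) -> float:
    """Percent of molecules carried by the k most frequent scaffolds."""
    if k < 1:
        raise ValueError("k must be >= 1")
    covered = sum(c for _, c in ft.entries[:k])
    return 100.0 * covered / ft.n_molecules


def diversity_report(scaffolds: Iterable[str] | Counter, top_k: int = 10) -> dict:
    """JSON-ready bundle: table sizes, PC50C, top-k coverage, CSFP points."""
    ft = frequency_table(scaffolds)
    curve = csfp(ft, mode="percent")
    return {
        "n_molecules": ft.n_molecules,
        "n_unique": ft.n_unique,
        "pc50c": pc50c(ft),
        "top_k": top_k,
        "top_k_coverage": top_k_coverage(ft, top_k),
        "top_scaffolds": [{"smiles": s, "count": c} for s, c in ft.top(top_k)],
        "csfp": {"x": list(curve.x), "y": list(curve.y), "mode": curve.mode},
    }
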