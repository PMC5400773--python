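"""MW-distribution-matched subset construction.

Scaffold counts are confounded by molecular weight: heavier molecules carry
more rings and fragments.  Before comparing libraries we therefore draw
random subsets whose MW histograms are *exactly* equal at a fixed bin
resolution: within every bin the target count is the minimum over libraries,
and each library contributes exactly that many molecules, sampled uniformly
without replacement.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .library_io import LibrarySet, MoleculeRecord


@dataclass(frozen=True)
class MwBinningScheme:
    """Half-open MW bins ``[low + k*width, low + (k+1)*width)`` in Da."""

    low: float = 100.0
    high: float = 700.0
    width: float = 100.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low must be < high")
        n = (self.high - self.low) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(high - low) must be divisible by width")

    @property
    def n_bins(self) -> int:
        return int(round((self.high - self.low) / self.width))

    def bin_index(self, mw: float) -> int | None:
        """Bin index for ``mw``, or None when outside ``[low, high)``."""
        if mw < self.low or mw >= self.high:
            return None
        return int((mw - self.low) // self.width)

    def bin_label(self, k: int) -> str:
        lo = self.low + k * self.width
        return f"[{lo:g},{lo + self.width:g})"


@dataclass
class StandardizedSubset:
    source: str
    records: list[MoleculeRecord]
    per_bin_counts: dict[int, int]
    seed: int

    def __len__(self) -> int:
        return len(self.records)


def bin_counts(lib: LibrarySet, scheme: MwBinningScheme) -> dict[int, int]:
    """Molecule counts per MW bin; out-of-range molecules contribute nowhere."""
    counts = {k: 0 for k in range(scheme.n_bins)}
    for rec in lib.records:
        k = scheme.bin_index(rec.mw)
        if k is not None:
            counts[k] += 1
    return counts


def _substream(seed: int, library: str, bin_index: int) -> np.random.Generator:
    # Per-(library, bin) substreams keyed on a stable name hash, so adding or
    # reordering libraries never perturbs another library's sample.
    tag = zlib.crc32(library.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, tag, bin_index]))


def standardize(
    libs: list[LibrarySet], scheme: MwBinningScheme, seed: int
) -> list[StandardizedSubset]:
    """Build one MW-matched subset per library.

    For each bin the target is the minimum count over libraries; every
    subset receives exactly that many molecules from its library's bin,
    drawn uniformly without replacement.  Deterministic under ``seed``.
    """
    if len(libs) < 2:
        raise ValueError("standardization needs at least 2 libraries")
    all_counts = [bin_counts(lib, scheme) for lib in libs]
    targets = {
        k: min(c[k] for c in all_counts) for k in range(scheme.n_bins)
    }
    if all(t == 0 for t in targets.values()):
        raise ValueError("no overlapping MW support across libraries")

    subsets = []
    for lib in libs:
        by_bin: dict[int, list[int]] = {k: [] for k in range(scheme.n_bins)}
        for i, rec in enumerate(lib.records):
            k = scheme.bin_index(rec.mw)
            if k is not None:
                by_bin[k].append(i)
        chosen: list[int] = []
        for k in range(scheme.n_bins):
            if targets[k] == 0:
                continue
            rng = _substream(seed, lib.name, k)
            picks = rng.choice(len(by_bin[k]), size=targets[k], replace=False)
            chosen.extend(by_bin[k][p] for p in sorted(picks))
        chosen.sort()  # preserve the library's record order
        subsets.append(
            StandardizedSubset(
                source=lib.name,
                records=[lib.records[i] for i in chosen],
                per_bin_counts=dict(targets),
                seed=seed,
            )
        )
    return subsets


def manifest(
    libs: list[LibrarySet], subsets: list[StandardizedSubset], scheme: MwBinningScheme
) -> dict:
    """JSON-ready record of input counts, targets and subset sizes."""
    inputs = {lib.name: bin_counts(lib, scheme) for lib in libs}
    targets = subsets[0].per_bin_counts if subsets else {}
    return {
        "scheme": {"low": scheme.low, "high": scheme.high, "width": scheme.width},
        "bins": {scheme.bin_label(k): k for k in range(scheme.n_bins)},
        "input_counts": {
            name: {scheme.bin_label(k): v for k, v in c.items()}
            for name, c in inputs.items()
        },
        "targets": {scheme.bin_label(k): v for k, v in targets.items()},
        "subset_sizes": {s.source: len(s) for s in subsets},
        "seed": subsets[0].seed if subsets else None,
    }
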