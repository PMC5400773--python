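"""Structural-similarity analytics over scaffolds and molecules.

Circular fingerprints (Morgan radius 2, 2048 bits — the ECFP_4 equivalent)
feed four analyses:

* order-dependent leader clustering with two recentering passes, reporting
  each member's Tanimoto distance to its cluster center (DTC);
* Tree-Map layout export (area proportional to scaffold frequency, color
  from DTC on a red→white→green scale) plus the "Forest Coverage" share of
  high-DTC area;
* OptiSim diverse-subset selection with an exclusion radius;
* Sammon-style nonlinear mapping (NLM) of a pairwise-distance matrix into
  2D, with a dissimilarity *horizon* capping long distances and a
  *singleton radius* flagging neighbour-less compounds, followed by greedy
  dense-area extraction at a similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .diversity_metrics import FrequencyTable
from .library_io import LibrarySet, MoleculeRecord

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


# --------------------------------------------------------------------------
# fingerprints and distances

def fingerprint(mol: Chem.Mol | str) -> DataStructs.ExplicitBitVect:
    """Morgan radius-2, 2048-bit fingerprint; deterministic per structure."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    return _MORGAN.GetFingerprint(mol)


def tanimoto_distance(a: DataStructs.ExplicitBitVect, b: DataStructs.ExplicitBitVect) -> float:
    """1 − Tanimoto similarity; two all-zero vectors are at distance 0."""
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError("fingerprint lengths differ")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return 1.0 - DataStructs.TanimotoSimilarity(a, b)


def distance_matrix(fps: Sequence[DataStructs.ExplicitBitVect]) -> np.ndarray:
    """Symmetric pairwise Tanimoto distance matrix."""
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        if fps[i].GetNumOnBits() == 0:
            sims = [1.0 if fps[j].GetNumOnBits() == 0 else 0.0 for j in range(i + 1, n)]
        else:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], list(fps[i + 1:]))
        for k, s in enumerate(sims):
            d[i, i + 1 + k] = d[i + 1 + k, i] = 1.0 - s
    return d


# --------------------------------------------------------------------------
# leader clustering with recentering

@dataclass
class Cluster:
    center: int                      # index into the input sequence
    members: list[int]
    dtc: dict[int, float] = field(default_factory=dict)
    order_index: int = 0

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    labels: list[str]                # canonical structure per input index
    threshold: float
    recenter_passes: int

    def assignment(self) -> dict[int, int]:
        return {m: ci for ci, cl in enumerate(self.clusters) for m in cl.members}

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def total_within_distance(self, dist: np.ndarray) -> float:
        return float(
            sum(dist[m, cl.center] for cl in self.clusters for m in cl.members)
        )


def _recenter_once(clusters: list[list[int]], dist: np.ndarray) -> tuple[list[int], list[list[int]]]:
    """One recentering pass: medoid update then nearest-center reassignment."""
    centers = []
    for members in clusters:
        best = min(members, key=lambda m: (sum(dist[m, o] for o in members), m))
        centers.append(best)
    new_members: list[list[int]] = [[] for _ in centers]
    n = dist.shape[0]
    for i in range(n):
        ci = min(range(len(centers)), key=lambda c: (dist[i, centers[c]], c))
        new_members[ci].append(i)
    keep = [k for k, mem in enumerate(new_members) if mem]
    return [centers[k] for k in keep], [new_members[k] for k in keep]


def leader_cluster(
    items: Sequence[str] | Sequence[Chem.Mol],
    threshold: float = 0.6,
    recenter_passes: int = 2,
    fps: Sequence[DataStructs.ExplicitBitVect] | None = None,
    dist: np.ndarray | None = None,
) -> ClusterSet:
    """Leader clustering in input order, healed by recentering passes.

    A new item joins the first existing cluster whose center is nearer than
    ``threshold``, else founds a new cluster.  Each recentering pass moves
    every center to its cluster medoid and reassigns all items to their
    nearest center.  Deterministic for a fixed input order.
    """
    if len(items) == 0:
        raise ValueError("nothing to cluster")
    labels = [it if isinstance(it, str) else Chem.MolToSmiles(it) for it in items]
    if dist is None:
        if fps is None:
            fps = [fingerprint(it) for it in items]
        dist = distance_matrix(fps)

    centers: list[int] = []
    members: list[list[int]] = []
    for i in range(len(labels)):
        placed = False
        for c, center in enumerate(centers):
            if dist[i, center] < threshold:
                members[c].append(i)
                placed = True
                break
        if not placed:
            centers.append(i)
            members.append([i])

    for _ in range(recenter_passes):
        centers, members = _recenter_once(members, dist)

    clusters = []
    for k, (c, mem) in enumerate(zip(centers, members)):
        dtc = {m: float(dist[m, c]) for m in mem}
        clusters.append(Cluster(center=c, members=mem, dtc=dtc, order_index=k))
    clusters.sort(key=lambda cl: (-cl.size, cl.center))
    for k, cl in enumerate(clusters):
        cl.order_index = k
    return ClusterSet(
        clusters=clusters, labels=labels, threshold=threshold, recenter_passes=recenter_passes
    )


# --------------------------------------------------------------------------
# Tree-Map export and Forest Coverage

def _dtc_color(t: float) -> tuple[int, int, int]:
    """Linear red (t=0) → white (t=0.5) → green (t=1) ramp."""
    red, white, green = (220, 30, 30), (255, 255, 255), (20, 120, 40)
    if t <= 0.5:
        f = t / 0.5
        a, b = red, white
    else:
        f = (t - 0.5) / 0.5
        a, b = white, green
    return tuple(int(round(a[i] + f * (b[i] - a[i]))) for i in range(3))


def treemap_export(clusters: ClusterSet, frequencies: FrequencyTable) -> dict:
    """Hierarchical cluster→scaffold layout table for any treemap renderer.

    Circle areas are the scaffold frequencies (proportionality is exact);
    colors map DTC linearly with red at 0, white at the midpoint and green
    at the maximum observed DTC.
    """
    freq = dict(frequencies.entries)
    missing = [s for s in clusters.labels if s not in freq]
    if missing:
        raise ValueError(f"no frequency for {len(missing)} scaffold(s), e.g. {missing[0]!r}")
    max_dtc = max((d for cl in clusters.clusters for d in cl.dtc.values()), default=0.0)
    out_clusters = []
    for cl in clusters.clusters:
        children = []
        for m in sorted(cl.members):
            dtc = cl.dtc[m]
            t = dtc / max_dtc if max_dtc > 0 else 0.0
            children.append(
                {
                    "smiles": clusters.labels[m],
                    "frequency": freq[clusters.labels[m]],
                    "area": float(freq[clusters.labels[m]]),
                    "dtc": dtc,
                    "color_value": t,
                    "color_rgb": _dtc_color(t),
                }
            )
        out_clusters.append(
            {
                "order_index": cl.order_index,
                "center": clusters.labels[cl.center],
                "size": cl.size,
                "total_frequency": sum(c["frequency"] for c in children),
                "children": children,
            }
        )
    return {
        "max_dtc": max_dtc,
        "color_scale": {"low": "red", "mid": "white", "high": "green"},
        "clusters": out_clusters,
    }


def forest_coverage(
    clusters: ClusterSet,
    cutoff_fraction: float = 0.75,
    frequencies: FrequencyTable | None = None,
) -> float:
    """Percent of (frequency-weighted) scaffolds in the deep-green DTC band.

    A scaffold counts when its DTC >= cutoff_fraction * max observed DTC.
    With every DTC at zero there is no green at all (0%); a zero cutoff
    degenerates to 100%.
    """
    if cutoff_fraction == 0:
        return 100.0
    freq = dict(frequencies.entries) if frequencies is not None else None
    weights, flags = [], []
    for cl in clusters.clusters:
        for m in cl.members:
            w = freq[clusters.labels[m]] if freq is not None else 1.0
            weights.append(w)
            flags.append(cl.dtc[m])
    max_dtc = max(flags, default=0.0)
    if max_dtc == 0:
        return 0.0
    cut = cutoff_fraction * max_dtc
    covered = sum(w for w, d in zip(weights, flags) if d >= cut)
    return 100.0 * covered / sum(weights)


# --------------------------------------------------------------------------
# OptiSim selection

def optisim_select(
    items: Sequence,
    subsample_size: int = 10,
    radius: float = 0.3,
    seed: int = 0,
    fps: Sequence[DataStructs.ExplicitBitVect] | None = None,
    dist: np.ndarray | None = None,
) -> list[int]:
    """OptiSim diverse-representative selection; returns selected indices.

    Iteratively draws up to ``subsample_size`` random candidates that are
    not within ``radius`` of any already-selected item (closer candidates
    are permanently discarded), then keeps the candidate most dissimilar to
    the current selection (max–min distance).  Deterministic under ``seed``;
    the selected set contains no pair closer than ``radius``.
    """
    n = len(items)
    if n == 0:
        raise ValueError("nothing to select from")
    if dist is None:
        if fps is None:
            fps = [fingerprint(it) for it in items]
        dist = distance_matrix(fps)
    rng = np.random.default_rng(seed)

    pool = list(range(n))
    first = int(pool.pop(rng.integers(len(pool))))
    selected = [first]
    while pool:
        candidates: list[int] = []
        while pool and len(candidates) < subsample_size:
            i = int(pool.pop(rng.integers(len(pool))))
            if min(dist[i, s] for s in selected) < radius:
                continue  # inside the exclusion radius: discard permanently
            candidates.append(i)
        if not candidates:
            break
        best = max(candidates, key=lambda i: (min(dist[i, s] for s in selected), -i))
        selected.append(best)
        candidates.remove(best)
        pool.extend(candidates)
    return selected


# --------------------------------------------------------------------------
# nonlinear mapping (Sammon) and dense areas

@dataclass
class Embedding2D:
    coords: np.ndarray               # (n, 2)
    stress: float
    stress_history: list[float]
    singletons: list[int]
    horizon: float
    singleton_radius: float


def _sammon_stress_grad(
    coords: np.ndarray, d_target: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    diff = coords[:, None, :] - coords[None, :, :]
    d_emb = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d_emb, 1.0)
    scale = (w * d_target).sum()
    err = d_emb - d_target
    stress = float((w * err ** 2 / d_target).sum() / scale)
    coef = 2.0 * w * err / (d_target * np.maximum(d_emb, 1e-12)) / scale
    np.fill_diagonal(coef, 0.0)
    grad = (coef[:, :, None] * diff).sum(axis=1)
    return stress, grad


def nlm_project(
    dist: np.ndarray,
    horizon: float = 0.3,
    singleton_radius: float = 0.3,
    max_iter: int = 300,
    seed: int = 0,
    beyond_weight: float = 0.1,
    tol: float = 1e-12,
) -> Embedding2D:
    """Sammon-style 2D projection of a pairwise dissimilarity matrix.

    Pairs farther apart than ``horizon`` are capped at the horizon value and
    down-weighted by ``beyond_weight`` — beyond the horizon plotted
    distances are not to scale.  Compounds with no neighbour within
    ``singleton_radius`` are flagged singletons and started on the embedding
    periphery.  Optimisation is gradient descent with a backtracking step,
    so the reported stress history is non-increasing.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    n = dist.shape[0]
    rng = np.random.default_rng(seed)

    offdiag = dist + np.diag(np.full(n, np.inf))
    singletons = [i for i in range(n) if offdiag[i].min() > singleton_radius]

    w = np.where(dist > horizon, beyond_weight, 1.0)
    np.fill_diagonal(w, 0.0)
    d_target = np.minimum(dist, horizon)
    d_target = np.maximum(d_target, 1e-9)  # duplicates: avoid /0
    np.fill_diagonal(d_target, 1.0)        # masked by zero weight

    if n == 1:
        return Embedding2D(np.zeros((1, 2)), 0.0, [0.0], singletons, horizon, singleton_radius)

    # classical-MDS initialisation on the capped distances (deterministic),
    # plus a tiny seeded jitter to break exact degeneracies
    d2 = np.minimum(dist, horizon) ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:2]
    coords = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    coords = coords + rng.normal(0.0, 1e-9, coords.shape)
    if singletons and len(singletons) < n:
        r = 1.2 * max(np.linalg.norm(coords, axis=1).max(), 1.0)
        for k, i in enumerate(singletons):
            ang = 2.0 * np.pi * k / len(singletons)
            coords[i] = (r * np.cos(ang), r * np.sin(ang))

    if w.sum() == 0:  # every pair beyond a zero-weight horizon: nothing to fit
        return Embedding2D(coords, 0.0, [0.0], singletons, horizon, singleton_radius)

    stress, grad = _sammon_stress_grad(coords, d_target, w)
    history = [stress]
    step = 0.1
    for _ in range(max_iter):
        moved = False
        for _ in range(40):
            trial = coords - step * grad
            s_new, g_new = _sammon_stress_grad(trial, d_target, w)
            if s_new < stress:
                coords, stress, grad = trial, s_new, g_new
                step *= 1.2
                moved = True
                break
            step *= 0.5
        history.append(stress)
        if not moved or (len(history) > 1 and history[-2] - history[-1] < tol):
            break
    return Embedding2D(coords, stress, history, singletons, horizon, singleton_radius)


def dense_areas(
    emb: Embedding2D | None,
    fps: Sequence[DataStructs.ExplicitBitVect],
    sim_threshold: float = 0.8,
    min_members: int = 3,
) -> list[dict]:
    """Greedy extraction of mutually similar molecule groups.

    Repeatedly picks the unassigned molecule with the most unassigned
    neighbours at Tanimoto similarity >= ``sim_threshold`` as a group
    center; stops when the best remaining group is smaller than
    ``min_members``.  Groups are disjoint.  ``emb`` is only used to attach
    map coordinates to the report and may be None.
    """
    n = len(fps)
    sim = 1.0 - distance_matrix(fps)
    unassigned = set(range(n))
    groups: list[dict] = []
    while True:
        best_center, best_nbrs = None, None
        for i in sorted(unassigned):
            nbrs = [j for j in unassigned if j != i and sim[i, j] >= sim_threshold]
            if best_nbrs is None or len(nbrs) > len(best_nbrs):
                best_center, best_nbrs = i, nbrs
        if best_center is None or 1 + len(best_nbrs) < min_members:
            break
        members = [best_center] + best_nbrs
        group = {"center": best_center, "members": members}
        if emb is not None:
            group["center_xy"] = tuple(float(v) for v in emb.coords[best_center])
        groups.append(group)
        unassigned -= set(members)
    return groups


# --------------------------------------------------------------------------
# substructure search

def substructure_hits(lib: LibrarySet, query_scaffolds: Iterable[str | Chem.Mol]) -> LibrarySet:
    """Molecules containing at least one query as a subgraph, deduplicated."""
    queries = []
    for q in query_scaffolds:
        qm = Chem.MolFromSmiles(q) if isinstance(q, str) else q
        if qm is None:
            raise ValueError(f"unparseable query: {q!r}")
        queries.append(qm)
    hits: list[MoleculeRecord] = []
    seen: set[str] = set()
    for rec in lib.records:
        if rec.mol_id in seen:
            continue
        if any(rec.mol.HasSubstructMatch(q) for q in queries):
            hits.append(rec)
            seen.add(rec.mol_id)
    return LibrarySet(name=f"{lib.name}-hits", records=hits, provenance=lib.provenance)
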