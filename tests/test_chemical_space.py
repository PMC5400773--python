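from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from rdkit import DataStructs

from scaffold_profiler.chemical_space import (
    dense_areas,
    distance_matrix,
    fingerprint,
    forest_coverage,
    leader_cluster,
    nlm_project,
    optisim_select,
    substructure_hits,
    tanimoto_distance,
    treemap_export,
)
from scaffold_profiler.diversity_metrics import frequency_table
from scaffold_profiler.library_io import library_from_smiles

from conftest import canon


def _bv(bits, n=64):
    v = DataStructs.ExplicitBitVect(n)
    for b in bits:
        v.SetBit(b)
    return v


# --------------------------------------------------------------------- fingerprints

def test_fingerprint_identity_and_discrimination():
    assert tanimoto_distance(fingerprint("c1ccccc1"), fingerprint("c1ccccc1")) == 0.0
    assert tanimoto_distance(fingerprint("c1ccccc1"), fingerprint("C1CCCCC1")) > 0.0
    # disjoint hashed features: methane vs water share nothing
    assert tanimoto_distance(fingerprint("C"), fingerprint("O")) == 1.0


def test_tanimoto_distance_formula_and_conventions():
    a = _bv([0, 1, 2])
    b = _bv([2, 3])          # intersection 1, union 4 -> distance 3/4
    assert tanimoto_distance(a, b) == pytest.approx(0.75)
    assert tanimoto_distance(_bv([1]), _bv([2])) == 1.0
    assert tanimoto_distance(_bv([]), _bv([])) == 0.0  # both-empty convention
    with pytest.raises(ValueError):
        tanimoto_distance(_bv([0], n=64), _bv([0], n=128))


def test_distance_matrix_symmetric_zero_diagonal():
    fps = [fingerprint(s) for s in ["c1ccccc1", "Cc1ccccc1", "CCO"]]
    d = distance_matrix(fps)
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    assert d[0, 1] < d[0, 2]  # toluene closer to benzene than ethanol is


# --------------------------------------------------------------------- clustering

def _planted_two_group_fps():
    # group 1 shares bits 0..19, group 2 shares 40..59; one private bit each
    g1 = [_bv(list(range(20)) + [30 + i]) for i in range(4)]
    g2 = [_bv(list(range(40, 60)) + [62 - i % 2]) for i in range(3)]
    labels = [f"g1_{i}" for i in range(4)] + [f"g2_{i}" for i in range(3)]
    return labels, g1 + g2


def test_leader_cluster_identical_items_single_cluster():
    fps = [_bv([1, 2, 3])] * 3
    cs = leader_cluster(["a", "b", "c"], threshold=0.5, fps=fps)
    assert cs.n_clusters == 1
    assert all(d == 0.0 for cl in cs.clusters for d in cl.dtc.values())


def test_leader_cluster_planted_two_groups_and_partition():
    labels, fps = _planted_two_group_fps()
    cs = leader_cluster(labels, threshold=0.6, fps=fps)
    assert cs.n_clusters == 2
    assign = cs.assignment()
    assert len(assign) == len(labels)  # every item in exactly one cluster
    g1 = {assign[i] for i in range(4)}
    g2 = {assign[i] for i in range(4, 7)}
    assert len(g1) == len(g2) == 1 and g1 != g2
    assert all(0.0 <= d <= 1.0 for cl in cs.clusters for d in cl.dtc.values())


def test_leader_cluster_order_independent_for_separated_groups():
    labels, fps = _planted_two_group_fps()
    base = leader_cluster(labels, threshold=0.6, fps=fps)
    order = [3, 5, 0, 6, 1, 4, 2]
    cs = leader_cluster([labels[i] for i in order], threshold=0.6,
                        fps=[fps[i] for i in order])
    def partition(c):
        return {frozenset(c.labels[m] for m in cl.members) for cl in c.clusters}
    assert partition(cs) == partition(base)


def test_recentering_never_increases_within_cluster_distance():
    labels, fps = _planted_two_group_fps()
    d = distance_matrix(fps)
    totals = [
        leader_cluster(labels, threshold=0.6, recenter_passes=p, dist=d)
        .total_within_distance(d)
        for p in range(4)
    ]
    for a, b in zip(totals, totals[1:]):
        assert b <= a + 1e-12


# --------------------------------------------------------------------- treemap / FC

def test_treemap_area_proportionality_and_colors():
    fps = [_bv([1, 2, 3]), _bv([1, 2, 3, 4])]
    cs = leader_cluster(["A", "B"], threshold=0.9, fps=fps)
    ft = frequency_table(Counter({"A": 3, "B": 1}))
    layout = treemap_export(cs, ft)
    children = {c["smiles"]: c for cl in layout["clusters"] for c in cl["children"]}
    assert children["A"]["area"] / children["B"]["area"] == pytest.approx(3.0)
    per_cluster = layout["clusters"][0]
    assert per_cluster["total_frequency"] == sum(c["frequency"] for c in per_cluster["children"])
    center = next(c for c in children.values() if c["dtc"] == 0.0)
    assert center["color_rgb"] == (220, 30, 30)          # red endpoint
    top = max(children.values(), key=lambda c: c["dtc"])
    if layout["max_dtc"] > 0:
        assert top["color_rgb"] == (20, 120, 40)         # green endpoint


def test_treemap_missing_frequency_fatal():
    fps = [_bv([1])]
    cs = leader_cluster(["A"], threshold=0.5, fps=fps)
    with pytest.raises(ValueError):
        treemap_export(cs, frequency_table(Counter({"B": 1})))


def test_forest_coverage_bounds():
    fps = [_bv([1, 2, 3])] * 3
    cs = leader_cluster(["a", "b", "c"], threshold=0.5, fps=fps)
    assert forest_coverage(cs) == 0.0                 # all DTC zero: no green
    assert forest_coverage(cs, cutoff_fraction=0.0) == 100.0
    labels, pfps = _planted_two_group_fps()
    cs2 = leader_cluster(labels, threshold=0.6, fps=pfps)
    fc = forest_coverage(cs2)
    assert 0.0 <= fc <= 100.0


# --------------------------------------------------------------------- OptiSim

def test_optisim_identical_items_selects_one():
    d = np.zeros((5, 5))
    assert optisim_select(list(range(5)), radius=0.3, seed=1, dist=d) == pytest.approx([0]) or \
        len(optisim_select(list(range(5)), radius=0.3, seed=1, dist=d)) == 1


def test_optisim_all_far_selects_all_and_radius_separation():
    rng = np.random.default_rng(0)
    n = 12
    far = np.full((n, n), 0.9)
    np.fill_diagonal(far, 0.0)
    assert len(optisim_select(list(range(n)), radius=0.3, seed=2, dist=far)) == n

    # random geometry: selected set must be radius-separated and deterministic
    pts = rng.random((30, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    sel = optisim_select(list(range(30)), subsample_size=5, radius=0.25, seed=7, dist=d)
    for i in sel:
        for j in sel:
            if i != j:
                assert d[i, j] >= 0.25
    assert sel == optisim_select(list(range(30)), subsample_size=5, radius=0.25, seed=7, dist=d)


# --------------------------------------------------------------------- NLM

def test_nlm_two_points_recover_distance():
    d = np.array([[0.0, 0.2], [0.2, 0.0]])
    emb = nlm_project(d, horizon=1.0, seed=1)
    got = np.linalg.norm(emb.coords[0] - emb.coords[1])
    assert got == pytest.approx(0.2, abs=1e-4)


def test_nlm_equilateral_triangle_embeds_exactly():
    d = np.full((3, 3), 0.25)
    np.fill_diagonal(d, 0.0)
    emb = nlm_project(d, horizon=1.0, seed=0)
    assert emb.stress < 1e-8


def test_nlm_planar_selfrecovery_and_monotone_stress():
    rng = np.random.default_rng(42)
    pts = rng.random((10, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    emb = nlm_project(d, horizon=10.0, singleton_radius=10.0, seed=3)
    assert emb.stress < 1e-6
    tri = np.triu_indices(10, 1)
    emb_d = np.sqrt(((emb.coords[:, None] - emb.coords[None]) ** 2).sum(-1))
    corr = np.corrcoef(d[tri], emb_d[tri])[0, 1]
    assert corr > 0.99
    assert all(b <= a + 1e-15 for a, b in zip(emb.stress_history, emb.stress_history[1:]))


def test_nlm_singleton_flagging_and_validation():
    d = np.array(
        [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]
    )
    emb = nlm_project(d, horizon=1.0, singleton_radius=0.3, seed=0)
    assert emb.singletons == [2]
    with pytest.raises(ValueError):
        nlm_project(np.array([[0.0, 0.5], [0.4, 0.0]]))
    with pytest.raises(ValueError):
        nlm_project(np.array([[0.1, 0.5], [0.5, 0.0]]))


# --------------------------------------------------------------------- dense areas

def test_dense_areas_identical_set_and_empty():
    fps = [_bv([1, 2, 3])] * 5
    groups = dense_areas(None, fps, sim_threshold=0.8, min_members=3)
    assert len(groups) == 1 and len(groups[0]["members"]) == 5

    lone = [_bv([i * 3, i * 3 + 1]) for i in range(5)]
    assert dense_areas(None, lone, sim_threshold=0.8, min_members=2) == []


def test_dense_areas_recover_planted_cliques():
    cliques = []
    for base in (0, 20, 40):
        cliques.extend(_bv(list(range(base, base + 10))) for _ in range(4))
    noise = [_bv([55 + 2 * i]) for i in range(5)]
    groups = dense_areas(None, cliques + noise, sim_threshold=0.8, min_members=3)
    assert len(groups) == 3
    covered = sorted(m for g in groups for m in g["members"])
    assert covered == list(range(12))


# --------------------------------------------------------------------- substructure

def test_substructure_hits_union_dedup():
    lib = library_from_smiles(
        [("Cc1ccccc1", "tol"), ("CCCCCC", "hex"), ("c1ccc2ccccc2c1", "naph")], "lib"
    )
    hits = substructure_hits(lib, ["c1ccccc1"])
    assert [r.mol_id for r in hits.records] == ["tol", "naph"]
    # a molecule matches itself; overlapping queries count once
    hits2 = substructure_hits(lib, ["c1ccccc1", "Cc1ccccc1"])
    assert [r.mol_id for r in hits2.records] == ["tol", "naph"]
    assert canon("Cc1ccccc1") in hits2.smiles()
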