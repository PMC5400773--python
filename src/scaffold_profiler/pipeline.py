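"""End-to-end comparative scaffold-diversity workflow.

ingest → preprocess → MW-standardize → fragment → scaffold-tree →
diversity statistics → Level-1 scaffold clustering / Tree-Map →
OptiSim + NLM chemical-space map → cross-library shared-scaffold table.

All stages are driven by one :class:`RunConfig`; every source of randomness
derives from its seeds, so a rerun with the same config yields an identical
report.  Stage outputs are plain JSON/TSV files, independently inspectable.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import chemical_space as cs
from . import diversity_metrics as dm
from . import fragmentation as fg
from . import standardization as std
from . import synthetic_library as synth
from .scaffold_tree import (
    LevelInventory,
    level_inventory,
    rose_map_table,
    scaffold_tree as build_scaffold_tree,
)
from .library_io import LibrarySet, preprocess, read_library, write_library

logger = logging.getLogger("scaffold_profiler")


class PipelineError(RuntimeError):
    """Fatal failure, tagged with the stage that raised it."""


@dataclass
class RunConfig:
    """Validated configuration of one comparative run (YAML-serializable).

    ``libraries`` entries are dicts: either ``{"name", "path", "fmt"}`` for
    files on disk or ``{"synthetic": {...GeneratorConfig fields...}}``.
    """

    libraries: list[dict] = field(default_factory=list)
    mw_low: float = 100.0
    mw_high: float = 700.0
    mw_width: float = 100.0
    standardize: bool = True
    fragment_kinds: tuple[str, ...] = fg.KINDS
    cluster_threshold: float = 0.6
    recenter_passes: int = 2
    top_k: int = 10
    sarmap: bool = True
    sarmap_max_points: int = 300
    optisim_subsample: int = 10
    optisim_radius: float = 0.3
    nlm_horizon: float = 0.3
    nlm_singleton_radius: float = 0.3
    dense_sim_threshold: float = 0.8
    dense_min_members: int = 3
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.libraries:
            raise ValueError("config lists no libraries")
        unknown = set(self.fragment_kinds) - set(fg.KINDS)
        if unknown:
            raise ValueError(f"unknown fragment kinds: {sorted(unknown)}")
        self.fragment_kinds = tuple(self.fragment_kinds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fragment_kinds"] = list(self.fragment_kinds)
        return d


def _ingest(spec: dict, seed: int) -> tuple[LibrarySet, synth.GroundTruth | None]:
    if "synthetic" in spec:
        params = dict(spec["synthetic"])
        params.setdefault("seed", seed)
        cfg = synth.GeneratorConfig(**params)
        lib, truth = synth.generate(cfg)
        return lib, truth
    lib = read_library(spec["path"], spec.get("fmt", "sdf"), name=spec.get("name"))
    return lib, None


def _library_section(
    records: list, name: str, cfg: RunConfig, lib_seed: int
) -> tuple[dict, dict]:
    """Per-library analytics; returns (report section, cross-library handles)."""
    section: dict[str, Any] = {"n_molecules": len(records)}
    handles: dict[str, Any] = {}

    inv = fg.inventory(LibrarySet(name=name, records=list(records)), cfg.fragment_kinds, name=name)
    section["fragments"] = {
        "totals": dict(inv.totals),
        "uniques": dict(inv.uniques),
        "acyclic_pct": inv.acyclic_pct,
    }

    trees = []
    for rec in records:
        t = build_scaffold_tree(rec)
        if t is not None:
            trees.append(t)
    linv = level_inventory(records, trees=trees, name=name)
    section["scaffold_tree_levels"] = linv.as_table()
    handles["level_inventory"] = linv

    if not trees:
        section["diversity"] = {"no_scaffolds": True}
        section["clustering"] = {"no_scaffolds": True}
        return section, handles

    murcko_scaffolds = []
    for rec in records:
        fr = fg.murcko_framework(rec.mol, rec.mol_id)
        if fr is not None:
            murcko_scaffolds.append(fr.canonical_smiles)
    level1 = [t.level1_scaffold() for t in trees]

    section["diversity"] = {
        "murcko": dm.diversity_report(murcko_scaffolds, top_k=cfg.top_k),
        "st_level1": dm.diversity_report(level1, top_k=cfg.top_k),
        "acyclic_pct": inv.acyclic_pct,
    }

    ft_level1 = dm.frequency_table(level1)
    unique_level1 = ft_level1.scaffolds()
    fps = [cs.fingerprint(s) for s in unique_level1]
    dist = cs.distance_matrix(fps)
    clusters = cs.leader_cluster(
        unique_level1,
        threshold=cfg.cluster_threshold,
        recenter_passes=cfg.recenter_passes,
        dist=dist,
    )
    treemap = cs.treemap_export(clusters, ft_level1)
    fc = cs.forest_coverage(clusters, frequencies=ft_level1)
    section["clustering"] = {
        "n_clusters": clusters.n_clusters,
        "forest_coverage_pct": fc,
        "max_dtc": treemap["max_dtc"],
        "top_cluster_centers": [
            clusters.labels[cl.center] for cl in clusters.clusters[: cfg.top_k]
        ],
    }
    handles["treemap"] = treemap
    handles["top_frequent"] = [s for s, _ in ft_level1.top(cfg.top_k)]
    handles["top_centers"] = section["clustering"]["top_cluster_centers"]

    if cfg.sarmap:
        queries = list(dict.fromkeys(handles["top_centers"]))
        lib_obj = LibrarySet(name=name, records=list(records))
        hits = cs.substructure_hits(lib_obj, queries)
        sar: dict[str, Any] = {"n_query_scaffolds": len(queries), "n_hits": len(hits)}
        if len(hits) >= 2:
            hit_recs = hits.records[: cfg.sarmap_max_points]
            hit_fps = [cs.fingerprint(r.mol) for r in hit_recs]
            hdist = cs.distance_matrix(hit_fps)
            selected = cs.optisim_select(
                hit_recs,
                subsample_size=cfg.optisim_subsample,
                radius=cfg.optisim_radius,
                seed=lib_seed,
                dist=hdist,
            )
            sel_dist = hdist[np.ix_(selected, selected)]
            emb = cs.nlm_project(
                sel_dist,
                horizon=cfg.nlm_horizon,
                singleton_radius=cfg.nlm_singleton_radius,
                seed=lib_seed,
            )
            # dense areas live in the full hit set: the OptiSim subset is
            # radius-separated, so >=0.8-similarity groups only exist among
            # the unselected neighbours of the representatives
            areas = cs.dense_areas(
                None, hit_fps, sim_threshold=cfg.dense_sim_threshold,
                min_members=cfg.dense_min_members,
            )
            sar.update(
                {
                    "n_selected": len(selected),
                    "nlm_stress": emb.stress,
                    "n_singletons": len(emb.singletons),
                    "n_dense_areas": len(areas),
                    "map": [
                        {
                            "mol_id": hit_recs[i].mol_id,
                            "x": float(emb.coords[k, 0]),
                            "y": float(emb.coords[k, 1]),
                            "singleton": k in emb.singletons,
                        }
                        for k, i in enumerate(selected)
                    ],
                }
            )
        section["sar_map"] = sar
    return section, handles


def shared_scaffolds(
    per_library: dict[str, tuple[list[str], list[str]]], min_frequency: int = 2
) -> list[dict]:
    """Scaffolds appearing in >= min_frequency libraries' top lists.

    Each library contributes the union of its top most-frequent Level-1
    scaffolds and its top cluster centers.
    """
    from collections import Counter

    counts: Counter[str] = Counter()
    for top_freq, top_centers in per_library.values():
        for s in set(top_freq) | set(top_centers):
            counts[s] += 1
    rows = [
        {"smiles": s, "n_libraries": c}
        for s, c in counts.items()
        if c >= min_frequency
    ]
    rows.sort(key=lambda r: (-r["n_libraries"], r["smiles"]))
    return rows


def run(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the comparative report dict."""
    report: dict[str, Any] = {"config": cfg.to_dict(), "libraries": {}}
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    libs: list[LibrarySet] = []
    truths: dict[str, synth.GroundTruth] = {}
    for i, spec in enumerate(cfg.libraries):
        try:
            lib, truth = _ingest(spec, seed=cfg.seed + i)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[ingest] {spec}: {e}") from e
        try:
            clean, prep = preprocess(lib)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[preprocess] {lib.name}: {e}") from e
        report["libraries"][clean.name] = {"preprocess": prep.as_dict()}
        if truth is not None:
            truths[clean.name] = truth
        libs.append(clean)

    scheme = std.MwBinningScheme(cfg.mw_low, cfg.mw_high, cfg.mw_width)
    if cfg.standardize and len(libs) >= 2:
        try:
            subsets = std.standardize(libs, scheme, seed=cfg.seed)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[standardize] {e}") from e
        report["standardization"] = std.manifest(libs, subsets, scheme)
        analysed = {s.source: s.records for s in subsets}
    else:
        analysed = {lib.name: lib.records for lib in libs}

    per_library_tops: dict[str, tuple[list[str], list[str]]] = {}
    level_inventories: list[LevelInventory] = []
    for i, (name, records) in enumerate(analysed.items()):
        try:
            section, handles = _library_section(records, name, cfg, lib_seed=cfg.seed + i)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[analysis] {name}: {e}") from e
        if name in truths:
            t = truths[name]
            section["ground_truth"] = {
                "n_scaffolds": t.true_frequencies.n_unique,
                "expected_pc50c": t.expected_pc50c,
                "acyclic_pct": 100.0 * t.n_acyclic / t.config.n_molecules,
            }
        report["libraries"][name].update(section)
        per_library_tops[name] = (
            handles.get("top_frequent", []),
            handles.get("top_centers", []),
        )
        level_inventories.append(handles["level_inventory"])
        if outdir and "treemap" in handles:
            with open(outdir / f"{name}.treemap.json", "w") as fh:
                json.dump(handles["treemap"], fh, indent=1, sort_keys=True)

    if len(per_library_tops) >= 2:
        report["shared_scaffolds"] = shared_scaffolds(per_library_tops)

    if len(level_inventories) >= 2:
        report["rose_map"] = rose_map_table(level_inventories)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        for lib in libs:
            write_library(lib, outdir / f"{lib.name}.clean.smi", "smiles")
    return report
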