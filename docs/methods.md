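# Methods

This note records the scientific conventions, parameter choices and known
limitations behind `scaffold-profiler`. Everything stated here is what the
code does; no empirical claim is made beyond what the test suite and
`scripts/acceptance.py` compute.

## Preprocessing

A record survives ingestion if RDKit can sanitize it. Preprocessing then
applies, in order: salt stripping (keep the largest covalent component —
largest heavy-atom count, ties broken by MW then canonical SMILES), an
"organic subset" element filter (default `{H, C, N, O, P, S, F, Cl, Br,
I}`, configurable), re-sanitization (failures are dropped and counted, not
repaired — heuristic valence repair is deliberately out of scope), and
deduplication on canonical SMILES keeping the first occurrence. Molecular
weight is the average MW of the hydrogen-complete structure. Preprocessing
is idempotent, and the removal report satisfies the accounting identity
`inorganic + sanitize_failed + mw_capped + duplicates + retained = input`.
An optional MW ceiling exists for libraries of very large natural products.

## MW standardization

Scaffold and fragment counts grow with molecular weight, so libraries are
compared on random subsets with *identical* MW histograms: half-open bins
(default `[100, 700)` Da in 100 Da steps, lower edge inclusive — 700 Da is
excluded, a convention we fixed since edge handling is otherwise
ambiguous), per-bin target = the minimum count over libraries, and uniform
sampling without replacement inside each bin. Each (library, bin) pair
draws from its own seeded substream keyed by a CRC of the library name, so
adding a library to a run never perturbs another library's sample. At bin
resolution the matched histograms are exactly equal, not approximately.

## Fragment decompositions

Ring perception uses the true (non-symmetrized) SSSR throughout. RDKit's
default ring info keeps symmetry-equivalent extra rings — bicyclo[2.2.2]-
octane would count three six-rings — which would inflate ring counts and
break the one-ring-per-level scaffold-tree contract, so the SSSR is
re-perceived explicitly wherever rings are enumerated or counted.

- **Ring assemblies** are connected components of ring atoms under ring
  bonds; spiro junctions (shared atom, no shared bond) therefore merge
  assemblies, matching the "assembly" notion of fragment-generation tools.
- **Bridge assemblies** are the assemblies in which some pair of SSSR rings
  shares at least two bonds. Ortho-fused systems (naphthalene: one shared
  bond) and spiro systems are excluded.
- **Chain assemblies** are the connected components left after deleting all
  ring atoms. Each former bond to a ring atom is replaced by a bond of the
  same order to a dummy atom, so a methyl side chain (`*C`) and a methylene
  linker (`*C*`) are distinct unique fragments, and an exocyclic carbonyl
  oxygen appears as `*=O`. A fully acyclic molecule is one chain: itself.
- **Murcko frameworks** iteratively delete terminal non-ring atoms until a
  fixed point; what survives is the union of ring systems and inter-ring
  linkers. Exocyclic multiply-bonded atoms (e.g. a carbonyl O on a ring)
  are pruned like any side chain by default because they are terminal;
  `keep_exocyclic=True` switches to the convention that retains them
  (toolkits differ on this point). Acyclic molecules have no framework and
  are reported separately as the acyclic percentage.
- **RECAP fragments** come from cutting *all* acyclic bonds matching the
  eleven retrosynthetic bond classes simultaneously (SMARTS authored in
  `fragmentation.RECAP_BOND_SMARTS`), with attachment dummies and no
  minimum-fragment-size filter. Cutting simultaneously (rather than
  emitting the leaves of a recursive cleavage tree) makes the fragments an
  exact partition of the parent's heavy atoms — reassembly at the dummies
  conserves atom counts, which the test suite verifies. On single-cleavage
  molecules the output coincides with RDKit's recursive RECAP
  implementation, which serves as an independent cross-check in the tests;
  on multi-cleavage molecules the two conventions can differ and ours is
  the documented one.

## Scaffold trees (ST-rules v1)

Trees are built top-down: Level *n* is the molecule, Level *n−1* its Murcko
framework (when the molecule *is* its own framework the two coincide and
the level is not duplicated — a bare benzene has a one-element tree), and
each further level removes exactly one peripheral SSSR ring until a single
ring remains at Level 0.

A removal candidate is an SSSR ring with atoms exclusive to it; removing it
deletes those atoms, re-prunes dangling linkers, and is *valid* only if the
scaffold stays connected, sanitizes, and loses exactly one SSSR ring.
Among valid candidates an ordered filter chain decides:

1. prefer removals whose result is linker-free (no acyclic bonds remain);
2. prefer removing rings not involved in bridged or spiro fusion (i.e.
   retain bridged/spiro systems);
3. prefer removing larger rings;
4. prefer removing the ring with the fewest heteroatoms (retain
   heteroatom-rich rings);
5. tie-break on the lexicographically smallest canonical SMILES of the
   resulting scaffold.

The chain is total, so trees are deterministic. It follows the spirit of
the published scaffold-tree prioritization rules as a documented,
reproducible variant; byte-level parity with proprietary implementations is
not claimed. Pruning an aromatic ring can demote the atoms it shared with
a surviving ring (indane's five-ring keeps two former-aromatic carbons), so
the *subscaffold* relation between consecutive levels is defined — and
tested — on element-labelled skeletons, ignoring bond orders and
aromaticity (`is_subscaffold`). In rare ring systems where no valid
removal exists the tree is returned truncated and flagged
(`complete=False`) rather than raising.

The **Level 1 scaffold** of a molecule whose tree has only one level below
the top (single-ring molecules) is the molecule's top level itself; this
matches the convention of trees that include the original molecule as the
highest level, and it is what feeds the clustering stage.

## Diversity statistics

Frequency tables sort by count descending, canonical SMILES ascending (a
total, documented tie-break). The CSFP point *k* has `x = 100·k/n_unique`
(or `x = k` in count mode) and `y = 100·(Σ_{i≤k} c_i)/N`; the optional
truncation stops the curve where frequency first drops to 1, de-cluttering
the singleton tail. PC50C is the first crossing of 50% coverage, without
interpolation, expressed against the number of *unique* scaffolds — an
all-singleton library scores 50, a single-scaffold library degenerately
scores 100 (outside the statistic's intended regime, documented as such).
Acyclic molecules are excluded from scaffold tables and reported as a
separate percentage.

## Chemical-space analytics

Fingerprints are Morgan radius 2, 2048 bits — the ECFP_4 equivalent — used
for scaffold clustering and also for the map distances (classic 2D UNITY
fingerprints are proprietary; this substitution is a stated divergence).
Tanimoto distance between two all-zero vectors is defined as 0.

**Leader clustering** assigns items in input order (join the first center
nearer than the distance threshold, default 0.6 — the threshold of the
original order-dependent tool is unpublished, so it is exposed as
configuration), then runs two recentering passes: move each center to its
cluster medoid, reassign every item to its nearest center. Both
half-steps are non-increasing in total member-to-center distance, and for
well-separated groups recentering heals the order dependence (verified by
permutation tests). DTC is the Tanimoto distance to the final center.

**Tree-Map export** emits a renderer-agnostic JSON hierarchy: per-scaffold
area equals scaffold frequency (exact proportionality), and color value
maps DTC linearly onto red (0) → white (mid) → green (max observed DTC).
**Forest Coverage** — an informal "deep green share" with no published
formula — is operationalized as the frequency-weighted share of scaffolds
with DTC ≥ 0.75 × max DTC; the cutoff fraction is configurable and the
definition is labelled as ours.

**OptiSim** draws up to `subsample_size` random candidates outside the
exclusion radius (default 0.3; closer candidates are permanently
discarded), keeps the one most dissimilar to the current selection
(max–min), and repeats until the pool is exhausted. The selected set is
radius-separated and seed-deterministic.

**NLM** is a Sammon mapping: stress `Σ w_ij (D_ij − d_ij)² / D_ij`
normalized by `Σ w_ij D_ij`, minimized by gradient descent with a
backtracking step, so stress is non-increasing per accepted iteration.
Initialisation is classical MDS on the capped distances (hence exact,
zero-stress starts for 2D-embeddable inputs) plus seeded 1e-9 jitter.
Dissimilarities above the horizon (default 0.3) are capped at the horizon
and down-weighted to 0.1 — beyond the horizon plotted distances are not to
scale. A weight of exactly 0 would leave far pairs unconstrained and let
disconnected groups drift arbitrarily, which is why the down-weight is
small but nonzero (configurable, 0 allowed). Compounds with no neighbour
within the singleton radius (default 0.3) are flagged and initialised on
the embedding periphery. Typical Sammon stress on real fingerprint
distance matrices is ~0.1–0.2; exact recovery (stress < 1e-6) is expected
only for inputs that embed in the plane, which is what the tests assert.

**Dense areas** greedily pick the unassigned molecule with the most
unassigned neighbours at similarity ≥ 0.8 (the threshold used for
representative-area extraction) and form disjoint groups of at least
`min_members` (default 3). In the orchestrated pipeline dense areas are
extracted from the full substructure-hit set, not from the OptiSim subset:
the subset is radius-separated (pairwise distance ≥ 0.3, similarity
≤ 0.7), so by construction it can never contain a 0.8-similarity group.

## Synthetic libraries and what they do (not) show

Each ring-bearing molecule is a scaffold template — a curated pure Murcko
framework (1–5 ring systems; fused, spiro, bridged, and linker-joined
exemplars) — decorated with random acyclic substituents until its MW lands
in the requested window (default 100–700 Da, matching the standardization
range). Scaffold frequencies follow a Zipf law (`w_k ∝ k^-α`), a uniform
split, or an explicit list, apportioned by largest remainder with a floor
of one molecule per scaffold, so realized counts are deterministic and the
expected PC50C is computable in closed form from them. When more scaffolds
are requested than the curated pool holds, the pool is extended
deterministically by joining template pairs through short acyclic linkers
(the products are again pure frameworks). The acyclic fraction is drawn
from chain-grammar molecules with no rings.

Because default substituents are ring-free, the Murcko framework of every
generated molecule equals its template *exactly*; recovery tests can
therefore demand exact equality of frequency tables, unique counts, PC50C
and acyclic percentages. This is the generator's central design trade-off:
it validates the bookkeeping of the whole pipeline with zero tolerance, but
the molecules are decoratively random, not reaction-derived. Real
libraries additionally feature correlated substitution patterns, charged
and tautomeric forms, stereochemistry, and near-duplicate analog series —
none of which the generator emulates, so passing recovery tests demonstrate
pipeline correctness, not robustness to real-world standardization noise.
One visible consequence: randomly decorated same-scaffold molecules sit
near Tanimoto 0.5, so dense areas at the 0.8 threshold rarely occur in
synthetic runs (the extraction logic is instead verified by
planted-structure recovery). `hard_mode` admits ring-bearing substituents
to stress the fragmenter, forfeiting the ground-truth guarantee.

## Problem sizes and numerics

The shipped acceptance checks run the scaffold-tree contract on 10,000
generated molecules, parameter recovery on four 20,000-molecule libraries
(50 and 500 scaffolds × Zipf 1.0 and 1.5, 2% acyclic), the PC50C oracle on
1,000 random tables plus an exhaustive scan of every table with ≤ 12
molecules, and whole-pipeline determinism on two 600-molecule libraries;
`scripts/acceptance.py` profiles three 4,000-molecule libraries end to end.
These sizes exercise every code path at full fidelity while keeping a
complete run in minutes on one core. Degenerate inputs are handled
explicitly: acyclic molecules yield "no tree"/"no framework" flags rather
than errors, an all-acyclic library completes with its diversity section
marked `no_scaffolds`, empty frequency tables and empty clustering inputs
are fatal with stage-tagged messages, and duplicate points in the NLM
target matrix are floored at 1e-9 to avoid division by zero.
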