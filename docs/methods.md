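# Methods

This note records the models, conventions and design choices behind
`evoscreen`, in the order the pipeline applies them.

## Combinatorial libraries

A library is two tab-separated files: building rules
(`reaction_id, smarts, arity`) and building blocks
(`substrate_id, smiles, reaction_id, position`, one row per allowed
usage).  Validation is strict for rules (a malformed SMARTS or an
arity/template mismatch aborts the load, naming the reaction) and lenient
for blocks (rows whose SMILES does not sanitize are dropped with a logged
warning — real vendor files contain dirty rows).  A reaction left with an
empty slot stays in the library but is excluded from everything that
samples or enumerates.

Product assembly applies the reaction SMARTS to the ordered substrate
tuple with RDKit.  When a promiscuous template yields several products,
the lexicographically smallest canonical SMILES is kept: this is a pure
determinism device, not a chemical judgement, and it makes assembly a pure
function of the address.  One canonical-SMILES writer (RDKit's default) is
fixed package-wide; every cache key, deduplication key and cross-module
molecule identifier is that canonical string.

`sample_random_molecule` draws a reaction uniformly among usable
reactions, then each slot's substrate uniformly.  This is *not* uniform
over products (reactions with larger slot products are under-weighted
relative to product-uniform sampling); it is O(1), matches the
substrates-and-reactions genotype the search engine manipulates, and the
tests assert exactly this distribution.

Hit expansion (`expand_partners`) substitutes every allowed substrate at
each position while fixing the others, deduplicated by address; the
original combination is kept exactly once, so a two-component reaction
with slot sizes m and n expands to m + n − 1 candidates.

## Physicochemical triage

Descriptor conventions are fixed so that reference compounds with
published values reproduce exactly:

| descriptor | convention | unit |
| --- | --- | --- |
| MW | average molecular weight | Da |
| logP | Crippen atomic contributions | — |
| HBD | hydrogens on N or O | count |
| HBA | Lipinski N+O atom count (S excluded) | count |
| rotatable bonds | acyclic single bonds between non-terminal heavy atoms, amide C–N excluded | count |
| PSA | topological polar surface area | Å² |
| Fsp³ | fraction of sp³ carbons | 0–1 |

Hard bounds: MW 150–500 Da, logP −1–5, ≤10 rotatable bonds, ≤5 donors,
≤12 acceptors (≤10 in round 2).  PSA and Fsp³ are computed but are never
hard-filter reasons; they act only through the traffic-light total.

The traffic-light scheme bands five properties into 0/1/2 and removes
compounds whose total exceeds 2 (a total of exactly 2 survives).  Band
boundaries in the published scheme are written with bare `<`/`>` signs and
leave the boundary values themselves undefined; here bands are half-open
with the **worse band winning at boundaries** (logP exactly 3 → 1, exactly
4 → 2; MW 400 → 1, 500 → 2; PSA 120 → 1, 140 → 2; Fsp³ exactly 0.3 → 1,
0.2 → 2; rotatable-bond rows are disjoint integers 0–7 / 8–10 / ≥11).
Choosing the stricter band is conservative and is asserted by tests.  The
scheme's experimental columns (K_D, solubility) are represented as absent,
not as zero.  PAINS screening uses RDKit's built-in catalog of the
published PAINS substructure patterns.

## Scoring and filters

`lid_root2 = ΔE_interface / √N_heavy` (REU·atoms^−1/2): dividing by the
square root of the heavy-atom count removes the additive-per-contact bias
of interface energies toward large molecules while still rewarding
genuinely better binders.

* **Threshold filter** — "better than −3.5" is implemented inclusively
  (≤ −3.5); ties at the boundary are vanishingly rare in floating scores
  and inclusivity makes boundary behaviour deterministic.  The same
  operation runs the off-target counter screen in `exclude_better` mode.
* **Redock consistency** — two deltas are computed: |search score − best
  redock score| and (worst − best) of the ten best redock poses.  The
  compound fails if **either** exceeds 0.8 lid_root2.  The OR reading is
  the conservative one (it removes more unstable poses); `require_both`
  flips it for users who prefer the laxer reading.
* **Ensemble consensus** — the consensus is the arithmetic mean of the
  per-receptor-model best scores and the spread is the **population**
  standard deviation (the handful of receptor models is the whole
  ensemble, not a sample); compounds with σ > 0.5 are excluded.

Scores are cached by (canonical SMILES, receptor): an evolutionary search
revisits genotypes constantly, and caching preserves
"every molecule is reported" semantics without re-docking.

## The synthetic docking oracle

Physics-based docking is out of scope; the oracle contract
(`dock(molecule, receptor_id) → poses`) abstracts it, and two
implementations are provided.  The **table oracle** replays externally
computed per-pose score tables (CSV: `molecule_key, receptor_id,
pose_index, interface_delta`).  The **synthetic oracle** plants a
similarity landscape around a target motif:

```
base(m)  = −A·tanimoto(ECFP4(m), ECFP4(motif)) − B·√N_heavy(m)   [REU]
pose_i   = base + s·i + ε_i,   ε_i ~ Normal(0, noise_scale)
```

with defaults A = 15 REU, B = 1 REU (so the best lid_root2 values sit in
the −3 to −4 range, straddling the −3.5 cutoff), pose spread s = 0.3 REU
per rank, and noise 0.  In lid_root2 terms the size term B is a constant
offset, so the ranking is driven by similarity per √size — small faithful
analogues of the motif outrank large vague ones, which is exactly the
behaviour the normalization is meant to induce.  The noise stream is
derived by hashing (config seed, molecule key, receptor id), which makes
the oracle a pure function of its arguments even at non-zero noise and
keeps cached searches bit-reproducible regardless of evaluation order.
Requested pose coordinates are planted reference coordinates plus jitter
proportional to the pose's energy above the best pose, so funnel analyses
see the expected monotone RMSD-score structure.

What the oracle does **not** emulate: rugged multi-modal energy
landscapes, receptor-dependent pose geometry, scoring-function biases
(e.g. the over-reward of nitrogen-rich rings that physics-based interface
scores can exhibit), or correlations between chemical series beyond
fingerprint similarity.  Tests passing against it therefore demonstrate
the correctness of the search and triage machinery, not the virtue of any
docking engine.

## The evolutionary engine

Genotype: a library address.  Defaults mirror the campaign shape — seed
population 200, survivors 50, 30 generations, 300 offspring per
generation.  The operator mixture is substrate mutation 0.45, reaction
mutation 0.10, crossover 0.35, immigrants 0.10; these realize the three
roles a balanced search needs (local exploitation, escaping local minima,
fresh exploration) and are exposed in `EvolutionConfig` rather than
asserted as facts.  Selection is linear ranking (weight N − rank + 1,
drawn without replacement) with 5 elites kept deterministically; elitism
makes the per-generation best score monotone.  Crossover between parents
of different reactions is undefined (incompatible slot lists), so each
parent falls back to a substrate mutation, keeping the offspring budget
full.  Reaction mutation keeps each substrate that is allowed in the
corresponding slot of the new reaction and resamples the rest.

Seeded initialization (hit-expansion rounds) draws `seeded_pick` molecules
without replacement from the supplied pool (all of it if smaller) plus
`seeded_random_extra` random molecules from the whole library.

Every evaluated individual is logged once per distinct molecule;
generation summaries record best/median fitness and cache statistics.
Several runs aggregate into one best-score-per-molecule table with per-run
provenance.

## Clustering and budget pruning

Similarity is ECFP4 (Morgan radius 2, 2048 bits) with Tanimoto.
"k-means under Tanimoto" is internally inconsistent — k-means needs a
vector mean — so the default clusters the raw bit vectors with k-means
(seeded, empty clusters dropped), and a k-medoids variant working directly
in Tanimoto distance is provided for the literal metric.  Budget pruning
re-finds the currently most-similar pair after **every** removal and drops
the worse-scoring member until the target count remains; at the few
hundred molecules where this runs, the O(n²) recomputation is immaterial.
Ties in similarity break by key order of the pair, ties in score keep the
lexicographically earlier key; the removal audit trail is returned so the
decision can be replayed.

## Structural post-processing

Contact maps count **distinct compounds** (not poses or atoms), using one
representative — best-scored — pose per compound: a compound touches a
residue if any of its heavy atoms lies within the cutoff (default 4.0 Å)
of any residue heavy atom.  Hydrogens are ignored on both sides because
docked structures vary in protonation.  Display bins are descending
half-open intervals (>500, 400–500, 200–400, 100–200, ≤100 compounds).
PDB reading keeps ATOM/HETATM records, the first alternate location, and
author residue numbering with insertion codes.

Ligand RMSD uses identity atom correspondence with no re-superposition —
poses from one docking engine share the receptor frame — and no
graph-symmetry correction (symmetry-aware RMSD is deliberately out of
scope).  The funnel table takes the lowest-lid_root2 pose as reference and
computes RMSD only for poses with interface score at or below the floor
(default −10 REU, the published cost-control rule); other rows carry NaN.

## Pipeline composition and reports

`run_screen` chains evolve → aggregate → first filter → top-N →
redock/consistency → (round 2: ensemble consensus) → score threshold →
(optional off-target) → cluster → prune, writing a manifest whose
per-stage input count equals the previous stage's output count (the
clustering stage annotates rather than filters).  `run_expand` prepends
partner enumeration and a score filter whose survivors seed the
evolutionary runs.  All randomness flows from one global seed through
SHA-256-derived per-stage sub-seeds, so any stage re-run in isolation
reproduces its outputs and whole runs are bit-identical.

Report percentages follow the conventions of campaign write-ups: hit rates
to 3 significant digits (3/138 → 2.17%), sampled fractions of the library
to 2 significant digits (358 713 of 19 548 368 812 → 0.0018%), stage pass
rates to whole percent (628/757 → 83%); raw values are retained in the
JSON/CSV outputs.

## Synthetic fixtures and test scale

Toy libraries draw substrates from curated, reliably reactive families —
carboxylic acids and primary amines in aliphatic and aromatic flavours,
combined by amide coupling (two-component) or amine diacylation
(three-component) — so SMARTS application never fails silently and test
failures isolate engine bugs rather than chemistry edge cases.  Search-
quality tests use a 1 200-product library (30×40 amide space) with a
noiseless planted landscape and a scaled-down engine configuration (seed
60, survivors 15, 10 generations × 30 offspring): across 5 seeds the
search reaches the brute-force top 1% while evaluating under 30% of the
space.  The cross-seed convergence check uses a fuller budget (20
generations × 60 offspring) because trajectory convergence is an
asymptotic property of the search, not of its first few generations.
Pipeline tests run a 180-product library with 2 runs of 4 generations.
These sizes keep the whole suite under a minute while leaving every
mechanism (caching, selection pressure, cascade accounting) fully
exercised.

## Known limitations

* No physics: the synthetic oracle is a similarity landscape; conclusions
  about real docking engines, scoring biases or binding modes are out of
  reach by design.
* No stereochemical enumeration of reaction outcomes, protecting groups or
  synthesis-route feasibility; multi-product SMARTS outcomes are resolved
  lexicographically.
* RMSD ignores molecular graph symmetry; symmetric ligands can report
  inflated pose deviations.
* The expert "hit-picking" step of real campaigns is not automated; the
  toolkit emits its decision-support products (cluster sheets, top-pose
  tables, funnel tables) instead.
* The k-means default operates on bit vectors in Euclidean space; for
  strict Tanimoto-metric clustering use the k-medoids option.
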