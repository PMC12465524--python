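# evoscreen

Evolutionary screening of ultra-large combinatorial ("make-on-demand")
compound libraries, with the complete hit-triage cascade used in
structure-based virtual-screening campaigns.

## The problem

Make-on-demand chemical spaces such as Enamine REAL are defined
*implicitly*: a list of reactions ("building rules", SMARTS with two or
three components) and a list of substrates ("building blocks", SMILES with
declared reaction/position usages).  Fully enumerated, such spaces reach
tens of billions of products — far beyond exhaustive docking.  `evoscreen`
implements the alternative: a genetic algorithm that searches the space by
mutating and recombining *library addresses* (reaction + substrate tuple),
using a size-normalized docking score as fitness, followed by the triage
cascade that reduces hundreds of thousands of sampled molecules to a
purchasable candidate set.

It is aimed at computational chemists who want to run, test or teach this
class of pipeline without a proprietary library or a physics-based docking
engine: every stage runs against bundled synthetic fixtures, and every
external dependency (real vendor files, real docking score tables) plugs in
through the same interfaces.

## The model

**Fitness.**  Raw interface energies ΔE (Rosetta energy units, more
negative = better) favour large molecules, so the pipeline's currency is
the square-root–normalized score

```
lid_root2 = ΔE_interface / √N_heavy
```

**Search.**  A seed population of 200 random library members is docked and
reduced to 50 survivors by linear rank-based selection (with elitism).
Each of 30 generations produces several hundred offspring via substrate
mutation, reaction mutation, substrate crossover between compounds sharing
a reaction, and random immigrants; duplicate genotypes are served from a
score cache, and every evaluated molecule — including discarded ones — is
kept in the run log.  Several independent runs are aggregated best-score-first.

**Triage.**  Sampled molecules then pass through, in order: hard
physicochemical filters (150 ≤ MW ≤ 500 Da, −1 ≤ logP ≤ 5, ≤10 rotatable
bonds, ≤5 H-bond donors, ≤12 acceptors — 10 in round 2); a traffic-light
score banding logP/MW/PSA/rotatable bonds/Fsp³ into 0/1/2 and removing
totals above 2; PAINS substructure exclusion; redocking with 600 poses and
a consistency filter (fail if the search-vs-redock gap or the top-10 pose
spread exceeds 0.8 lid_root2); a −3.5 lid_root2 cutoff; optionally an
ensemble-consensus filter (exclude σ > 0.5 across receptor models) and an
off-target counter screen (exclude compounds scoring better than −3.5
against the anti-target); ECFP4/Tanimoto k-means clustering into 100
diversity groups; and greedy similarity pruning (repeatedly drop the
worse-scoring member of the most similar pair) down to the purchase budget.

Structural post-processing provides residue-contact consensus maps
(distinct compounds within 4 Å of each residue), fixed-correspondence
ligand RMSD, and RMSD-score funnel tables for pose-convergence analysis.

## Worked example

Search a 1 200-product toy amide library on a planted (noiseless) scoring
landscape and compare against exhaustive enumeration:

```python
import numpy as np
from evoscreen import chemlib, fixtures
from evoscreen.evolve import EvolutionConfig, run_evolution
from evoscreen.scoring import SyntheticOracle
from evoscreen.physchem import compute_properties, assign_traffic_lights

spec = fixtures.ToyLibrarySpec(
    reactions=(fixtures.ReactionSpec(arity=2, slot_sizes=(30, 40)),), seed=5)
rules, blocks = fixtures.make_toy_library(spec, "toy-lib")
library = chemlib.load_library(rules, blocks)

landscape, oracle_config = fixtures.make_planted_landscape(
    library, np.random.default_rng(11))
oracle = SyntheticOracle(oracle_config)

config = EvolutionConfig(seed_size=60, survivors=15, generations=10,
                         offspring_per_generation=30, elitism_count=3,
                         rng_seed=0)
log = run_evolution(library, oracle, config)
best = log.best()
print("best molecule:", best.key)
print("best lid_root2: %.3f" % best.fitness)
print("brute-force rank:", landscape.rank_of(best.key))
print("distinct molecules evaluated:", len(log.individuals))
```

prints

```
best molecule: CCCCCCCCCC(=O)NCC
best lid_root2: -3.566
brute-force rank: 4
distinct molecules evaluated: 190
```

i.e. the search reached the 5th-best molecule of the 1 200-product space
(top 0.4%) while docking only 15.8% of it.  The winner is a close analogue
of the planted optimum `CCCCCCCCCCCC(=O)NC`, and its triage descriptors
(`compute_properties` → MW 199.3 Da, logP 3.26, HBD 1, HBA 2, 9 rotatable
bonds; traffic-light total 2) keep it in the surviving set.

The same flow is available from the shell:

```bash
evoscreen fixtures make-library --slots 30x40 --seed 5 --out toy-lib
evoscreen evolve --rules toy-lib/rules.tsv --blocks toy-lib/blocks.tsv \
    --motif "CCCCCCCCCCCC(=O)NC" --runs 2 --seed 0 --out runs/
evoscreen filter --smiles-file mols.smi --out audit.csv
evoscreen site-map --receptor receptor.pdb --poses best_poses.sdf --out contacts.csv
```

## Layout

| module | role |
| --- | --- |
| `evoscreen.chemlib` | library parsing/validation, product assembly, streaming enumeration, sampling, hit expansion |
| `evoscreen.physchem` | descriptors, hard filters, traffic lights, PAINS |
| `evoscreen.scoring` | `lid_root2`, score/consistency/consensus filters, docking-oracle contract, score-table I/O |
| `evoscreen.evolve` | the evolutionary engine and run logs |
| `evoscreen.select` | ECFP4 fingerprints, Tanimoto, clustering, budget pruning |
| `evoscreen.site` | receptor reading, contact maps, ligand RMSD, funnel tables |
| `evoscreen.fixtures` | synthetic toy libraries, planted landscapes, toy complexes |
| `evoscreen.app` | pipeline composition, manifests, campaign reports |
| `evoscreen.cli` | the `evoscreen` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
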