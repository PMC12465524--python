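"""Evolutionary search over combinatorial library addresses.

The engine treats a library address — (reaction, ordered substrate tuple)
— as the genotype and the size-normalized docking score (lid_root2, lower
= better) as the fitness.  A seed population of random molecules is docked
by the oracle, reduced by rank-based selection, and then evolved through a
fixed number of generations via substrate/reaction mutation, substrate
crossover between compounds sharing a reaction, and random immigrants.
Every evaluated molecule, including discarded ones, is retained in the run
log; duplicate genotypes are served from a score cache rather than
re-docked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from evoscreen.chemlib import (
    CombinatorialLibrary,
    LibraryMolecule,
    assemble_product,
    sample_random_molecule,
)
from evoscreen.errors import EmptyLibraryError, InputError
from evoscreen.scoring import DockingOracle, derive_seed, score_result


@dataclass
class Individual:
    """One evaluated (or pending) member of the population."""

    molecule: LibraryMolecule
    fitness: float | None = None  # lid_root2, lower = better
    generation_born: int = 0
    parent_keys: tuple[str, ...] = ()
    operator: str = "seed"  # seed|mutation_substrate|mutation_reaction|crossover|immigrant
    unchanged: bool = False  # operator could not produce a different genotype

    @property
    def key(self) -> str:
        return self.molecule.product_smiles


@dataclass
class EvolutionConfig:
    """Campaign constants of one evolutionary run.

    Defaults mirror the screening-campaign shape: a 200-molecule seed
    population reduced to 50 survivors, 30 generations, each growing the
    population by several hundred offspring before re-selection.
    """

    seed_size: int = 200
    survivors: int = 50
    generations: int = 30
    offspring_per_generation: int = 300
    p_mut_substrate: float = 0.45
    p_mut_reaction: float = 0.10
    p_crossover: float = 0.35
    p_immigrant: float = 0.10
    elitism_count: int = 5
    seeded_pool: list[LibraryMolecule] | None = None
    seeded_pick: int = 200
    seeded_random_extra: int = 50
    receptor_id: str = "receptor-1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.survivors > self.seed_size:
            raise InputError("survivors must not exceed seed_size")
        if self.generations < 1:
            raise InputError("generations must be >= 1")
        weights = (self.p_mut_substrate + self.p_mut_reaction
                   + self.p_crossover + self.p_immigrant)
        if abs(weights - 1.0) > 1e-9:
            raise InputError("operator mixture weights must sum to 1")


@dataclass
class GenerationSummary:
    generation: int
    best_fitness: float
    median_fitness: float
    n_evaluated: int  # oracle evaluations + cache hits this generation
    n_new: int  # distinct new molecules this generation


@dataclass
class RunLog:
    """Complete record of one run: every molecule ever evaluated."""

    run_id: str
    individuals: dict[str, Individual] = field(default_factory=dict)
    generations: list[GenerationSummary] = field(default_factory=list)
    oracle_calls: int = 0
    cache_hits: int = 0
    valid: bool = True

    def best(self) -> Individual:
        return min(self.individuals.values(), key=lambda i: (i.fitness, i.key))

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for ind in self.individuals.values():
                fh.write(json.dumps({
                    "run_id": self.run_id,
                    "molecule_key": ind.key,
                    "reaction_id": ind.molecule.reaction_id,
                    "substrate_ids": list(ind.molecule.substrate_ids),
                    "fitness": ind.fitness,
                    "generation_born": ind.generation_born,
                    "parent_keys": list(ind.parent_keys),
                    "operator": ind.operator,
                }) + "\n")

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "generation": g.generation,
            "best_fitness": g.best_fitness,
            "median_fitness": g.median_fitness,
            "n_evaluated": g.n_evaluated,
            "n_new": g.n_new,
        } for g in self.generations])


# -- variation operators -------------------------------------------------


def mutate(
    individual: Individual,
    library: CombinatorialLibrary,
    rng: np.random.Generator,
    kind: str = "substrate",
) -> Individual:
    """Mutate one address component.

    Substrate mutation replaces one uniformly chosen slot with a different
    allowed substrate.  Reaction mutation moves the genotype to a different
    uniformly chosen reaction, keeping each substrate that is allowed in
    the corresponding new slot and resampling the rest.  If no alternative
    exists (singleton library) the parent is returned flagged unchanged.
    """
    mol = individual.molecule
    gen = individual.generation_born
    if kind == "substrate":
        arity = library.reactions[mol.reaction_id].arity
        mutable = [
            p for p in range(arity)
            if len(library.slots[(mol.reaction_id, p)]) > 1
        ]
        if not mutable:
            return Individual(molecule=mol, generation_born=gen,
                              parent_keys=(mol.product_smiles,),
                              operator="mutation_substrate", unchanged=True)
        pos = mutable[int(rng.integers(len(mutable)))]
        options = [s for s in library.slots[(mol.reaction_id, pos)]
                   if s != mol.substrate_ids[pos]]
        new_sid = options[int(rng.integers(len(options)))]
        sids = tuple(new_sid if p == pos else mol.substrate_ids[p]
                     for p in range(arity))
        child = assemble_product(library, mol.reaction_id, sids)
        return Individual(molecule=child, generation_born=gen,
                          parent_keys=(mol.product_smiles,),
                          operator="mutation_substrate")
    if kind == "reaction":
        others = [r for r in library.usable_reactions()
                  if r.reaction_id != mol.reaction_id]
        if not others:
            return Individual(molecule=mol, generation_born=gen,
                              parent_keys=(mol.product_smiles,),
                              operator="mutation_reaction", unchanged=True)
        rxn = others[int(rng.integers(len(others)))]
        sids = []
        for p in range(rxn.arity):
            slot = library.slots[(rxn.reaction_id, p)]
            if p < len(mol.substrate_ids) and mol.substrate_ids[p] in slot:
                sids.append(mol.substrate_ids[p])
            else:
                sids.append(slot[int(rng.integers(len(slot)))])
        child = assemble_product(library, rxn.reaction_id, tuple(sids))
        return Individual(molecule=child, generation_born=gen,
                          parent_keys=(mol.product_smiles,),
                          operator="mutation_reaction")
    raise InputError(f"unknown mutation kind {kind!r}")


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    library: CombinatorialLibrary,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Exchange a substrate between two compounds.

    Parents sharing a reaction swap the substrate of one uniformly chosen
    slot, giving the two recombinants.  Substrate exchange is undefined
    across different reactions (incompatible slot lists), so each parent
    falls back to a substrate mutation instead.  Identical parents yield
    children identical to themselves, flagged unchanged.
    """
    ma, mb = parent_a.molecule, parent_b.molecule
    if ma.reaction_id != mb.reaction_id:
        return (mutate(parent_a, library, rng, kind="substrate"),
                mutate(parent_b, library, rng, kind="substrate"))
    if ma.substrate_ids == mb.substrate_ids:
        keys = (ma.product_smiles, mb.product_smiles)
        return (
            Individual(molecule=ma, generation_born=parent_a.generation_born,
                       parent_keys=keys, operator="crossover", unchanged=True),
            Individual(molecule=mb, generation_born=parent_b.generation_born,
                       parent_keys=keys, operator="crossover", unchanged=True),
        )
    arity = library.reactions[ma.reaction_id].arity
    pos = int(rng.integers(arity))
    sids_a = tuple(mb.substrate_ids[p] if p == pos else ma.substrate_ids[p]
                   for p in range(arity))
    sids_b = tuple(ma.substrate_ids[p] if p == pos else mb.substrate_ids[p]
                   for p in range(arity))
    keys = (ma.product_smiles, mb.product_smiles)
    child_a = assemble_product(library, ma.reaction_id, sids_a)
    child_b = assemble_product(library, mb.reaction_id, sids_b)
    unchanged = sids_a == ma.substrate_ids
    return (
        Individual(molecule=child_a, parent_keys=keys, operator="crossover",
                   unchanged=unchanged),
        Individual(molecule=child_b, parent_keys=keys, operator="crossover",
                   unchanged=unchanged),
    )


def rank_select(
    population: Sequence[Individual],
    k: int,
    elitism_count: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Linear-ranking selection of ``k`` survivors.

    The ``elitism_count`` best individuals by fitness are kept
    deterministically; the remaining ``k − elitism_count`` are drawn
    without replacement with probability proportional to ``N − rank + 1``
    (rank 1 = best).  Fitness ties break by molecule key order.
    """
    if k > len(population):
        raise InputError(f"cannot select {k} from population of {len(population)}")
    ordered = sorted(population, key=lambda i: (i.fitness, i.key))
    n_elite = min(elitism_count, k)
    survivors = list(ordered[:n_elite])
    rest = ordered[n_elite:]
    n_draw = k - n_elite
    if n_draw and rest:
        # ranks continue after the elites: weight N - rank + 1, rank 1 = best
        n_total = len(ordered)
        weights = np.array([n_total - (n_elite + i + 1) + 1 for i in range(len(rest))],
                           dtype=float)
        probs = weights / weights.sum()
        idx = rng.choice(len(rest), size=n_draw, replace=False, p=probs)
        survivors.extend(rest[i] for i in sorted(idx))
    return survivors


# -- generation loop -----------------------------------------------------


class _Evaluator:
    """Cache-aware oracle front end shared across a run."""

    def __init__(self, oracle: DockingOracle, receptor_id: str, log: RunLog):
        self.oracle = oracle
        self.receptor_id = receptor_id
        self.log = log
        self.cache: dict[str, float] = {}

    def evaluate(self, individual: Individual) -> Individual:
        key = individual.key
        if key in self.cache:
            self.log.cache_hits += 1
            individual.fitness = self.cache[key]
            return individual
        result = self.oracle.dock(individual.molecule, self.receptor_id)
        scored = score_result(result, provenance="evolve")
        self.log.oracle_calls += 1
        individual.fitness = scored.lid_root2
        self.cache[key] = scored.lid_root2
        self.log.individuals.setdefault(key, individual)
        return individual


def init_population(
    library: CombinatorialLibrary,
    config: EvolutionConfig,
    oracle: DockingOracle,
    rng: np.random.Generator | None = None,
    _evaluator: _Evaluator | None = None,
) -> list[Individual]:
    """Build and evaluate the initial population.

    Random mode draws ``seed_size`` random molecules.  Seeded mode draws
    ``seeded_pick`` molecules without replacement from the seeded pool (all
    of it if smaller) plus ``seeded_random_extra`` random molecules from
    the whole library.
    """
    if not library.usable_reactions():
        raise EmptyLibraryError("library has no usable reaction")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    evaluator = _evaluator or _Evaluator(oracle, config.receptor_id, RunLog(run_id="adhoc"))
    population: list[Individual] = []
    if config.seeded_pool is not None:
        pool = list(config.seeded_pool)
        if not pool:
            raise InputError("seeded_pool is empty")
        n_pick = min(config.seeded_pick, len(pool))
        idx = rng.choice(len(pool), size=n_pick, replace=False)
        for i in sorted(idx):
            population.append(Individual(molecule=pool[i], operator="seed"))
        for _ in range(config.seeded_random_extra):
            population.append(Individual(
                molecule=sample_random_molecule(library, rng), operator="immigrant"))
    else:
        for _ in range(config.seed_size):
            population.append(Individual(
                molecule=sample_random_molecule(library, rng), operator="seed"))
    return [evaluator.evaluate(ind) for ind in population]


def run_evolution(
    library: CombinatorialLibrary,
    oracle: DockingOracle,
    config: EvolutionConfig,
    run_id: str = "run-0",
) -> RunLog:
    """Execute one full evolutionary run and return its complete log.

    Each generation the survivors produce ``offspring_per_generation``
    children through the operator mixture (immigrants are fresh random
    molecules); children are evaluated cache-aware, the pool of survivors
    plus children is reduced back by rank selection, and the generation's
    best/median fitness recorded.  A fixed ``rng_seed`` makes the whole
    log bit-identical across runs.
    """
    log = RunLog(run_id=run_id)
    rng = np.random.default_rng(derive_seed(config.rng_seed, run_id))
    evaluator = _Evaluator(oracle, config.receptor_id, log)

    population = init_population(library, config, oracle, rng, _evaluator=evaluator)
    survivors = rank_select(population, config.survivors, config.elitism_count, rng)

    ops = ("mutation_substrate", "mutation_reaction", "crossover", "immigrant")
    probs = np.array([config.p_mut_substrate, config.p_mut_reaction,
                      config.p_crossover, config.p_immigrant])
    for gen in range(1, config.generations + 1):
        children: list[Individual] = []
        while len(children) < config.offspring_per_generation:
            op = ops[int(rng.choice(len(ops), p=probs))]
            if op == "immigrant":
                children.append(Individual(
                    molecule=sample_random_molecule(library, rng),
                    operator="immigrant", generation_born=gen))
            elif op == "crossover":
                if len(survivors) < 2:
                    continue
                ia, ib = rng.choice(len(survivors), size=2, replace=False)
                ca, cb = crossover(survivors[int(ia)], survivors[int(ib)],
                                   library, rng)
                ca.generation_born = cb.generation_born = gen
                children.append(ca)
                if len(children) < config.offspring_per_generation:
                    children.append(cb)
            else:
                parent = survivors[int(rng.integers(len(survivors)))]
                kind = "substrate" if op == "mutation_substrate" else "reaction"
                child = mutate(parent, library, rng, kind=kind)
                child.generation_born = gen
                children.append(child)
        seen_before = set(log.individuals)
        for child in children:
            evaluator.evaluate(child)
        n_new = len(set(log.individuals) - seen_before)
        pool = survivors + children
        survivors = rank_select(pool, config.survivors, config.elitism_count, rng)
        fitnesses = np.array([ind.fitness for ind in pool])
        log.generations.append(GenerationSummary(
            generation=gen,
            best_fitness=min(ind.fitness for ind in survivors),
            median_fitness=float(np.median(fitnesses)),
            n_evaluated=len(children),
            n_new=n_new,
        ))
    return log


def aggregate_runs(run_logs: Sequence[RunLog]) -> pd.DataFrame:
    """Merge several independent runs into one scored-molecule table.

    The union of all evaluated molecules is kept with the best fitness per
    molecule and the ids of every run that evaluated it, sorted best-first.
    """
    if not run_logs:
        raise InputError("no run logs to aggregate")
    merged: dict[str, dict] = {}
    for log in run_logs:
        for key, ind in log.individuals.items():
            entry = merged.get(key)
            if entry is None:
                merged[key] = {
                    "molecule_key": key,
                    "reaction_id": ind.molecule.reaction_id,
                    "substrate_ids": "+".join(ind.molecule.substrate_ids),
                    "best_fitness": ind.fitness,
                    "runs": [log.run_id],
                }
            else:
                entry["runs"].append(log.run_id)
                if ind.fitness < entry["best_fitness"]:
                    entry["best_fitness"] = ind.fitness
    df = pd.DataFrame(merged.values())
    df["runs"] = df["runs"].map(lambda r: ";".join(r))
    return df.sort_values(
        ["best_fitness", "molecule_key"], ignore_index=True
    )
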