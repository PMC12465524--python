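"""Pipeline orchestration, manifests and campaign reports.

``run_screen`` composes the full hit-finding cascade — evolutionary runs,
aggregation, property triage, redocking, score/consistency/consensus
filters, off-target counter screen, clustering and budget pruning — and
writes a stage-by-stage manifest so that no compound is ever lost
silently.  ``run_expand`` mirrors the hit-expansion round: partner
enumeration around a confirmed hit, score-filtered into a seed pool for
further evolutionary runs, then the same cascade.  ``report`` turns a
manifest into campaign statistics (per-stage pass rates, sampled fraction
of the library, hit rates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from evoscreen import chemlib
from evoscreen.chemlib import CombinatorialLibrary, LibraryMolecule
from evoscreen.errors import InputError
from evoscreen.evolve import EvolutionConfig, RunLog, aggregate_runs, run_evolution
from evoscreen.physchem import FilterConfig, audit_table, first_filter
from evoscreen.scoring import (
    OracleConfig,
    ScoredMolecule,
    SyntheticOracle,
    derive_seed,
    ensemble_consensus_filter,
    lid_root2,
    redock_consistency_filter,
    score_threshold_filter,
)
from evoscreen.select import cluster_compounds, fingerprint, similarity_budget_prune

# -- campaign statistics -------------------------------------------------


def _round_sig(x: float, n_sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n_sig - 1))


def hit_rate(hits: int, tested: int) -> float:
    """Hit rate as a percentage, 3 significant digits (3/138 → 2.17)."""
    if tested <= 0:
        raise InputError("tested must be positive")
    return _round_sig(100.0 * hits / tested, 3)


def sampled_fraction(sampled: int, library_size: int) -> float:
    """Sampled share of the space as a percentage, 2 significant digits."""
    if library_size <= 0:
        raise InputError("library_size must be positive")
    return _round_sig(100.0 * sampled / library_size, 2)


def pass_rate(passed: int, total: int) -> float:
    """Stage pass rate as a whole percentage (628/757 → 83)."""
    if total <= 0:
        raise InputError("total must be positive")
    return float(round(100.0 * passed / total))


def campaign_statistics(counts: dict[str, int]) -> dict[str, float]:
    """Compute campaign statistics from manifest-style counts.

    Recognized keys: (hits, tested) → ``hit_rate_pct``; (sampled,
    library_size) → ``sampled_fraction_pct``; (passed, total) →
    ``pass_rate_pct``.  Unknown keys are ignored so manifests can carry
    extra counts.
    """
    out: dict[str, float] = {}
    if "hits" in counts and "tested" in counts:
        out["hit_rate_pct"] = hit_rate(counts["hits"], counts["tested"])
    if "sampled" in counts and "library_size" in counts:
        out["sampled_fraction_pct"] = sampled_fraction(
            counts["sampled"], counts["library_size"])
    if "passed" in counts and "total" in counts:
        out["pass_rate_pct"] = pass_rate(counts["passed"], counts["total"])
    return out


# -- configuration -------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one screening campaign needs, under a single global seed."""

    rules_path: str
    blocks_path: str
    out_dir: str
    round_number: int = 1
    receptors: tuple[str, ...] = ("receptor-1",)
    off_target_receptor: str | None = None
    oracle: OracleConfig = field(default_factory=OracleConfig)
    off_target_oracle: OracleConfig | None = None  # defaults to `oracle`
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    n_runs: int = 2
    score_threshold: float = -3.5
    consistency_delta_max: float = 0.8
    consensus_std_max: float = 0.5
    redock_top_n: int = 10_000
    redock_poses: int = 600
    k_clusters: int = 100
    n_target: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.round_number not in (1, 2):
            raise InputError("round_number must be 1 or 2")
        if not self.receptors:
            raise InputError("at least one receptor is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "oracle" in raw:
            raw["oracle"] = OracleConfig(**raw["oracle"])
        if raw.get("off_target_oracle"):
            raw["off_target_oracle"] = OracleConfig(**raw["off_target_oracle"])
        if "evolution" in raw:
            raw["evolution"] = EvolutionConfig(**raw["evolution"])
        if "receptors" in raw:
            raw["receptors"] = tuple(raw["receptors"])
        return cls(**raw)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(round_number=self.round_number)


# -- internal cascade ----------------------------------------------------


@dataclass
class _Stage:
    stage: str
    n_in: int
    n_out: int
    detail: dict = field(default_factory=dict)

    @property
    def casualties(self) -> int:
        return self.n_in - self.n_out


class _Manifest:
    def __init__(self, out_dir: Path, config_summary: dict):
        self.out_dir = out_dir
        self.stages: list[_Stage] = []
        self.config_summary = config_summary

    def add(self, stage: _Stage) -> None:
        self.stages.append(stage)

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        payload = {
            "config": self.config_summary,
            "stages": [{
                "stage": s.stage, "n_in": s.n_in, "n_out": s.n_out,
                "casualties": s.casualties, **s.detail,
            } for s in self.stages],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _evolve_stage(
    library: CombinatorialLibrary,
    config: PipelineConfig,
    manifest: _Manifest,
    seeded_pool: list[LibraryMolecule] | None = None,
) -> tuple[pd.DataFrame, dict[str, LibraryMolecule]]:
    oracle = SyntheticOracle(replace(config.oracle, seed=derive_seed(config.seed, "oracle")))
    logs: list[RunLog] = []
    molecules: dict[str, LibraryMolecule] = {}
    for i in range(config.n_runs):
        receptor = config.receptors[i % len(config.receptors)]
        evo = replace(
            config.evolution,
            receptor_id=receptor,
            rng_seed=derive_seed(config.seed, "evolve", i),
            seeded_pool=seeded_pool,
        )
        log = run_evolution(library, oracle, evo, run_id=f"run-{i + 1}")
        logs.append(log)
        for key, ind in log.individuals.items():
            molecules.setdefault(key, ind.molecule)
    table = aggregate_runs(logs)
    manifest.add(_Stage(
        "evolve", n_in=len(table), n_out=len(table),
        detail={
            "n_runs": config.n_runs,
            "oracle_calls": sum(l.oracle_calls for l in logs),
            "cache_hits": sum(l.cache_hits for l in logs),
            "sampled_distinct": len(table),
            "library_size": library.product_count(),
        },
    ))
    return table, molecules


def _cascade(
    library: CombinatorialLibrary,
    table: pd.DataFrame,
    molecules: dict[str, LibraryMolecule],
    config: PipelineConfig,
    manifest: _Manifest,
    out_dir: Path,
) -> list[tuple[str, float]]:
    """Shared post-search cascade: triage → redock → filters → cluster → prune."""
    # first filter (hard properties + traffic lights + PAINS)
    keys = list(table["molecule_key"])
    survivors, audit = first_filter(keys, config.filter_config())
    audit_table(audit).to_csv(out_dir / "first_filter_audit.csv", index=False)
    by_stage = {}
    for rec in audit:
        if not rec.passed:
            by_stage[rec.stage] = by_stage.get(rec.stage, 0) + 1
    manifest.add(_Stage("first_filter", n_in=len(keys), n_out=len(survivors),
                        detail={"rejected_by_stage": by_stage}))

    # top-N selection by search-stage fitness
    fitness = dict(zip(table["molecule_key"], table["best_fitness"]))
    ranked = sorted(survivors, key=lambda k: (fitness[k], k))
    top = ranked[: config.redock_top_n]
    manifest.add(_Stage("top_n_selection", n_in=len(survivors), n_out=len(top),
                        detail={"redock_top_n": config.redock_top_n}))

    # redock with the expanded pose count against each receptor model
    redock_oracle = SyntheticOracle(replace(
        config.oracle,
        n_poses=config.redock_poses,
        seed=derive_seed(config.seed, "redock"),
    ))
    per_model: dict[str, dict[str, float]] = {}
    redock_top10: dict[str, list[float]] = {}
    for key in top:
        mol = molecules[key]
        n_heavy = chemlib.heavy_atom_count(key)
        per_model[key] = {}
        for receptor in config.receptors:
            result = redock_oracle.dock(mol, receptor)
            per_model[key][receptor] = lid_root2(result.best_interface_delta, n_heavy)
        best_receptor = min(per_model[key], key=per_model[key].get)
        result = redock_oracle.dock(mol, best_receptor)
        redock_top10[key] = [
            lid_root2(p.interface_delta, n_heavy) for p in result.poses[:10]
        ]

    # consistency between the search-stage score and redocking
    consistent = []
    for key in top:
        verdict = redock_consistency_filter(
            fitness[key], redock_top10[key], config.consistency_delta_max)
        if verdict.passed:
            consistent.append(key)
    manifest.add(_Stage("redock_consistency", n_in=len(top), n_out=len(consistent),
                        detail={"delta_max": config.consistency_delta_max}))

    # ensemble consensus across receptor models (round 2, >=2 models)
    scored: dict[str, float] = {}
    if config.round_number == 2 and len(config.receptors) >= 2:
        kept = []
        for key in consistent:
            verdict = ensemble_consensus_filter(per_model[key], config.consensus_std_max)
            if verdict.keep:
                kept.append(key)
                scored[key] = verdict.consensus
        manifest.add(_Stage("ensemble_consensus", n_in=len(consistent),
                            n_out=len(kept),
                            detail={"std_max": config.consensus_std_max}))
        consistent = kept
    else:
        for key in consistent:
            scored[key] = min(per_model[key].values())

    # lid_root2 threshold on the redock score
    scored_mols = [
        ScoredMolecule(
            molecule_key=key,
            heavy_atoms=chemlib.heavy_atom_count(key),
            best_interface_delta=scored[key] * math.sqrt(chemlib.heavy_atom_count(key)),
            lid_root2=scored[key],
            provenance="redock",
        )
        for key in consistent
    ]
    kept = score_threshold_filter(scored_mols, config.score_threshold, "keep_better")
    manifest.add(_Stage("score_threshold", n_in=len(scored_mols), n_out=len(kept),
                        detail={"threshold": config.score_threshold}))

    # off-target counter screen: discard predicted anti-target binders
    if config.off_target_receptor is not None:
        base = config.off_target_oracle or config.oracle
        off_oracle = SyntheticOracle(replace(
            base, seed=derive_seed(config.seed, "offtarget")))
        off_scored = []
        for s in kept:
            result = off_oracle.dock(molecules[s.molecule_key],
                                     config.off_target_receptor)
            off_scored.append(ScoredMolecule(
                molecule_key=s.molecule_key,
                heavy_atoms=s.heavy_atoms,
                best_interface_delta=result.best_interface_delta,
                lid_root2=lid_root2(result.best_interface_delta, s.heavy_atoms),
                provenance="offtarget",
            ))
        passed_keys = {
            s.molecule_key
            for s in score_threshold_filter(off_scored, config.score_threshold,
                                            "exclude_better")
        }
        n_in = len(kept)
        kept = [s for s in kept if s.molecule_key in passed_keys]
        manifest.add(_Stage("off_target", n_in=n_in, n_out=len(kept),
                            detail={"receptor": config.off_target_receptor,
                                    "threshold": config.score_threshold}))

    # clustering into diversity groups
    pairs = [(s.molecule_key, s.lid_root2) for s in kept]
    if pairs:
        fps = [fingerprint(k) for k, _ in pairs]
        assignment = cluster_compounds(
            fps, k=config.k_clusters, seed=derive_seed(config.seed, "cluster"),
            scores=dict(pairs))
        cluster_rows = [{
            "cluster": cid,
            "size": len(assignment.members(cid)),
            "representative": assignment.representatives.get(cid, ""),
            "best_score": min(dict(pairs)[k] for k in assignment.members(cid)),
        } for cid in range(assignment.k)]
        pd.DataFrame(cluster_rows).to_csv(out_dir / "clusters.csv", index=False)
        manifest.add(_Stage("cluster", n_in=len(pairs), n_out=len(pairs),
                            detail={"k": assignment.k}))

    # budget pruning down to the purchasable set
    if len(pairs) > config.n_target:
        pruned, removals = similarity_budget_prune(pairs, config.n_target)
        pd.DataFrame([{
            "step": r.step, "removed": r.removed_key, "kept": r.kept_key,
            "similarity": r.similarity,
        } for r in removals]).to_csv(out_dir / "prune_audit.csv", index=False)
        manifest.add(_Stage("prune", n_in=len(pairs), n_out=len(pruned),
                            detail={"n_target": config.n_target}))
        pairs = pruned

    pd.DataFrame(pairs, columns=["molecule_key", "lid_root2"]).to_csv(
        out_dir / "selection.csv", index=False)
    return pairs


def run_screen(config: PipelineConfig) -> Path:
    """Execute the full screening pipeline; returns the output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = chemlib.load_library(config.rules_path, config.blocks_path)
    manifest = _Manifest(out_dir, {
        "round": config.round_number, "seed": config.seed,
        "n_runs": config.n_runs, "receptors": list(config.receptors),
        "mode": "screen",
    })
    table, molecules = _evolve_stage(library, config, manifest)
    table.to_csv(out_dir / "aggregate.csv", index=False)
    _cascade(library, table, molecules, config, manifest, out_dir)
    manifest.write()
    return out_dir


def run_expand(config: PipelineConfig, hit: LibraryMolecule) -> Path:
    """Hit-expansion round: partner enumeration seeds the evolutionary runs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = chemlib.load_library(config.rules_path, config.blocks_path)
    manifest = _Manifest(out_dir, {
        "round": config.round_number, "seed": config.seed,
        "n_runs": config.n_runs, "receptors": list(config.receptors),
        "mode": "expand", "hit": hit.product_smiles,
    })

    expansion = chemlib.expand_partners(library, hit)
    manifest.add(_Stage("expand_partners", n_in=1, n_out=len(expansion)))

    # dock the expansion and keep candidates better than the threshold
    oracle = SyntheticOracle(replace(config.oracle,
                                     seed=derive_seed(config.seed, "oracle")))
    scored = []
    for mol in expansion:
        result = oracle.dock(mol, config.receptors[0])
        n = chemlib.heavy_atom_count(mol.product_smiles)
        scored.append(ScoredMolecule(
            molecule_key=mol.product_smiles, heavy_atoms=n,
            best_interface_delta=result.best_interface_delta,
            lid_root2=lid_root2(result.best_interface_delta, n),
            provenance="evolve",
        ))
    kept = score_threshold_filter(scored, config.score_threshold, "keep_better")
    kept_keys = {s.molecule_key for s in kept}
    pool = [m for m in expansion if m.product_smiles in kept_keys]
    manifest.add(_Stage("expansion_score_filter", n_in=len(expansion),
                        n_out=len(pool),
                        detail={"threshold": config.score_threshold}))

    table, molecules = _evolve_stage(library, config, manifest, seeded_pool=pool or expansion)
    table.to_csv(out_dir / "aggregate.csv", index=False)
    _cascade(library, table, molecules, config, manifest, out_dir)
    manifest.write()
    return out_dir


def report(run_dir: str | Path) -> dict:
    """Summarize a finished run from its manifest.

    Emits per-stage pass rates (whole percent), the sampled fraction of
    the library, and echoes the stage counts; raw values are written to
    ``report.json`` alongside the manifest.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    stages = []
    for s in manifest["stages"]:
        entry = dict(s)
        if s["n_in"] > 0:
            entry["pass_rate_pct"] = pass_rate(s["n_out"], s["n_in"])
        stages.append(entry)
    out: dict = {"stages": stages}
    evolve_stage = next((s for s in manifest["stages"] if s["stage"] == "evolve"), None)
    if evolve_stage and evolve_stage.get("library_size"):
        out["sampled_fraction_pct"] = sampled_fraction(
            evolve_stage["sampled_distinct"], evolve_stage["library_size"])
    (run_dir / "report.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    return out
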