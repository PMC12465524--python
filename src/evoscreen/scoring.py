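"""Docking fitness, score-based filters and the docking-oracle contract.

The pipeline's fitness and filtering currency is ``lid_root2`` — the
ligand interface delta (Rosetta energy units, more negative = better)
divided by the square root of the heavy-atom count, which removes the bias
of raw interface energies toward large molecules.

A docking oracle is anything with a ``dock(molecule, receptor_id)`` method
returning a :class:`DockingResult`.  Two implementations are provided: a
synthetic oracle whose pseudo-energy landscape is planted around a target
motif (for desk-scale testing and benchmarking), and a table oracle backed
by externally computed score tables.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from evoscreen.chemlib import LibraryMolecule, heavy_atom_count
from evoscreen.errors import InputError, OracleConfigError, ScoreTableError
from evoscreen.select import fingerprint, tanimoto


def derive_seed(base_seed: int, *tokens: object) -> int:
    """Derive a stable sub-stream seed (< 2**31) from a base seed and tokens."""
    h = hashlib.sha256(repr((int(base_seed),) + tokens).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def lid_root2(interface_delta: float, heavy_atoms: int) -> float:
    """Size-normalized docking score: interface_delta / sqrt(heavy_atoms)."""
    if heavy_atoms < 1:
        raise InputError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    return interface_delta / math.sqrt(heavy_atoms)


@dataclass(frozen=True)
class Pose:
    """One docked pose: interface energy plus optional heavy-atom coordinates."""

    interface_delta: float  # REU
    coordinates: np.ndarray | None = None  # (n_heavy, 3) Angstrom


@dataclass
class DockingResult:
    """All poses of one molecule against one receptor, best first."""

    molecule_key: str
    receptor_id: str
    poses: list[Pose]

    def __post_init__(self) -> None:
        if not self.poses:
            raise InputError("DockingResult requires at least one pose")
        self.poses.sort(key=lambda p: p.interface_delta)

    @property
    def best_interface_delta(self) -> float:
        return self.poses[0].interface_delta


@dataclass(frozen=True)
class ScoredMolecule:
    """A molecule key with its best interface energy and lid_root2 fitness."""

    molecule_key: str
    heavy_atoms: int
    best_interface_delta: float
    lid_root2: float
    provenance: str  # 'evolve' | 'redock' | 'offtarget'

    def __post_init__(self) -> None:
        expected = self.best_interface_delta / math.sqrt(self.heavy_atoms)
        if not math.isclose(self.lid_root2, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise InputError("lid_root2 inconsistent with interface delta and size")


def score_result(
    result: DockingResult, heavy_atoms: int | None = None, provenance: str = "evolve"
) -> ScoredMolecule:
    """Attach the lid_root2 fitness to a docking result."""
    n = heavy_atoms if heavy_atoms is not None else heavy_atom_count(result.molecule_key)
    best = result.best_interface_delta
    return ScoredMolecule(
        molecule_key=result.molecule_key,
        heavy_atoms=n,
        best_interface_delta=best,
        lid_root2=lid_root2(best, n),
        provenance=provenance,
    )


# -- score-based filters -------------------------------------------------


def score_threshold_filter(
    scored: Sequence[ScoredMolecule],
    threshold: float = -3.5,
    mode: str = "keep_better",
) -> list[ScoredMolecule]:
    """Cut a scored list at a lid_root2 threshold.

    "Better" means lid_root2 <= threshold (the boundary value counts as
    better).  ``keep_better`` retains the better molecules (on-target
    triage); ``exclude_better`` removes them (off-target counter screen,
    where predicted anti-target binders are discarded).
    """
    if mode not in ("keep_better", "exclude_better"):
        raise InputError(f"unknown mode {mode!r}")
    better = [s for s in scored if s.lid_root2 <= threshold]
    if mode == "keep_better":
        return better
    better_keys = {s.molecule_key for s in better}
    return [s for s in scored if s.molecule_key not in better_keys]


@dataclass(frozen=True)
class ConsistencyVerdict:
    passed: bool
    delta_engine_vs_redock: float  # |search-stage score - best redock score|
    delta_top10_spread: float  # worst - best among the top-10 redock poses


def redock_consistency_filter(
    revold_score: float,
    redock_poses_top10: Sequence[float],
    delta_max: float = 0.8,
    require_both: bool = False,
) -> ConsistencyVerdict:
    """Flag docking artifacts by score instability between stages.

    Two deltas are computed from the (sorted, best-first, at most ten)
    redock lid_root2 scores: the gap to the search-stage score and the
    spread among the top-10 redock poses.  By default the compound fails if
    EITHER delta exceeds ``delta_max`` (the conservative reading; set
    ``require_both`` to demand both).
    """
    if not redock_poses_top10:
        raise InputError("redock pose list is empty")
    if len(redock_poses_top10) > 10:
        raise InputError("at most the ten best redock poses are expected")
    scores = list(redock_poses_top10)
    if scores != sorted(scores):
        raise InputError("redock poses must be sorted best-first")
    d1 = abs(revold_score - scores[0])
    d2 = scores[-1] - scores[0]
    if require_both:
        failed = d1 > delta_max and d2 > delta_max
    else:
        failed = d1 > delta_max or d2 > delta_max
    return ConsistencyVerdict(not failed, d1, d2)


@dataclass(frozen=True)
class ConsensusVerdict:
    consensus: float  # mean of per-model best lid_root2
    std: float  # population standard deviation
    keep: bool


def ensemble_consensus_filter(
    per_model_scores: dict[str, float], std_max: float = 0.5
) -> ConsensusVerdict:
    """Aggregate per-receptor-model lid_root2 scores into a consensus.

    The consensus is the arithmetic mean over models; the spread is the
    population standard deviation (the models ARE the ensemble, not a
    sample).  Compounds with std above ``std_max`` are flagged for
    exclusion.
    """
    if len(per_model_scores) < 2:
        raise InputError("consensus needs at least two receptor models")
    vals = np.array(list(per_model_scores.values()), dtype=float)
    std = float(vals.std(ddof=0))
    return ConsensusVerdict(float(vals.mean()), std, std <= std_max)


# -- oracles -------------------------------------------------------------


@dataclass
class OracleConfig:
    """Synthetic-oracle landscape and pose-sampling parameters.

    The pseudo-energy planted around ``motif_smiles`` is
    ``base = -similarity_weight * tanimoto(molecule, motif)
    - size_weight * sqrt(heavy_atoms)`` REU; pose ``i`` adds
    ``pose_spread * i`` plus Normal(0, noise_scale) noise drawn from a
    stream keyed by (seed, molecule, receptor).  With ``noise_scale`` 0 the
    oracle is a pure function of (molecule, receptor, config).
    """

    motif_smiles: str = ""
    n_poses: int = 150  # 200 for exploratory grids, 600 for redocking
    seed: int = 0
    similarity_weight: float = 15.0  # REU at tanimoto 1
    size_weight: float = 1.0  # REU per sqrt(heavy atom)
    noise_scale: float = 0.0  # REU, per-pose
    pose_spread: float = 0.3  # REU added per pose rank
    with_coordinates: bool = False
    coordinate_jitter: float = 0.5  # Angstrom per REU above the best pose

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise OracleConfigError("n_poses must be >= 1")
        if self.noise_scale < 0:
            raise OracleConfigError("noise_scale must be >= 0")


class DockingOracle(Protocol):
    def dock(self, molecule: LibraryMolecule, receptor_id: str) -> DockingResult: ...


def _motif_coordinates(n_atoms: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(derive_seed(seed, "motif-coords", n_atoms))
    return rng.normal(scale=2.0, size=(n_atoms, 3))


def synthetic_dock(
    molecule: LibraryMolecule,
    receptor_id: str,
    config: OracleConfig,
    rng: np.random.Generator | None = None,
) -> DockingResult:
    """Dock a molecule against the synthetic planted landscape.

    The noise stream is derived from (config.seed, molecule key, receptor)
    unless an explicit ``rng`` is passed, so results are reproducible and
    cache-consistent across call orders.  Coordinates, when requested, are
    planted reference coordinates plus jitter growing with pose energy, so
    funnel analyses see the expected monotone structure.
    """
    if not config.motif_smiles:
        raise OracleConfigError("oracle config has no target motif")
    try:
        motif_fp = fingerprint(config.motif_smiles)
    except InputError as exc:
        raise OracleConfigError(f"invalid motif SMILES: {exc}") from exc
    mol_fp = fingerprint(molecule.product_smiles)
    n_heavy = heavy_atom_count(molecule.product_smiles)
    sim = tanimoto(mol_fp, motif_fp)
    base = -config.similarity_weight * sim - config.size_weight * math.sqrt(n_heavy)
    if rng is None:
        rng = np.random.default_rng(
            derive_seed(config.seed, molecule.product_smiles, receptor_id)
        )
    energies = base + config.pose_spread * np.arange(config.n_poses)
    if config.noise_scale > 0:
        energies = energies + rng.normal(scale=config.noise_scale,
                                         size=config.n_poses)
    order = np.argsort(energies, kind="stable")
    energies = energies[order]
    poses = []
    if config.with_coordinates:
        ref = _motif_coordinates(n_heavy, config.seed)
        for e in energies:
            jitter_scale = config.coordinate_jitter * max(0.0, float(e - energies[0]))
            coords = ref + rng.normal(scale=jitter_scale, size=ref.shape)
            poses.append(Pose(float(e), coords))
    else:
        poses = [Pose(float(e)) for e in energies]
    return DockingResult(
        molecule_key=molecule.product_smiles,
        receptor_id=receptor_id,
        poses=poses,
    )


class SyntheticOracle:
    """Planted-landscape oracle implementing the docking-oracle contract."""

    def __init__(self, config: OracleConfig):
        self.config = config
        self.n_calls = 0

    def dock(self, molecule: LibraryMolecule, receptor_id: str) -> DockingResult:
        self.n_calls += 1
        return synthetic_dock(molecule, receptor_id, self.config)

    def with_poses(self, n_poses: int) -> "SyntheticOracle":
        return SyntheticOracle(replace(self.config, n_poses=n_poses))


class TableOracle:
    """Oracle backed by an externally computed docking score table."""

    def __init__(self, results: Sequence[DockingResult]):
        self._by_key: dict[tuple[str, str], DockingResult] = {
            (r.molecule_key, r.receptor_id): r for r in results
        }
        self.n_calls = 0

    def dock(self, molecule: LibraryMolecule, receptor_id: str) -> DockingResult:
        self.n_calls += 1
        try:
            return self._by_key[(molecule.product_smiles, receptor_id)]
        except KeyError as exc:
            raise ScoreTableError(
                f"no docking record for {molecule.product_smiles!r} against "
                f"{receptor_id!r}"
            ) from exc


# -- score-table I/O -----------------------------------------------------

_TABLE_COLUMNS = ["molecule_key", "receptor_id", "pose_index", "interface_delta"]


def write_score_table(results: Sequence[DockingResult], path: str | Path) -> None:
    """Write docking results as a per-pose CSV score table."""
    rows = []
    for res in results:
        for i, pose in enumerate(res.poses):
            rows.append({
                "molecule_key": res.molecule_key,
                "receptor_id": res.receptor_id,
                "pose_index": i,
                "interface_delta": pose.interface_delta,
            })
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def dock_adapter(score_table_path: str | Path) -> list[DockingResult]:
    """Parse an external per-pose CSV score table into docking results.

    Malformed rows are skipped with a warning; a file from which nothing
    parses is a file-level error.  Poses are sorted best-first per
    (molecule, receptor).
    """
    path = Path(score_table_path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ScoreTableError(f"cannot read score table {path}: {exc}") from exc
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ScoreTableError(f"score table {path} lacks columns {missing}")
    df["interface_delta"] = pd.to_numeric(df["interface_delta"], errors="coerce")
    bad = df["interface_delta"].isna() | df["molecule_key"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} malformed rows skipped in {path.name}")
        df = df[~bad]
    if df.empty:
        raise ScoreTableError(f"no parsable rows in score table {path}")
    results = []
    for (key, receptor), grp in df.groupby(["molecule_key", "receptor_id"], sort=True):
        poses = [Pose(float(e)) for e in grp["interface_delta"]]
        results.append(DockingResult(molecule_key=str(key),
                                     receptor_id=str(receptor), poses=poses))
    return results
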