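"""Synthetic data generation: toy libraries, planted landscapes, toy complexes.

Everything the pipeline consumes at production scale under NDA or from
heavyweight docking engines is emulated here at desk scale: combinatorial
toy libraries with the same two-file TSV shape as real vendor
specifications, planted pseudo-energy landscapes with recorded brute-force
rankings, and minimal receptor/pose systems with known contact and funnel
ground truth.  Every generator is deterministic under its seed.

Toy substrates are drawn from curated, reliably-reactive families
(carboxylic acids and primary amines, in aliphatic and aromatic flavours)
so that reaction-SMARTS application never fails silently and test signal
isolates engine behaviour from chemistry edge cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem

from evoscreen.chemlib import (
    CombinatorialLibrary,
    LibraryMolecule,
    enumerate_products,
    heavy_atom_count,
    load_library,
)
from evoscreen.errors import InputError
from evoscreen.scoring import OracleConfig, synthetic_dock

ENUMERABLE_BOUND = 100_000

AMIDE_2C = "[C:1](=O)[OH].[N;H2:2]>>[C:1](=O)[N:2]"
DIACYL_3C = "[C:1](=O)[OH].[N;H2:2].[C:3](=O)[OH]>>[C:1](=O)[N:2][C:3]=O"


# -- substrate family pools ---------------------------------------------


def _alkyl_fragments() -> list[str]:
    """Distinct alkyl SMILES prefixes: chains, branches, small rings."""
    frags = [("C" * i) for i in range(1, 13)]
    frags += ["CC(C)", "CCC(C)", "CC(C)C", "CCCC(C)", "CC(C)CC", "CC(C)(C)",
              "CCC(C)C", "CCC(CC)", "CC(CC)C", "CCCC(C)C", "CC(C)C(C)",
              "CCCCC(C)", "CC(C)CCC", "CCC(C)CC"]
    frags += ["C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CC1C", "C1CCC1C",
              "C1CCCC1C", "C1CCCCC1C"]
    return frags


_ARYL_DECORATIONS = [
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "C(C)C", "C(F)(F)F",
    "OC", "OCC", "CO", "CCO", "C#N", "C=C", "CC=C", "OC(C)C",
    "SC", "CS", "C(C)(C)C", "CCCC", "OC(F)(F)F", "CF", "CCl",
]


def _family_pool(kind: str, family: str) -> list[str]:
    """Candidate substrate SMILES for (acid|amine) x (aliphatic|aromatic)."""
    out: list[str] = []
    if kind == "acid":
        if family in ("aliphatic", "mixed"):
            out += [f"{r}C(=O)O" for r in _alkyl_fragments()]
        if family in ("aromatic", "mixed"):
            out += ["O=C(O)c1ccccc1"]
            out += [f"O=C(O)c1ccc({d})cc1" for d in _ARYL_DECORATIONS]
            out += [f"O=C(O)c1cccc({d})c1" for d in _ARYL_DECORATIONS]
    elif kind == "amine":
        if family in ("aliphatic", "mixed"):
            out += [f"{r}N" for r in _alkyl_fragments()]
        if family in ("aromatic", "mixed"):
            out += ["Nc1ccccc1", "NCc1ccccc1"]
            out += [f"Nc1ccc({d})cc1" for d in _ARYL_DECORATIONS]
            out += [f"NCc1ccc({d})cc1" for d in _ARYL_DECORATIONS]
    else:
        raise InputError(f"unknown substrate kind {kind!r}")
    # canonical-dedup while preserving order; drop anything unparsable
    seen: set[str] = set()
    pool: list[str] = []
    for smi in out:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            pool.append(smi)
    return pool


@dataclass(frozen=True)
class ReactionSpec:
    """Shape of one toy building rule."""

    arity: int
    slot_sizes: tuple[int, ...]
    family: str = "mixed"  # aliphatic | aromatic | mixed

    def __post_init__(self) -> None:
        if self.arity not in (2, 3):
            raise InputError("arity must be 2 or 3")
        if len(self.slot_sizes) != self.arity:
            raise InputError("slot_sizes must match arity")


@dataclass(frozen=True)
class ToyLibrarySpec:
    """Shape of a whole toy library; must stay enumerable in memory."""

    reactions: tuple[ReactionSpec, ...]
    seed: int = 0

    def product_count(self) -> int:
        return sum(int(np.prod(r.slot_sizes)) for r in self.reactions)


def make_toy_library(
    spec: ToyLibrarySpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a toy library as (rules TSV, blocks TSV) in the standard dialect.

    Slot 0 (and slot 2 of three-component rules) is filled with carboxylic
    acids, slot 1 with primary amines, drawn deterministically (seeded,
    without replacement) from the requested structural family.  Byte
    identical under the same spec.
    """
    if spec.product_count() > ENUMERABLE_BOUND:
        raise InputError(
            f"spec enumerates {spec.product_count()} products, above the "
            f"{ENUMERABLE_BOUND} bound"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rules_path = out_dir / "rules.tsv"
    blocks_path = out_dir / "blocks.tsv"

    rng = np.random.default_rng(spec.seed)
    rule_rows: list[str] = []
    block_rows: list[str] = []
    for ri, rxn in enumerate(spec.reactions):
        rid = f"rxn-{ri + 1}"
        smarts = AMIDE_2C if rxn.arity == 2 else DIACYL_3C
        rule_rows.append(f"{rid}\t{smarts}\t{rxn.arity}")
        for pos in range(rxn.arity):
            kind = "amine" if pos == 1 else "acid"
            pool = _family_pool(kind, rxn.family)
            n = rxn.slot_sizes[pos]
            if n > len(pool):
                raise InputError(
                    f"slot {pos} of {rid} wants {n} substrates but the "
                    f"{rxn.family} {kind} pool has only {len(pool)}"
                )
            chosen = rng.choice(len(pool), size=n, replace=False)
            for si, pi in enumerate(sorted(chosen)):
                sid = f"{rid}-p{pos}-s{si + 1}"
                block_rows.append(f"{sid}\t{pool[pi]}\t{rid}\t{pos}")

    rules_path.write_text(
        "# building rules: reaction_id\tsmarts\tarity\n"
        + "\n".join(rule_rows) + "\n",
        encoding="utf-8",
    )
    blocks_path.write_text(
        "# building blocks: substrate_id\tsmiles\treaction_id\tposition\n"
        + "\n".join(block_rows) + "\n",
        encoding="utf-8",
    )
    return rules_path, blocks_path


# -- planted landscape ---------------------------------------------------


@dataclass
class PlantedLandscape:
    """A planted-optimum pseudo-energy landscape over an enumerable library."""

    motif: LibraryMolecule
    similarity_weight: float
    size_weight: float
    noise_scale: float
    ranking: pd.DataFrame  # molecule_key, lid_root2, noiseless, sorted best-first

    def rank_of(self, molecule_key: str) -> int:
        """0-based brute-force rank of a molecule (best = 0)."""
        pos = self.ranking.index[self.ranking["molecule_key"] == molecule_key]
        if len(pos) == 0:
            raise InputError(f"{molecule_key!r} is not in the recorded ranking")
        return int(pos[0])


def brute_force_ranking(
    library: CombinatorialLibrary, config: OracleConfig, receptor_id: str = "receptor-1"
) -> pd.DataFrame:
    """Enumerate every product and rank it by noiseless lid_root2."""
    rows = []
    seen: set[str] = set()
    noiseless = OracleConfig(
        motif_smiles=config.motif_smiles,
        n_poses=1,
        seed=config.seed,
        similarity_weight=config.similarity_weight,
        size_weight=config.size_weight,
        noise_scale=0.0,
        pose_spread=config.pose_spread,
    )
    for mol in enumerate_products(library):
        if mol.product_smiles in seen:
            continue
        seen.add(mol.product_smiles)
        res = synthetic_dock(mol, receptor_id, noiseless)
        n = heavy_atom_count(mol.product_smiles)
        rows.append({
            "molecule_key": mol.product_smiles,
            "lid_root2": res.best_interface_delta / np.sqrt(n),
        })
    return (
        pd.DataFrame(rows)
        .sort_values(["lid_root2", "molecule_key"], ignore_index=True)
    )


def make_planted_landscape(
    library: CombinatorialLibrary,
    rng: np.random.Generator,
    similarity_weight: float = 15.0,
    size_weight: float = 1.0,
    noise_scale: float = 0.0,
    n_poses: int = 5,
) -> tuple[PlantedLandscape, OracleConfig]:
    """Pick a motif molecule and build the matching oracle configuration.

    The full noiseless brute-force ranking is recorded so downstream tests
    can compare search results against an exact enumeration oracle without
    re-deriving it.
    """
    products = list(enumerate_products(library))
    if not products:
        raise InputError("library has no products")
    motif = products[int(rng.integers(len(products)))]
    config = OracleConfig(
        motif_smiles=motif.product_smiles,
        n_poses=n_poses,
        seed=int(rng.integers(2**31)),
        similarity_weight=similarity_weight,
        size_weight=size_weight,
        noise_scale=noise_scale,
    )
    ranking = brute_force_ranking(library, config)
    landscape = PlantedLandscape(
        motif=motif,
        similarity_weight=similarity_weight,
        size_weight=size_weight,
        noise_scale=noise_scale,
        ranking=ranking,
    )
    return landscape, config


# -- toy receptor and poses ----------------------------------------------

_RESIDUE_SPACING = 10.0  # Angstrom between residue centers
_CONTACT_DISTANCE = 3.0  # planted in-contact nearest-atom distance
_FAR_DISTANCE = 9.0  # planted out-of-contact distance


def _write_receptor_pdb(path: Path, centers: np.ndarray) -> list[np.ndarray]:
    """Write a minimal glycine-backbone receptor; returns residue atom sets."""
    structure = gemmi.Structure()
    structure.name = "toy-receptor"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    offsets = np.array([[-0.7, 0.5, 0.0], [0.0, 0.0, 0.0], [0.7, 0.5, 0.0]])
    names = ["N", "CA", "C"]
    elements = ["N", "C", "C"]
    residue_coords = []
    for i, center in enumerate(centers):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i + 1, " ")
        coords = center + offsets
        for name, elem, xyz in zip(names, elements, coords):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        chain.add_residue(res)
        residue_coords.append(coords)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
    return residue_coords


def _alkane_mol(n_atoms: int, coords: np.ndarray) -> Chem.Mol:
    mol = Chem.RWMol()
    for _ in range(n_atoms):
        mol.AddAtom(Chem.Atom(6))
    for i in range(n_atoms - 1):
        mol.AddBond(i, i + 1, Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(n_atoms)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*map(float, xyz)))
    m.AddConformer(conf)
    return m


def _chain_coords(n_atoms: int, anchor: np.ndarray, direction: np.ndarray) -> np.ndarray:
    direction = direction / np.linalg.norm(direction)
    return anchor + np.outer(np.arange(n_atoms), direction * 1.5)


def make_toy_receptor_and_poses(
    n_residues: int,
    n_compounds: int,
    geometry: str = "funnel",
    rng: np.random.Generator | None = None,
    out_dir: str | Path = ".",
    n_poses: int = 20,
    contact_probability: float = 0.6,
    cutoff: float = 4.0,
) -> dict[str, Path]:
    """Emit a toy receptor/pose system with recorded ground truth.

    The receptor is a line of ``n_residues`` three-atom backbone residues.
    Each compound is a short alkane whose best pose is planted either in
    contact with one residue (nearest-atom distance 3 Å) or far away
    (9 Å).  ``funnel`` geometry jitters worse-scoring poses progressively
    further from the best pose; ``scatter`` jitters all non-best poses by a
    constant large amount, destroying the RMSD-score correlation.  Written
    files: ``receptor.pdb``, ``poses.sdf`` (all poses), ``best_poses.sdf``
    (best pose per compound), ``scores.csv``, ``truth.json``.
    """
    if geometry not in ("funnel", "scatter"):
        raise InputError(f"unknown geometry {geometry!r}")
    if n_residues < 1 or n_compounds < 1:
        raise InputError("need at least one residue and one compound")
    rng = rng if rng is not None else np.random.default_rng(0)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    centers = np.array([[_RESIDUE_SPACING * i, 0.0, 0.0] for i in range(n_residues)])
    residue_coords = _write_receptor_pdb(out_dir / "receptor.pdb", centers)

    writer = Chem.SDWriter(str(out_dir / "poses.sdf"))
    best_writer = Chem.SDWriter(str(out_dir / "best_poses.sdf"))
    score_rows = []
    best_pose_coords: dict[str, np.ndarray] = {}
    truth_contacts: dict[str, list[str]] = {}
    n_atoms_by_key: dict[str, int] = {}
    for j in range(n_compounds):
        key = f"compound-{j + 1}"
        n_atoms = 4 + (j % 4)
        target = j % n_residues
        in_contact = bool(rng.random() < contact_probability)
        # anchor the chain head at the planted distance from the residue CA,
        # pointing away from the receptor line
        distance = _CONTACT_DISTANCE if in_contact else _FAR_DISTANCE
        anchor = centers[target] + np.array([0.0, distance, 0.0])
        ref = _chain_coords(n_atoms, anchor, np.array([0.0, 1.0, 0.3]))
        scores = -12.0 + 0.4 * np.arange(n_poses)
        for p in range(n_poses):
            if p == 0:
                coords = ref
            elif geometry == "funnel":
                jitter = 0.15 * (scores[p] - scores[0])
                coords = ref + rng.normal(scale=jitter, size=ref.shape)
            else:
                coords = ref + rng.normal(scale=4.0, size=ref.shape)
            mol = _alkane_mol(n_atoms, coords)
            mol.SetProp("molecule_key", key)
            mol.SetProp("pose_id", f"{key}/pose-{p}")
            mol.SetProp("interface_delta", f"{scores[p]:.4f}")
            writer.write(mol)
            if p == 0:
                best_writer.write(mol)
                best_pose_coords[key] = coords
            score_rows.append({
                "molecule_key": key, "pose_id": f"{key}/pose-{p}",
                "pose_index": p, "interface_delta": scores[p],
            })
        n_atoms_by_key[key] = n_atoms
    writer.close()
    best_writer.close()
    pd.DataFrame(score_rows).to_csv(out_dir / "scores.csv", index=False)

    # ground-truth contact counts by independent all-pairs distance check
    truth_counts: dict[str, int] = {}
    for i, res in enumerate(residue_coords):
        label = f"A/GLY{i + 1}"
        count = 0
        for key, coords in best_pose_coords.items():
            diff = coords[:, None, :] - res[None, :, :]
            if (np.sqrt((diff**2).sum(axis=2)) <= cutoff).any():
                count += 1
                truth_contacts.setdefault(label, []).append(key)
        truth_counts[label] = count
    truth = {
        "cutoff": cutoff,
        "geometry": geometry,
        "n_compounds": n_compounds,
        "contact_counts": truth_counts,
        "contacting_compounds": truth_contacts,
        "n_atoms_by_compound": n_atoms_by_key,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return {
        "receptor": out_dir / "receptor.pdb",
        "poses": out_dir / "poses.sdf",
        "best_poses": out_dir / "best_poses.sdf",
        "scores": out_dir / "scores.csv",
        "truth": out_dir / "truth.json",
    }


def load_toy_library(spec: ToyLibrarySpec, out_dir: str | Path) -> CombinatorialLibrary:
    """Convenience: write a toy library and load it back through the parser."""
    rules, blocks = make_toy_library(spec, out_dir)
    return load_library(rules, blocks)
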