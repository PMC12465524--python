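"""Structural post-processing of docked ligand clouds.

Three analyses support pose-level triage and binding-site interpretation:

* a residue-contact consensus map — for each receptor residue, the number
  of distinct compounds whose best pose places any heavy atom within a
  cutoff (default 4 Å) of any residue heavy atom, binned for display;
* fixed-correspondence ligand RMSD between poses of the same molecule in
  the shared receptor frame (no re-superposition, hydrogens ignored);
* the RMSD-score funnel table behind pose-convergence plots, where the
  RMSD to the best-scored pose is computed only for poses with interface
  score better than a floor (default −10 REU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem

from evoscreen.errors import InputError
from evoscreen.scoring import lid_root2

# descending half-open contact-count bins (shared-display convention)
CONTACT_BINS: tuple[tuple[str, float, float], ...] = (
    (">500", 500, math.inf),
    ("400-500", 400, 500),
    ("200-400", 200, 400),
    ("100-200", 100, 200),
    ("<=100", -math.inf, 100),
)


@dataclass(frozen=True)
class ResidueKey:
    chain: str
    resnum: int
    icode: str
    resname: str

    def label(self) -> str:
        return f"{self.chain}/{self.resname}{self.resnum}{self.icode}".rstrip()


@dataclass
class ReceptorStructure:
    """Ordered residues with heavy-atom coordinates, author numbering kept."""

    source_id: str
    residues: list[tuple[ResidueKey, np.ndarray]]  # (key, (n_heavy, 3) Å)

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError("receptor has no residues")


def read_receptor(path: str | Path, source_id: str | None = None) -> ReceptorStructure:
    """Read a receptor from PDB: ATOM/HETATM heavy atoms, first altloc kept,
    insertion codes preserved in the residue keys."""
    path = Path(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    residues: list[tuple[ResidueKey, np.ndarray]] = []
    model = structure[0]
    for chain in model:
        for res in chain:
            coords = []
            seen_names: set[str] = set()
            for atom in res:
                if atom.element.name == "H":
                    continue
                if atom.name in seen_names:  # keep first altloc only
                    continue
                seen_names.add(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if coords:
                key = ResidueKey(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    resname=res.name,
                )
                residues.append((key, np.array(coords, dtype=float)))
    return ReceptorStructure(source_id=source_id or path.stem, residues=residues)


@dataclass
class LigandPose:
    """One docked pose of one molecule in the receptor frame."""

    molecule_key: str
    pose_id: str
    coordinates: np.ndarray  # (n_heavy, 3) Å, fixed atom order per molecule
    interface_score: float  # REU

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InputError("pose coordinates must have shape (n_atoms, 3)")
        if not np.isfinite(self.coordinates).all():
            raise InputError("pose coordinates must be finite")

    @property
    def lid_root2(self) -> float:
        return lid_root2(self.interface_score, self.coordinates.shape[0])


def load_poses_sdf(path: str | Path) -> list[LigandPose]:
    """Read poses from an SDF with ``molecule_key``, ``pose_id`` and
    ``interface_delta`` data fields; heavy-atom conformer coordinates are
    taken in file atom order."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    poses: list[LigandPose] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        conf = mol.GetConformer()
        coords = [
            list(conf.GetAtomPosition(a.GetIdx()))
            for a in mol.GetAtoms()
            if a.GetAtomicNum() != 1
        ]
        poses.append(LigandPose(
            molecule_key=mol.GetProp("molecule_key") if mol.HasProp("molecule_key")
            else Chem.MolToSmiles(mol),
            pose_id=mol.GetProp("pose_id") if mol.HasProp("pose_id") else str(i),
            coordinates=np.array(coords),
            interface_score=float(mol.GetProp("interface_delta")),
        ))
    if not poses:
        raise InputError(f"no poses read from {path}")
    return poses


@dataclass
class ContactMap:
    """Per-residue distinct-compound contact counts with display bins."""

    cutoff: float
    counts: dict[ResidueKey, int] = field(default_factory=dict)
    n_compounds: int = 0

    def bin_label(self, residue: ResidueKey) -> str:
        count = self.counts.get(residue, 0)
        for label, lo, hi in CONTACT_BINS:
            if lo < count <= hi:
                return label
        return CONTACT_BINS[-1][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chain": k.chain, "resnum": k.resnum, "icode": k.icode,
            "resname": k.resname, "count": c, "bin": self.bin_label(k),
        } for k, c in self.counts.items()])


def residue_contact_map(
    receptor: ReceptorStructure,
    poses: Sequence[LigandPose],
    cutoff: float = 4.0,
) -> ContactMap:
    """Count, per residue, the distinct compounds within the cutoff.

    ``poses`` should hold one representative (best-scored) pose per
    compound; a compound counts once for a residue if ANY of its heavy
    atoms lies within ``cutoff`` of ANY residue heavy atom, regardless of
    how many atoms are in range.  Hydrogens are ignored on both sides.
    """
    if not poses:
        raise InputError("no poses given")
    seen_keys = [p.molecule_key for p in poses]
    if len(set(seen_keys)) != len(seen_keys):
        raise InputError("expected one representative pose per compound")
    cmap = ContactMap(cutoff=cutoff, n_compounds=len(poses))
    for key, res_coords in receptor.residues:
        count = 0
        for pose in poses:
            diff = pose.coordinates[:, None, :] - res_coords[None, :, :]
            if (np.einsum("ijk,ijk->ij", diff, diff) <= cutoff**2).any():
                count += 1
        cmap.counts[key] = count
    return cmap


def ligand_rmsd(pose_a: LigandPose, pose_b: LigandPose) -> float:
    """Heavy-atom RMSD with identity atom correspondence, no superposition
    (both poses live in the shared receptor frame)."""
    if pose_a.molecule_key != pose_b.molecule_key:
        raise InputError("RMSD is defined between poses of the same molecule")
    if pose_a.coordinates.shape != pose_b.coordinates.shape:
        raise InputError("atom count mismatch between poses")
    diff = pose_a.coordinates - pose_b.coordinates
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def funnel_table(
    poses: Sequence[LigandPose],
    score_floor: float = -10.0,
) -> pd.DataFrame:
    """Build the RMSD-score table behind pose-convergence (funnel) plots.

    The reference is the pose with the lowest lid_root2.  RMSD to it is
    computed only for poses whose interface score is better than (at or
    below) ``score_floor``; other rows carry NaN.  Rows are sorted by
    lid_root2, best first.
    """
    if not poses:
        raise InputError("no poses given")
    keys = {p.molecule_key for p in poses}
    if len(keys) != 1:
        raise InputError("funnel table is per molecule; got several keys")
    best = min(poses, key=lambda p: p.lid_root2)
    rows = []
    for pose in poses:
        rmsd = (
            ligand_rmsd(pose, best)
            if pose.interface_score <= score_floor
            else float("nan")
        )
        rows.append({
            "pose_id": pose.pose_id,
            "interface_score": pose.interface_score,
            "lid_root2": pose.lid_root2,
            "rmsd_to_best": rmsd,
        })
    return (
        pd.DataFrame(rows)
        .sort_values("lid_root2", ignore_index=True)
    )
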