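"""Physicochemical triage: descriptors, hard filters, traffic lights, PAINS.

Descriptor conventions (fixed so that printed reference compounds
reproduce exactly):

* HBA — Lipinski N+O atom count (sulfur excluded);
* HBD — number of hydrogens on nitrogen or oxygen;
* rotatable bonds — acyclic single bonds between two non-terminal heavy
  atoms, amide C–N excluded (RDKit default definition);
* logP — Crippen atomic-contribution estimate; PSA — topological polar
  surface area; Fsp3 — fraction of sp3-hybridized carbons.

The traffic-light scheme bands logP, MW, PSA, rotatable bonds and Fsp3
each into {0, 1, 2} (lower = more drug-like) and removes compounds whose
total exceeds 2.  Experimental columns of the published scheme (K_D,
solubility) are intentionally absent, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, FilterCatalog, Lipinski, rdMolDescriptors

from evoscreen.errors import InputError


@dataclass(frozen=True)
class PropertyProfile:
    """The eight triage descriptors of one molecule."""

    mw: float  # molecular weight, Da
    logp: float  # Crippen logP, unitless
    hbd: int  # H-bond donors (H on N/O)
    hba: int  # H-bond acceptors (Lipinski N+O count)
    rotb: int  # rotatable bonds
    psa: float  # topological polar surface area, A^2
    fsp3: float  # fraction sp3 carbons, 0..1
    heavy_atoms: int


@dataclass(frozen=True)
class TrafficLight:
    """Per-property 0/1/2 bands and their total."""

    logp_tl: int
    mw_tl: int
    psa_tl: int
    rotb_tl: int
    fsp3_tl: int

    @property
    def total(self) -> int:
        return self.logp_tl + self.mw_tl + self.psa_tl + self.rotb_tl + self.fsp3_tl

    def components(self) -> tuple[int, int, int, int, int]:
        return (self.logp_tl, self.mw_tl, self.psa_tl, self.rotb_tl, self.fsp3_tl)


@dataclass(frozen=True)
class FilterConfig:
    """Hard property bounds; ``round_number`` selects the HBA cap."""

    mw_min: float = 150.0
    mw_max: float = 500.0
    logp_min: float = -1.0
    logp_max: float = 5.0
    rotb_max: int = 10
    hbd_max: int = 5
    hba_max_round1: int = 12
    hba_max_round2: int = 10
    tl_total_max: int = 2
    round_number: int = 1

    def __post_init__(self) -> None:
        if self.round_number not in (1, 2):
            raise InputError("round_number must be 1 or 2")

    @property
    def hba_max(self) -> int:
        return self.hba_max_round1 if self.round_number == 1 else self.hba_max_round2


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    return mol


def compute_properties(smiles: str) -> PropertyProfile:
    """Compute the eight triage descriptors for a SMILES string."""
    mol = _mol(smiles)
    return PropertyProfile(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
        psa=rdMolDescriptors.CalcTPSA(mol),
        fsp3=rdMolDescriptors.CalcFractionCSP3(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
    )


def assign_traffic_lights(profile: PropertyProfile) -> TrafficLight:
    """Band each property into {0, 1, 2}.

    Bands are half-open with the worse band winning at boundaries:
    logP <3 → 0, [3,4) → 1, ≥4 → 2; MW <400 → 0, [400,500) → 1, ≥500 → 2;
    PSA <120 → 0, [120,140) → 1, ≥140 → 2; rotatable bonds 0–7 → 0,
    8–10 → 1, ≥11 → 2; Fsp3 >0.3 → 0, (0.2,0.3] → 1, ≤0.2 → 2.
    """
    if profile.logp < 3:
        logp_tl = 0
    elif profile.logp < 4:
        logp_tl = 1
    else:
        logp_tl = 2
    if profile.mw < 400:
        mw_tl = 0
    elif profile.mw < 500:
        mw_tl = 1
    else:
        mw_tl = 2
    if profile.psa < 120:
        psa_tl = 0
    elif profile.psa < 140:
        psa_tl = 1
    else:
        psa_tl = 2
    if profile.rotb <= 7:
        rotb_tl = 0
    elif profile.rotb <= 10:
        rotb_tl = 1
    else:
        rotb_tl = 2
    if profile.fsp3 > 0.3:
        fsp3_tl = 0
    elif profile.fsp3 > 0.2:
        fsp3_tl = 1
    else:
        fsp3_tl = 2
    return TrafficLight(logp_tl, mw_tl, psa_tl, rotb_tl, fsp3_tl)


def hard_property_filter(
    profile: PropertyProfile, config: FilterConfig | None = None
) -> tuple[bool, list[str]]:
    """Apply the hard bounds; returns (passed, violated-bound reasons).

    PSA and Fsp3 are computed but never hard-filter reasons; they enter
    only through the traffic-light total.
    """
    config = config or FilterConfig()
    reasons: list[str] = []
    if profile.mw < config.mw_min:
        reasons.append(f"mw<{config.mw_min:g}")
    if profile.mw > config.mw_max:
        reasons.append(f"mw>{config.mw_max:g}")
    if profile.logp < config.logp_min:
        reasons.append(f"logp<{config.logp_min:g}")
    if profile.logp > config.logp_max:
        reasons.append(f"logp>{config.logp_max:g}")
    if profile.rotb > config.rotb_max:
        reasons.append(f"rotb>{config.rotb_max}")
    if profile.hbd > config.hbd_max:
        reasons.append(f"hbd>{config.hbd_max}")
    if profile.hba > config.hba_max:
        reasons.append(f"hba>{config.hba_max}")
    return (not reasons, reasons)


_PAINS_CATALOG: FilterCatalog.FilterCatalog | None = None


def _pains_catalog() -> FilterCatalog.FilterCatalog:
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalog.FilterCatalogParams()
        ok = params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        if not ok:
            raise InputError("PAINS filter catalog unavailable")
        _PAINS_CATALOG = FilterCatalog.FilterCatalog(params)
    return _PAINS_CATALOG


def pains_screen(smiles: str) -> tuple[bool, list[str]]:
    """Screen against the published PAINS substructure catalog.

    Returns (passed, matched pattern names); a molecule fails if at least
    one pattern matches.
    """
    mol = _mol(smiles)
    matches = _pains_catalog().GetMatches(mol)
    names = [m.GetDescription() for m in matches]
    return (not names, names)


@dataclass(frozen=True)
class AuditRecord:
    """Per-compound triage outcome: descriptors, bands and rejection stage."""

    smiles: str
    profile: PropertyProfile
    traffic_light: TrafficLight
    passed: bool
    stage: str | None  # 'hard_filter' | 'traffic_light' | 'pains' | None
    reasons: tuple[str, ...] = ()


def first_filter(
    smiles_list: Iterable[str], config: FilterConfig | None = None
) -> tuple[list[str], list[AuditRecord]]:
    """First-stage triage of a compound list.

    A molecule survives iff it passes every hard bound, its traffic-light
    total is at most ``tl_total_max`` (a total of exactly 2 is kept), and
    no PAINS pattern matches.  The audit records name the stage that
    rejected each casualty; stages are checked in the order hard filter →
    traffic light → PAINS.
    """
    config = config or FilterConfig()
    survivors: list[str] = []
    audit: list[AuditRecord] = []
    for smiles in smiles_list:
        profile = compute_properties(smiles)
        tl = assign_traffic_lights(profile)
        hard_ok, hard_reasons = hard_property_filter(profile, config)
        if not hard_ok:
            audit.append(AuditRecord(smiles, profile, tl, False, "hard_filter",
                                     tuple(hard_reasons)))
            continue
        if tl.total > config.tl_total_max:
            audit.append(AuditRecord(
                smiles, profile, tl, False, "traffic_light",
                (f"tl_total={tl.total}>{config.tl_total_max}",),
            ))
            continue
        pains_ok, pains_names = pains_screen(smiles)
        if not pains_ok:
            audit.append(AuditRecord(smiles, profile, tl, False, "pains",
                                     tuple(pains_names)))
            continue
        audit.append(AuditRecord(smiles, profile, tl, True, None))
        survivors.append(smiles)
    return survivors, audit


def audit_table(records: Sequence[AuditRecord]) -> pd.DataFrame:
    """Flatten audit records into a CSV-ready table."""
    rows = []
    for rec in records:
        p, tl = rec.profile, rec.traffic_light
        rows.append({
            "smiles": rec.smiles,
            "mw": p.mw, "logp": p.logp, "hbd": p.hbd, "hba": p.hba,
            "rotb": p.rotb, "psa": p.psa, "fsp3": p.fsp3,
            "heavy_atoms": p.heavy_atoms,
            "tl_logp": tl.logp_tl, "tl_mw": tl.mw_tl, "tl_psa": tl.psa_tl,
            "tl_rotb": tl.rotb_tl, "tl_fsp3": tl.fsp3_tl, "tl_total": tl.total,
            "passed": rec.passed,
            "stage": rec.stage or "",
            "reasons": ";".join(rec.reasons),
        })
    return pd.DataFrame(rows)
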