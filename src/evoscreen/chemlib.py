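"""Combinatorial make-on-demand library handling.

A combinatorial library is defined implicitly by *building rules* (reaction
SMARTS with two or three components) and *building blocks* (substrate
SMILES annotated with the reaction/position slots they may occupy).  The
full chemical space is the union, over reactions, of the Cartesian product
of the per-position substrate lists; real vendor spaces of this shape reach
tens of billions of products, so enumeration always streams.

File dialect (tab-separated, UTF-8, ``#`` comments, no header):

* building rules: ``reaction_id <TAB> smarts <TAB> arity``
* building blocks: ``substrate_id <TAB> smiles <TAB> reaction_id <TAB> position``
  (0-based position; one row per allowed usage)
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from evoscreen.errors import (
    AssemblyError,
    EmptyLibraryError,
    LibraryValidationError,
    UsageError,
)

logger = logging.getLogger(__name__)

# RDKit is chatty about aromaticity in vendor files; warnings are surfaced
# through our own logger instead.
RDLogger.DisableLog("rdApp.warning")


def canonical_smiles(smiles: str) -> str:
    """Return the canonical SMILES used as the molecule key everywhere.

    One canonicalization dialect (RDKit's default writer) is fixed for the
    whole toolkit; every deduplication key, cache key and cross-module
    molecule identifier goes through this function.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LibraryValidationError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms of a molecule given as SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LibraryValidationError(f"unparsable SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


@dataclass(frozen=True)
class Reaction:
    """A building rule: a reaction SMARTS with 2 or 3 components."""

    reaction_id: str
    smarts: str
    arity: int

    def rdkit_reaction(self) -> AllChem.ChemicalReaction:
        try:
            rxn = AllChem.ReactionFromSmarts(self.smarts)
        except ValueError as exc:
            raise LibraryValidationError(
                f"reaction {self.reaction_id}: malformed SMARTS {self.smarts!r}: {exc}"
            ) from exc
        if rxn is None:
            raise LibraryValidationError(
                f"reaction {self.reaction_id}: malformed SMARTS {self.smarts!r}"
            )
        return rxn

    def validate(self) -> None:
        if self.arity not in (2, 3):
            raise LibraryValidationError(
                f"reaction {self.reaction_id}: arity must be 2 or 3, got {self.arity}"
            )
        rxn = self.rdkit_reaction()
        n = rxn.GetNumReactantTemplates()
        if n != self.arity:
            raise LibraryValidationError(
                f"reaction {self.reaction_id}: declared arity {self.arity} but "
                f"SMARTS has {n} reactant templates"
            )


@dataclass(frozen=True)
class Substrate:
    """A building block: a substrate SMILES with its allowed slot usages."""

    substrate_id: str
    smiles: str
    usages: frozenset[tuple[str, int]]


@dataclass(frozen=True)
class LibraryMolecule:
    """A library member: an address (reaction, substrate tuple) plus product.

    ``product_smiles`` is the canonical SMILES of the assembled product and
    doubles as the molecule key throughout the pipeline.
    """

    reaction_id: str
    substrate_ids: tuple[str, ...]
    product_smiles: str

    @property
    def key(self) -> str:
        return self.product_smiles

    @property
    def address(self) -> tuple[str, tuple[str, ...]]:
        return (self.reaction_id, self.substrate_ids)


@dataclass
class CombinatorialLibrary:
    """Reactions plus per-slot substrate lists: the searchable space."""

    reactions: dict[str, Reaction]
    substrates: dict[str, Substrate]
    # (reaction_id, position) -> ordered substrate_id list
    slots: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rxn_cache: dict[str, AllChem.ChemicalReaction] = {}
        self._mol_cache: dict[str, Chem.Mol] = {}

    # -- basic queries ---------------------------------------------------

    def usable_reactions(self) -> list[Reaction]:
        """Reactions for which every slot is present and non-empty."""
        usable = []
        for rxn in self.reactions.values():
            if all(self.slots.get((rxn.reaction_id, p)) for p in range(rxn.arity)):
                usable.append(rxn)
        return usable

    def slot_substrates(self, reaction_id: str, position: int) -> list[str]:
        if reaction_id not in self.reactions:
            raise LibraryValidationError(f"unknown reaction {reaction_id!r}")
        return list(self.slots.get((reaction_id, position), []))

    def product_count(self) -> int:
        """Closed-form size of the space: sum over reactions of the slot-size product."""
        total = 0
        for rxn in self.usable_reactions():
            sizes = [len(self.slots[(rxn.reaction_id, p)]) for p in range(rxn.arity)]
            total += int(np.prod(sizes))
        return total

    def _reaction_obj(self, reaction_id: str) -> AllChem.ChemicalReaction:
        if reaction_id not in self._rxn_cache:
            self._rxn_cache[reaction_id] = self.reactions[reaction_id].rdkit_reaction()
        return self._rxn_cache[reaction_id]

    def _substrate_mol(self, substrate_id: str) -> Chem.Mol:
        if substrate_id not in self._mol_cache:
            self._mol_cache[substrate_id] = Chem.MolFromSmiles(
                self.substrates[substrate_id].smiles
            )
        return self._mol_cache[substrate_id]


# -- loading -------------------------------------------------------------


def _read_tsv_rows(path: str | Path, n_cols: int) -> list[list[str]]:
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise LibraryValidationError(
                    f"{path.name}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(parts)}"
                )
            rows.append(parts)
    return rows


def load_library(rules_path: str | Path, substrates_path: str | Path) -> CombinatorialLibrary:
    """Load and validate a combinatorial library from two TSV files.

    Substrates whose SMILES do not sanitize are dropped with a logged
    warning (vendor files contain dirty rows); a malformed reaction SMARTS
    is a hard validation error naming the reaction.  Reactions left with an
    empty slot remain in the library but are excluded from
    :meth:`CombinatorialLibrary.usable_reactions`.
    """
    reactions: dict[str, Reaction] = {}
    for rid, smarts, arity_s in _read_tsv_rows(rules_path, 3):
        try:
            arity = int(arity_s)
        except ValueError as exc:
            raise LibraryValidationError(
                f"reaction {rid}: arity {arity_s!r} is not an integer"
            ) from exc
        rxn = Reaction(reaction_id=rid, smarts=smarts, arity=arity)
        rxn.validate()
        if rid in reactions:
            raise LibraryValidationError(f"duplicate reaction_id {rid!r}")
        reactions[rid] = rxn

    usages: dict[str, set[tuple[str, int]]] = {}
    smiles_by_id: dict[str, str] = {}
    slots: dict[tuple[str, int], list[str]] = {}
    dropped: set[str] = set()
    for sid, smiles, rid, pos_s in _read_tsv_rows(substrates_path, 4):
        if sid in dropped:
            continue
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise LibraryValidationError(
                f"substrate {sid}: position {pos_s!r} is not an integer"
            ) from exc
        if rid not in reactions:
            raise LibraryValidationError(
                f"substrate {sid}: unknown reaction {rid!r}"
            )
        if not 0 <= pos < reactions[rid].arity:
            raise LibraryValidationError(
                f"substrate {sid}: position {pos} out of range for reaction "
                f"{rid} (arity {reactions[rid].arity})"
            )
        if sid in smiles_by_id and smiles_by_id[sid] != smiles:
            raise LibraryValidationError(
                f"substrate {sid}: conflicting SMILES across rows"
            )
        if sid not in smiles_by_id:
            if Chem.MolFromSmiles(smiles) is None:
                logger.warning(
                    "dropping substrate %s: unparsable SMILES %r", sid, smiles
                )
                dropped.add(sid)
                continue
            smiles_by_id[sid] = smiles
        usages.setdefault(sid, set()).add((rid, pos))
        slot = slots.setdefault((rid, pos), [])
        if sid not in slot:
            slot.append(sid)

    substrates = {
        sid: Substrate(substrate_id=sid, smiles=smiles_by_id[sid], usages=frozenset(u))
        for sid, u in usages.items()
    }
    lib = CombinatorialLibrary(reactions=reactions, substrates=substrates, slots=slots)
    for rxn in reactions.values():
        if rxn not in lib.usable_reactions():
            logger.warning(
                "reaction %s has an empty slot and is unusable", rxn.reaction_id
            )
    return lib


# -- assembly ------------------------------------------------------------


def assemble_product(
    library: CombinatorialLibrary,
    reaction_id: str,
    substrate_ids: Sequence[str],
) -> LibraryMolecule:
    """Apply a building rule to an ordered substrate tuple.

    Deterministic: when the template yields several products, the
    lexicographically smallest canonical SMILES is kept, so repeated calls
    always return an identical ``product_smiles``.
    """
    if reaction_id not in library.reactions:
        raise LibraryValidationError(f"unknown reaction {reaction_id!r}")
    rxn_def = library.reactions[reaction_id]
    substrate_ids = tuple(substrate_ids)
    if len(substrate_ids) != rxn_def.arity:
        raise AssemblyError(
            f"reaction {reaction_id} has arity {rxn_def.arity}, got "
            f"{len(substrate_ids)} substrates"
        )
    for pos, sid in enumerate(substrate_ids):
        if sid not in library.substrates:
            raise UsageError(f"unknown substrate {sid!r}")
        if sid not in library.slots.get((reaction_id, pos), []):
            raise UsageError(
                f"substrate {sid} is not allowed in slot {pos} of reaction {reaction_id}"
            )

    rxn = library._reaction_obj(reaction_id)
    mols = tuple(library._substrate_mol(sid) for sid in substrate_ids)
    product_sets = rxn.RunReactants(mols)
    candidates: set[str] = set()
    for prods in product_sets:
        for prod in prods:
            try:
                Chem.SanitizeMol(prod)
            except Exception:  # unsanitizable outcome of a promiscuous template
                continue
            candidates.add(Chem.MolToSmiles(prod))
    if not candidates:
        # diagnose which position failed to match its template
        failing = [
            pos
            for pos in range(rxn_def.arity)
            if not mols[pos].HasSubstructMatch(rxn.GetReactantTemplate(pos))
        ]
        if failing:
            raise AssemblyError(
                f"reaction {reaction_id}: substrate(s) at position(s) {failing} "
                "do not match the reactant template"
            )
        raise AssemblyError(
            f"reaction {reaction_id}: no sanitizable product for {substrate_ids}"
        )
    return LibraryMolecule(
        reaction_id=reaction_id,
        substrate_ids=substrate_ids,
        product_smiles=min(candidates),
    )


def enumerate_products(library: CombinatorialLibrary) -> Iterator[LibraryMolecule]:
    """Stream every (reaction, substrate tuple) combination exactly once.

    The yielded count equals the closed form
    :meth:`CombinatorialLibrary.product_count`; nothing is materialized.
    """
    for rxn in library.usable_reactions():
        slot_lists = [
            library.slots[(rxn.reaction_id, p)] for p in range(rxn.arity)
        ]
        for combo in itertools.product(*slot_lists):
            yield assemble_product(library, rxn.reaction_id, combo)


def sample_random_molecule(
    library: CombinatorialLibrary, rng: np.random.Generator
) -> LibraryMolecule:
    """Draw a random library member: uniform over usable reactions, then
    uniform per slot (not uniform over products — O(1) and matching the
    substrates-and-reactions sampling unit of the search engine)."""
    usable = library.usable_reactions()
    if not usable:
        raise EmptyLibraryError("library has no usable reaction")
    rxn = usable[int(rng.integers(len(usable)))]
    sids = tuple(
        library.slots[(rxn.reaction_id, p)][
            int(rng.integers(len(library.slots[(rxn.reaction_id, p)])))
        ]
        for p in range(rxn.arity)
    )
    return assemble_product(library, rxn.reaction_id, sids)


def expand_partners(
    library: CombinatorialLibrary, molecule: LibraryMolecule
) -> list[LibraryMolecule]:
    """Hit expansion: substitute each position with every allowed substrate
    while keeping the others fixed; deduplicated by address, with the
    original combination appearing exactly once.  For slot sizes
    ``m, n, ...`` the result has ``m + n + ... − (arity − 1)`` entries.
    """
    if molecule.reaction_id not in library.reactions:
        raise LibraryValidationError(f"unknown reaction {molecule.reaction_id!r}")
    arity = library.reactions[molecule.reaction_id].arity
    seen: set[tuple[str, ...]] = set()
    out: list[LibraryMolecule] = []
    for pos in range(arity):
        for sid in library.slots[(molecule.reaction_id, pos)]:
            combo = tuple(
                sid if p == pos else molecule.substrate_ids[p] for p in range(arity)
            )
            if combo in seen:
                continue
            seen.add(combo)
            out.append(assemble_product(library, molecule.reaction_id, combo))
    return out


def write_molecules(path: str | Path, molecules: Sequence[LibraryMolecule]) -> None:
    """Write molecules as ``product_smiles <TAB> reaction_id <TAB> sid1+sid2``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for mol in molecules:
            fh.write(
                f"{mol.product_smiles}\t{mol.reaction_id}\t"
                f"{'+'.join(mol.substrate_ids)}\n"
            )
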