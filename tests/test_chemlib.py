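"""Library parsing, product assembly, enumeration, sampling and expansion."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy import stats

from evoscreen import chemlib
from evoscreen.errors import (
    AssemblyError,
    EmptyLibraryError,
    LibraryValidationError,
    UsageError,
)


def _write_library(tmp_path, rules_rows, block_rows):
    rules = tmp_path / "rules.tsv"
    blocks = tmp_path / "blocks.tsv"
    rules.write_text("\n".join("\t".join(r) for r in rules_rows) + "\n")
    blocks.write_text("\n".join("\t".join(r) for r in block_rows) + "\n")
    return rules, blocks


AMIDE = "[C:1](=O)[OH].[N;H2:2]>>[C:1](=O)[N:2]"


class TestLoadLibrary:
    def test_product_counts_match_slot_products(self, tiny_library, mixed_library):
        assert tiny_library.product_count() == 3 * 4
        assert mixed_library.product_count() == 3 * 4 + 2 * 2 * 2

    def test_invalid_smiles_row_dropped_with_warning(self, tmp_path, caplog):
        rules, blocks = _write_library(
            tmp_path,
            [("r1", AMIDE, "2")],
            [
                ("a1", "CC(=O)O", "r1", "0"),
                ("bad", "not_a_smiles((", "r1", "0"),
                ("b1", "CN", "r1", "1"),
            ],
        )
        with caplog.at_level("WARNING"):
            lib = chemlib.load_library(rules, blocks)
        assert "bad" not in lib.substrates
        assert any("bad" in rec.message for rec in caplog.records)
        assert lib.product_count() == 1

    def test_malformed_smarts_is_per_record_error_naming_reaction(self, tmp_path):
        rules, blocks = _write_library(
            tmp_path, [("rX", "not>>a>>smarts>>", "2")], [("a1", "CC(=O)O", "rX", "0")]
        )
        with pytest.raises(LibraryValidationError, match="rX"):
            chemlib.load_library(rules, blocks)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            chemlib.load_library(tmp_path / "nope.tsv", tmp_path / "nope2.tsv")

    def test_reaction_with_empty_slot_is_unusable(self, tmp_path):
        rules, blocks = _write_library(
            tmp_path,
            [("r1", AMIDE, "2"), ("r2", AMIDE, "2")],
            [
                ("a1", "CC(=O)O", "r1", "0"),
                ("b1", "CN", "r1", "1"),
                ("a2", "CCC(=O)O", "r2", "0"),  # r2 slot 1 left empty
            ],
        )
        lib = chemlib.load_library(rules, blocks)
        assert [r.reaction_id for r in lib.usable_reactions()] == ["r1"]
        assert lib.product_count() == 1

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        rules = tmp_path / "rules.tsv"
        rules.write_text(f"# comment\n\nr1\t{AMIDE}\t2\n")
        blocks = tmp_path / "blocks.tsv"
        blocks.write_text("# c\na1\tCC(=O)O\tr1\t0\nb1\tCN\tr1\t1\n")
        lib = chemlib.load_library(rules, blocks)
        assert lib.product_count() == 1

    def test_arity_must_match_smarts_templates(self, tmp_path):
        rules, blocks = _write_library(
            tmp_path, [("r1", AMIDE, "3")], [("a1", "CC(=O)O", "r1", "0")]
        )
        with pytest.raises(LibraryValidationError, match="arity"):
            chemlib.load_library(rules, blocks)


class TestAssembleProduct:
    @pytest.fixture()
    def amide_library(self, tmp_path):
        rules, blocks = _write_library(
            tmp_path,
            [("r1", "[C:1](=O)O.[N;H2:2]>>[C:1](=O)[N:2]", "2")],
            [("acid", "CC(=O)O", "r1", "0"), ("amine", "CN", "r1", "1")],
        )
        return chemlib.load_library(rules, blocks)

    def test_amide_coupling_gives_n_methylacetamide(self, amide_library):
        mol = chemlib.assemble_product(amide_library, "r1", ("acid", "amine"))
        expected = Chem.MolToSmiles(Chem.MolFromSmiles("CC(=O)NC"))
        assert mol.product_smiles == expected

    def test_assembly_is_deterministic_over_repeats(self, amide_library):
        results = {
            chemlib.assemble_product(amide_library, "r1", ("acid", "amine")).product_smiles
            for _ in range(100)
        }
        assert len(results) == 1

    def test_wrong_substrate_count_is_arity_error(self, mixed_library):
        three_comp = next(r for r in mixed_library.reactions.values() if r.arity == 3)
        sids = mixed_library.slots[(three_comp.reaction_id, 0)][:1] * 2
        with pytest.raises(AssemblyError, match="arity"):
            chemlib.assemble_product(mixed_library, three_comp.reaction_id, sids)

    def test_disallowed_substrate_is_usage_error(self, tiny_library):
        rid = next(iter(tiny_library.reactions))
        wrong = tiny_library.slots[(rid, 1)][0]  # an amine in the acid slot
        other = tiny_library.slots[(rid, 1)][0]
        with pytest.raises(UsageError):
            chemlib.assemble_product(tiny_library, rid, (wrong, other))

    def test_template_mismatch_names_failing_position(self, tmp_path):
        rules, blocks = _write_library(
            tmp_path,
            [("r1", "[C:1](=O)[OH].[N;H2:2]>>[C:1](=O)[N:2]", "2")],
            [("notacid", "CCO", "r1", "0"), ("amine", "CN", "r1", "1")],
        )
        lib = chemlib.load_library(rules, blocks)
        with pytest.raises(AssemblyError, match=r"position\(s\) \[0\]"):
            chemlib.assemble_product(lib, "r1", ("notacid", "amine"))


class TestEnumerateProducts:
    def test_tiny_library_yields_12_distinct_addresses(self, tiny_library):
        mols = list(chemlib.enumerate_products(tiny_library))
        assert len(mols) == 12
        assert len({m.address for m in mols}) == 12

    def test_matches_brute_force_nested_loop_oracle(self, mixed_library):
        """The enumeration stream equals an independent nested-loop product walk."""
        expected = []
        for rxn in mixed_library.usable_reactions():
            rdkit_rxn = AllChem.ReactionFromSmarts(rxn.smarts)
            slots = [
                mixed_library.slots[(rxn.reaction_id, p)] for p in range(rxn.arity)
            ]
            for combo in itertools.product(*slots):
                mols = tuple(
                    Chem.MolFromSmiles(mixed_library.substrates[s].smiles)
                    for s in combo
                )
                outcomes = set()
                for prods in rdkit_rxn.RunReactants(mols):
                    m = prods[0]
                    Chem.SanitizeMol(m)
                    outcomes.add(Chem.MolToSmiles(m))
                expected.append(min(outcomes))
        actual = [m.product_smiles for m in chemlib.enumerate_products(mixed_library)]
        assert sorted(actual) == sorted(expected)

    def test_round_trip_reassembly_reproduces_product_smiles(self, mixed_library):
        for mol in chemlib.enumerate_products(mixed_library):
            again = chemlib.assemble_product(
                mixed_library, mol.reaction_id, mol.substrate_ids
            )
            assert again.product_smiles == mol.product_smiles


class TestSampleRandomMolecule:
    def test_same_seed_gives_identical_sequences(self, mixed_library):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            seqs.append(
                [chemlib.sample_random_molecule(mixed_library, rng).address
                 for _ in range(20)]
            )
        assert seqs[0] == seqs[1]

    def test_uniform_over_products_of_single_reaction(self, tiny_library):
        """10 000 draws from the 3×4 space pass a chi-square uniformity test."""
        rng = np.random.default_rng(99)
        counts: dict = {}
        for _ in range(10_000):
            mol = chemlib.sample_random_molecule(tiny_library, rng)
            counts[mol.address] = counts.get(mol.address, 0) + 1
        assert len(counts) == 12
        _, p = stats.chisquare(list(counts.values()))
        assert p > 0.01

    def test_singleton_library_always_returns_same_molecule(self, tmp_path):
        rules, blocks = _write_library(
            tmp_path,
            [("r1", AMIDE, "2")],
            [("a1", "CC(=O)O", "r1", "0"), ("b1", "CN", "r1", "1")],
        )
        lib = chemlib.load_library(rules, blocks)
        rng = np.random.default_rng(0)
        keys = {chemlib.sample_random_molecule(lib, rng).key for _ in range(10)}
        assert len(keys) == 1

    def test_empty_library_raises(self, tmp_path):
        rules, blocks = _write_library(
            tmp_path, [("r1", AMIDE, "2")], [("a1", "CC(=O)O", "r1", "0")]
        )
        lib = chemlib.load_library(rules, blocks)
        with pytest.raises(EmptyLibraryError):
            chemlib.sample_random_molecule(lib, np.random.default_rng(0))


class TestExpandPartners:
    def test_two_component_expansion_size_is_m_plus_n_minus_1(self, tiny_library):
        hit = next(chemlib.enumerate_products(tiny_library))
        expansion = chemlib.expand_partners(tiny_library, hit)
        assert len(expansion) == 3 + 4 - 1
        assert sum(1 for m in expansion if m.address == hit.address) == 1

    def test_three_component_expansion_size(self, mixed_library):
        three = next(r for r in mixed_library.usable_reactions() if r.arity == 3)
        hit = chemlib.assemble_product(
            mixed_library,
            three.reaction_id,
            tuple(mixed_library.slots[(three.reaction_id, p)][0] for p in range(3)),
        )
        expansion = chemlib.expand_partners(mixed_library, hit)
        assert len(expansion) == 2 + 2 + 2 - 2

    def test_matches_brute_force_per_position_substitution(self, tiny_library):
        hit = list(chemlib.enumerate_products(tiny_library))[5]
        expected = set()
        for pos in range(2):
            for sid in tiny_library.slots[(hit.reaction_id, pos)]:
                combo = list(hit.substrate_ids)
                combo[pos] = sid
                expected.add(tuple(combo))
        actual = {m.substrate_ids for m in chemlib.expand_partners(tiny_library, hit)}
        assert actual == expected

    def test_expansion_is_subset_of_full_enumeration(self, mixed_library):
        hit = next(chemlib.enumerate_products(mixed_library))
        all_addresses = {m.address for m in chemlib.enumerate_products(mixed_library)}
        for mol in chemlib.expand_partners(mixed_library, hit):
            assert mol.address in all_addresses

    def test_unknown_reaction_is_lookup_error(self, tiny_library):
        bogus = chemlib.LibraryMolecule("no-such", ("a", "b"), "CC")
        with pytest.raises(LibraryValidationError):
            chemlib.expand_partners(tiny_library, bogus)
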