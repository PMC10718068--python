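"""Reaction-text parsing, name resolution, and candidate assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocatmap.ingest import (
    DictResolver,
    ParseError,
    assemble_reactions,
    parse_reaction_text,
    render_reaction_text,
    resolve_name,
    standardize_smiles,
)
from biocatmap.chem import ChemError
from biocatmap.records import ParsedReaction


class TestParseReactionText:
    @pytest.mark.parametrize(
        "text,tag,substrates,products,rev",
        [
            (
                "acetylene + H2O = acetaldehyde",
                "r",
                (("acetylene", 1), ("H2O", 1)),
                (("acetaldehyde", 1),),
                "reversible",
            ),
            (
                "2 H2O2 = 2 H2O + O2",
                "?",
                (("H2O2", 2),),
                (("H2O", 2), ("O2", 1)),
                "unknown",
            ),
            (
                "D-glucose + ATP = D-glucose 6-phosphate + ADP",
                "ir",
                (("D-glucose", 1), ("ATP", 1)),
                (("D-glucose 6-phosphate", 1), ("ADP", 1)),
                "irreversible",
            ),
        ],
    )
    def test_examples(self, text, tag, substrates, products, rev):
        parsed = parse_reaction_text(text, tag)
        assert parsed.substrates == substrates
        assert parsed.products == products
        assert parsed.reversibility == rev

    @pytest.mark.parametrize(
        "bad",
        ["A + = B", "A + B", "= B", "A =", "A = B = C", "0 A = B"],
    )
    def test_malformed_text_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_reaction_text(bad)

    name = st.text(
        alphabet="abcdefgXYZ-,'()", min_size=1, max_size=12
    ).filter(lambda s: s.strip() == s and s and not s[0].isdigit() and "+" not in s)
    side = st.lists(
        st.tuples(name, st.integers(min_value=1, max_value=9)),
        min_size=1,
        max_size=4,
    )

    @given(substrates=side, products=side)
    @settings(max_examples=60, deadline=None)
    def test_render_parse_round_trip(self, substrates, products):
        original = ParsedReaction(
            substrates=tuple(substrates),
            products=tuple(products),
            reversibility="reversible",
        )
        again = parse_reaction_text(render_reaction_text(original), "reversible")
        assert again == original


class TestStandardizeSmiles:
    def test_spellings_of_one_molecule_collapse(self):
        # brute-force graph-isomorphism oracle on small molecules: spellings
        # that describe the same graph must standardize to one string
        spellings = ["OCC", "C(O)C", "CCO", "C(C)O"]
        assert len({standardize_smiles(s) for s in spellings}) == 1
        for s in spellings:
            assert _isomorphic(s, spellings[0])

    def test_idempotent(self):
        for s in ["CCO", "c1ccccc1O", "C[C@H](N)C(=O)O", "[H+]", "O=C=O"]:
            once = standardize_smiles(s)
            assert standardize_smiles(once) == once

    def test_distinct_molecules_stay_distinct(self):
        assert standardize_smiles("CCO") != standardize_smiles("COC")
        assert not _isomorphic("CCO", "COC")

    def test_tautomers_not_collapsed(self):
        # vinyl alcohol and acetaldehyde are tautomers, not the same entry
        assert standardize_smiles("C=CO") != standardize_smiles("CC=O")

    def test_invalid_smiles_raises(self):
        with pytest.raises(ChemError):
            standardize_smiles("not_a_molecule(((")


def _isomorphic(smiles_a: str, smiles_b: str) -> bool:
    """Brute-force heavy-atom graph isomorphism for <=8-atom molecules."""
    from itertools import permutations

    from rdkit import Chem

    def graph(s):
        mol = Chem.MolFromSmiles(s)
        atoms = [(a.GetSymbol(), a.GetTotalNumHs(), a.GetFormalCharge()) for a in mol.GetAtoms()]
        bonds = {
            frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())): b.GetBondTypeAsDouble()
            for b in mol.GetBonds()
        }
        return atoms, bonds

    atoms_a, bonds_a = graph(smiles_a)
    atoms_b, bonds_b = graph(smiles_b)
    if len(atoms_a) != len(atoms_b) or len(atoms_a) > 8:
        return False
    for perm in permutations(range(len(atoms_b))):
        if any(atoms_a[i] != atoms_b[perm[i]] for i in range(len(atoms_a))):
            continue
        mapped = {
            frozenset((perm[i], perm[j])): order
            for pair, order in bonds_a.items()
            for i, j in [tuple(pair)]
        }
        if mapped == bonds_b:
            return True
    return False


class TestResolveName:
    def test_single_dictionary_hit(self):
        chain = [DictResolver({"H2O": ["O"]})]
        assert resolve_name("H2O", chain) == {"O"}

    def test_conflicting_resolvers_keep_both(self):
        chain = [
            DictResolver({"toyose": ["OC1CCCO1"]}),
            DictResolver({"toyose": ["O=CCCCO"]}),
        ]
        assert len(resolve_name("toyose", chain)) == 2

    def test_unknown_name_empty(self):
        assert resolve_name("unobtainium", [DictResolver({})]) == set()

    def test_duplicate_spellings_collapse(self):
        chain = [DictResolver({"ethanol": ["CCO", "OCC", "C(C)O"]})]
        assert len(resolve_name("ethanol", chain)) == 1

    def test_failing_resolver_is_not_fatal(self):
        def broken(name):
            raise IOError("connection refused")

        chain = [broken, DictResolver({"H2O": ["O"]})]
        assert resolve_name("H2O", chain) == {"O"}

    def test_case_sensitive_matching(self):
        chain = [DictResolver({"D-alanine": ["C[C@@H](N)C(=O)O"]})]
        assert resolve_name("d-alanine", chain) == set()


class TestAssembleReactions:
    def test_single_resolution_yields_one_candidate(self):
        parsed = parse_reaction_text("acetylene + H2O = acetaldehyde", "r")
        cands = assemble_reactions(
            "e", parsed, {"acetylene": {"C#C"}, "H2O": {"O"}, "acetaldehyde": {"CC=O"}}
        )
        assert len(cands) == 1
        assert cands[0].reactant_smiles == ("C#C", "O")

    def test_output_size_is_product_of_cardinalities(self):
        parsed = parse_reaction_text("a + b = c", "r")
        table = {"a": {"CC", "CCC"}, "b": {"O"}, "c": {"CO", "CCO", "OCCO"}}
        cands = assemble_reactions("e", parsed, table)
        assert len(cands) == 2 * 1 * 3
        assert len({c.resolution_path for c in cands}) == 6

    def test_coefficients_expand_to_repeats(self):
        parsed = parse_reaction_text("2 H2O2 = 2 H2O + O2", "r")
        table = {"H2O2": {"OO"}, "H2O": {"O"}, "O2": {"O=O"}}
        (cand,) = assemble_reactions("e", parsed, table)
        assert cand.reactant_smiles == ("OO", "OO")
        assert cand.product_smiles == ("O", "O", "O=O")

    def test_cap_truncates_deterministically(self):
        parsed = parse_reaction_text("a = b", "r")
        table = {"a": {f"{'C' * n}O" for n in range(1, 7)}, "b": {"CC=O"}}
        capped = assemble_reactions("e", parsed, table, cap=4)
        assert len(capped) == 4
        again = assemble_reactions("e", parsed, table, cap=4)
        assert capped == again

    def test_unresolved_name_raises(self):
        parsed = parse_reaction_text("a = b", "r")
        with pytest.raises(KeyError):
            assemble_reactions("e", parsed, {"a": {"CC"}, "b": set()})
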