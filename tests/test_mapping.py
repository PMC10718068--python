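"""Rule application with atom tracking, rule selection, rule ordering."""

import pytest
from rdkit import Chem

from biocatmap.chem import stripped_canonical
from biocatmap.mapcanon import check_atom_conservation, standardize_maps
from biocatmap.mapping import apply_rule, map_single, map_stereo_only, order_rules
from biocatmap.records import CandidateReaction

from conftest import OXIDATION_SMARTS, make_rule


class TestApplyRule:
    def test_hydration_single_outcome(self, hydration_rule):
        outcomes = apply_rule(hydration_rule, ["C#C", "O"])
        assert len(outcomes) == 1
        products = {stripped_canonical(p) for p in outcomes[0].product_mols}
        assert products == {"CC=O"}

    def test_two_site_diol_two_outcomes(self, oxidation_rule):
        outcomes = apply_rule(oxidation_rule, ["CCC(O)CO", "O=O"])
        product_sets = {
            tuple(sorted(stripped_canonical(p) for p in o.product_mols))
            for o in outcomes
        }
        assert product_sets == {
            ("CCC(=O)CO", "OO"),
            ("CCC(O)C=O", "OO"),
        }

    def test_no_match_empty(self, hydration_rule):
        assert apply_rule(hydration_rule, ["CCO"]) == []

    def test_spectators_pass_through_mapped(self, oxidation_rule):
        outcomes = apply_rule(oxidation_rule, ["CCO", "O=O", "O=O"])
        for o in outcomes:
            assert check_atom_conservation(o.mapped_rxn)
            # the unreacted O2 appears on both sides with identical maps
            lhs, rhs = o.mapped_rxn.split(">>")
            assert sum("=" in s and "O" in s for s in rhs.split(".")) >= 1

    def test_symmetric_outcomes_collapse(self, oxidation_rule):
        # 1,3-propanediol: both sites give the same product and an
        # equivalent mapping; only one outcome must remain per product
        outcomes = apply_rule(oxidation_rule, ["OCCCO", "O=O"])
        keys = [standardize_maps(o.mapped_rxn) for o in outcomes]
        assert len(keys) == len(set(keys)) == 1

    def test_matches_brute_force_embedding_oracle(self, oxidation_rule):
        # oracle: enumerate embeddings of the alcohol pattern and rewrite the
        # graph by hand; outcome product sets must agree exactly
        for substrate in ["CCO", "CC(O)C", "CCC(O)CO", "OCC(O)CC", "CC(C)(O)CO"]:
            expected = _oracle_oxidation_products(substrate)
            got = {
                tuple(sorted(stripped_canonical(p) for p in o.product_mols))
                for o in apply_rule(oxidation_rule, [substrate, "O=O"])
            }
            assert got == expected, substrate


def _oracle_oxidation_products(substrate: str) -> set[tuple[str, ...]]:
    """Brute-force rewrite: every C(-OH) with an H becomes C=O, O2 -> H2O2."""
    mol = Chem.MolFromSmiles(substrate)
    pattern = Chem.MolFromSmarts("[C;!$(C=O);!H0][OX2H1]")
    results = set()
    for c_idx, o_idx in mol.GetSubstructMatches(pattern):
        rw = Chem.RWMol(mol)
        rw.GetBondBetweenAtoms(c_idx, o_idx).SetBondType(Chem.BondType.DOUBLE)
        rw.GetAtomWithIdx(c_idx).SetNumExplicitHs(
            max(0, mol.GetAtomWithIdx(c_idx).GetTotalNumHs() - 1)
        )
        rw.GetAtomWithIdx(o_idx).SetNumExplicitHs(0)
        product = rw.GetMol()
        Chem.SanitizeMol(product)
        results.add(tuple(sorted([Chem.MolToSmiles(product), "OO"])))
    return results


class TestMapSingle:
    def test_hydration_entry_maps(self, hydration_rule):
        rec = map_single(
            CandidateReaction("e1", ("C#C", "O"), ("CC=O",)), [hydration_rule]
        )
        assert rec is not None
        assert rec.rule_id == "R01_alkyne_hydration"
        assert rec.steps == "single" and rec.source == "direct"
        assert check_atom_conservation(rec.mapped_rxn)

    def test_smaller_edit_rule_wins(self):
        # both rules give the identical product multiset; the wasteful one
        # additionally exchanges the carbonyl oxygen with an O2 oxygen and
        # so changes more bonds.  Its id sorts first, proving selection is
        # by edit count, not by id.
        direct = make_rule(
            "Rb_direct",
            "[C:1][OX2H1:2].[O:3]=[O:4]>>[C:1]=[O:2].[OH:3][OH:4]",
        )
        wasteful = make_rule(
            "Ra_wasteful",
            "[C:1][OX2H1:2].[O:3]=[O:4]>>[C:1]=[O:3].[OH:2][OH:4]",
        )
        assert (
            wasteful.n_atoms_changed + wasteful.n_bonds_changed
            > direct.n_atoms_changed + direct.n_bonds_changed
        )
        rec = map_single(
            CandidateReaction("e", ("CC(C)O", "O=O"), ("CC(C)=O", "OO")),
            [wasteful, direct],
        )
        assert rec.rule_id == "Rb_direct"

    def test_frequency_breaks_edit_ties(self):
        rare = make_rule("Ra_rare", OXIDATION_SMARTS, applicability=1)
        common = make_rule("Rb_common", OXIDATION_SMARTS, applicability=9)
        rec = map_single(
            CandidateReaction("e", ("CC(C)O", "O=O"), ("CC(C)=O", "OO")),
            [rare, common],
        )
        assert rec.rule_id == "Rb_common"

    def test_unreproducible_product_returns_none(self, hydration_rule):
        assert (
            map_single(
                CandidateReaction("e", ("C#C", "O"), ("CCO",)), [hydration_rule]
            )
            is None
        )

    def test_deterministic(self, oxidation_rule, hydration_rule):
        cand = CandidateReaction("e", ("CC(C)O", "O=O"), ("CC(C)=O", "OO"))
        first = map_single(cand, [oxidation_rule, hydration_rule])
        second = map_single(cand, [oxidation_rule, hydration_rule])
        assert first.mapped_rxn == second.mapped_rxn


class TestMapStereoOnly:
    def test_racemization_maps_identity_skeleton(self):
        rec = map_stereo_only(
            CandidateReaction("e", ("CC[C@@H](C)O",), ("CC[C@H](C)O",))
        )
        assert rec is not None
        assert rec.rule_id == "stereo_only"
        assert check_atom_conservation(rec.mapped_rxn)

    def test_exact_identity_reaction(self):
        rec = map_stereo_only(CandidateReaction("e", ("CCO",), ("CCO",)))
        assert rec is not None

    def test_skeleton_change_returns_none(self):
        assert (
            map_stereo_only(CandidateReaction("e", ("C#C", "O"), ("CC=O",))) is None
        )


class TestOrderRules:
    def corpus(self, *reactant_lists):
        return [
            CandidateReaction(f"c{i}", tuple(r), ("C",))
            for i, r in enumerate(reactant_lists)
        ]

    def test_frequency_ordering(self, oxidation_rule, hydration_rule):
        corpus = self.corpus(
            ["CCO", "O=O"], ["CC(C)O", "O=O"], ["OCCO", "O=O"], ["C#C", "O"]
        )
        ordered = order_rules([hydration_rule, oxidation_rule], corpus)
        assert [r.rule_id for r in ordered] == [
            "R02_alcohol_oxidase",
            "R01_alkyne_hydration",
        ]
        assert ordered[0].applicability_count == 3

    def test_empty_corpus_keeps_file_order(self, oxidation_rule, hydration_rule):
        ordered = order_rules([hydration_rule, oxidation_rule], [])
        assert [r.rule_id for r in ordered] == [
            "R01_alkyne_hydration",
            "R02_alcohol_oxidase",
        ]

    def test_equal_counts_fall_back_to_rule_id(self):
        a = make_rule("Rb", OXIDATION_SMARTS)
        b = make_rule("Ra", OXIDATION_SMARTS)
        ordered = order_rules([a, b], self.corpus(["CCO", "O=O"]))
        assert [r.rule_id for r in ordered] == ["Ra", "Rb"]
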