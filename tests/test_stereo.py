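"""Reaction centers, bond-edit counting, minimal-edit selection, stereo fixes."""

import pytest
from rdkit import Chem

from biocatmap.records import CandidateReaction, MappedRecord
from biocatmap.mapping import map_single
from biocatmap.stereo import (
    correct_stereo,
    count_bond_edits,
    reaction_center,
    select_minimal_edit,
)

from conftest import make_rule

IDENTITY = "[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][OH:3]"
HYDRATION = "[CH:1]#[CH:2].[OH2:3]>>[CH3:1][CH:2]=[O:3]"
# consistent-form glycoside hydrolysis vs the ring-opening variant of the
# same entry (open-form product from an ambiguous name resolution)
GLYC_CLOSED = (
    "[CH3:1][O:2][CH:3]1[CH2:4][CH2:5][CH2:6][O:7]1.[OH2:8]"
    ">>[CH3:1][OH:2].[OH:8][CH:3]1[CH2:4][CH2:5][CH2:6][O:7]1"
)
GLYC_OPEN = (
    "[CH3:1][O:2][CH:3]1[CH2:4][CH2:5][CH2:6][O:7]1.[OH2:8]"
    ">>[CH3:1][OH:2].[O:8]=[CH:3][CH2:4][CH2:5][CH2:6][OH:7]"
)


def record(mapped_rxn, rule_id="R", entry_id="e"):
    return MappedRecord(
        entry_id=entry_id, mapped_rxn=mapped_rxn, unmapped_rxn="", rule_id=rule_id
    )


class TestReactionCenter:
    def test_identity_mapping_empty(self):
        assert reaction_center(IDENTITY) == set()

    def test_hydration_center(self):
        # both alkyne carbons and the water oxygen change bonds
        assert reaction_center(HYDRATION) == {1, 2, 3}

    def test_remote_atoms_excluded(self):
        rxn = (
            "[CH3:1][CH:2]([OH:3])[CH2:4][CH:5]([CH3:6])[OH:7].[O:8]=[O:9]"
            ">>[CH3:1][C:2](=[O:3])[CH2:4][CH:5]([CH3:6])[OH:7].[OH:8][OH:9]"
        )
        center = reaction_center(rxn)
        assert center == {2, 3, 8, 9}
        assert 5 not in center  # the remote carbinol is untouched


class TestCountBondEdits:
    def graph_diff_oracle(self, rxn):
        """Independent edge-set diff over (map pair) -> bond order."""
        def side(s):
            edges = {}
            for part in s.split("."):
                mol = Chem.MolFromSmiles(part)
                for b in mol.GetBonds():
                    m1, m2 = b.GetBeginAtom().GetAtomMapNum(), b.GetEndAtom().GetAtomMapNum()
                    edges[frozenset((m1, m2))] = b.GetBondTypeAsDouble()
            return edges

        lhs, rhs = (side(x) for x in rxn.split(">>"))
        changed = [k for k in set(lhs) | set(rhs) if lhs.get(k) != rhs.get(k)]
        atoms = set().union(*changed) if changed else set()
        return len(changed), len(atoms)

    @pytest.mark.parametrize(
        "rxn,expected",
        [
            (IDENTITY, (0, 0)),
            (HYDRATION, (2, 3)),  # triple->single plus a new C=O
            (GLYC_CLOSED, (2, 3)),
            (GLYC_OPEN, (3, 4)),
        ],
    )
    def test_frozen_examples(self, rxn, expected):
        assert count_bond_edits(rxn) == expected
        assert self.graph_diff_oracle(rxn) == expected

    @pytest.mark.parametrize("rxn", [IDENTITY, HYDRATION, GLYC_CLOSED, GLYC_OPEN])
    def test_symmetric_under_reversal(self, rxn):
        lhs, rhs = rxn.split(">>")
        assert count_bond_edits(rxn) == count_bond_edits(f"{rhs}>>{lhs}")

    def test_open_form_variant_costs_more_edits(self):
        assert count_bond_edits(GLYC_OPEN)[0] > count_bond_edits(GLYC_CLOSED)[0]


class TestSelectMinimalEdit:
    def test_consistent_form_wins(self):
        closed, open_ = record(GLYC_CLOSED), record(GLYC_OPEN)
        assert select_minimal_edit([open_, closed]) == [closed]

    def test_single_candidate_kept(self):
        rec = record(HYDRATION)
        assert select_minimal_edit([rec]) == [rec]

    def test_ties_keep_all(self):
        a, b = record(GLYC_CLOSED, entry_id="a"), record(GLYC_CLOSED, entry_id="b")
        assert select_minimal_edit([a, b]) == [a, b]


class TestCorrectStereo:
    def test_wrong_epimer_outside_center_reset(self, oxidation_rule):
        # (2R,4R)-diol oxidized at C2; the recorded product has the wrong
        # configuration at the untouched C4
        rec = map_single(
            CandidateReaction(
                "e4",
                ("C[C@@H](O)C[C@@H](O)C", "O=O"),
                ("C[C@H](O)CC(C)=O", "OO"),
            ),
            [oxidation_rule],
        )
        fixed = correct_stereo(rec)
        lhs, rhs = fixed.mapped_rxn.split(">>")
        product = next(s for s in rhs.split(".") if "C@" in s)
        reactant = next(s for s in lhs.split(".") if "C@" in s)
        # the surviving stereocenter now carries the reactant's parity
        from biocatmap.stereo import _parity

        pmol = Chem.AddHs(Chem.MolFromSmiles(product))
        rmol = Chem.AddHs(Chem.MolFromSmiles(reactant))

        def parity_of(mol, map_num):
            for atom in mol.GetAtoms():
                if atom.GetAtomMapNum() == map_num:
                    return _parity(mol, atom.GetIdx())
            return None

        surviving = next(
            a.GetAtomMapNum()
            for a in Chem.MolFromSmiles(product).GetAtoms()
            if a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
        )
        assert parity_of(pmol, surviving) == parity_of(rmol, surviving)

    def test_achiral_reaction_unchanged(self):
        rec = record(HYDRATION)
        assert correct_stereo(rec).mapped_rxn == rec.mapped_rxn

    def test_inversion_at_reacting_center_preserved(self):
        # substitution with inversion: the stereocenter is part of the
        # reaction center, so its flip must survive correction
        rxn = (
            "[CH3:1][C@@H:2]([Cl:3])[CH2:4][CH3:5].[OH2:6]"
            ">>[CH3:1][C@H:2]([OH:6])[CH2:4][CH3:5].[ClH:3]"
        )
        rec = record(rxn)
        assert correct_stereo(rec).mapped_rxn == rxn

    def test_stereo_only_records_exempt(self):
        rec = record(
            "[CH3:1][CH2:2][C@@H:3]([CH3:4])[OH:5]"
            ">>[CH3:1][CH2:2][C@H:3]([CH3:4])[OH:5]",
            rule_id="stereo_only",
        )
        assert correct_stereo(rec).mapped_rxn == rec.mapped_rxn

    def test_never_alters_connectivity_or_maps(self, oxidation_rule):
        rec = map_single(
            CandidateReaction(
                "e4",
                ("C[C@@H](O)C[C@@H](O)C", "O=O"),
                ("C[C@H](O)CC(C)=O", "OO"),
            ),
            [oxidation_rule],
        )
        fixed = correct_stereo(rec)

        def skeleton(rxn):
            out = []
            for side in rxn.split(">>"):
                for part in sorted(side.split(".")):
                    mol = Chem.MolFromSmiles(part)
                    Chem.RemoveStereochemistry(mol)
                    out.append(Chem.MolToSmiles(mol))
            return out

        assert skeleton(fixed.mapped_rxn) == skeleton(rec.mapped_rxn)
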