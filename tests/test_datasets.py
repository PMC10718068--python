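"""Retrosynthesis and regioselectivity dataset construction and metrics."""

import pytest

from biocatmap.datasets import (
    build_regio_dataset,
    build_retro_dataset,
    random_split,
    regio_metrics,
)
from biocatmap.mapping import map_single
from biocatmap.records import CandidateReaction, RegioRow


@pytest.fixture(scope="module")
def oxidase_corpus():
    """Constructed corpus: many oxidations sharing the H2O2 co-product."""
    from conftest import make_rule, OXIDATION_SMARTS

    rule = make_rule("R02", OXIDATION_SMARTS)
    records = []
    # 101 distinct secondary alcohols -> H2O2 occurs 101 times as a product
    for n in range(1, 102):
        chain = "C" * n
        rec = map_single(
            CandidateReaction(
                f"r{n}", (f"{chain}C(C)O", "O=O"), (f"{chain}C(C)=O", "OO")
            ),
            [rule],
        )
        assert rec is not None
        records.append(rec)
    return records


class TestBuildRetroDataset:
    def test_frequent_product_removed_and_reactant_pruned(self, oxidase_corpus):
        retro, templates = build_retro_dataset(oxidase_corpus, threshold=100)
        assert len(retro) == 101
        for rec in retro:
            lhs, rhs = rec.unmapped_rxn.split(">>")
            assert "OO" not in rhs.split(".")  # the frequent co-product is gone
            assert "O=O" not in lhs.split(".")  # O2 shares no maps with the ketone
            assert len(rhs.split(".")) == 1  # single product
        assert len(templates) >= 1

    def test_below_threshold_products_survive(self, oxidase_corpus):
        retro, _ = build_retro_dataset(oxidase_corpus[:5], threshold=100)
        # only five H2O2 occurrences: nothing filtered, two products remain,
        # so the single-product filter drops every reaction
        assert retro == []

    def test_duplicates_removed_after_cofactor_removal(self, oxidase_corpus):
        doubled = oxidase_corpus + oxidase_corpus
        retro, _ = build_retro_dataset(doubled, threshold=200)
        assert len(retro) == len(
            build_retro_dataset(oxidase_corpus, threshold=100)[0]
        )

    def test_multi_product_reaction_excluded(self, oxidase_corpus, hydration_rule):
        # glycoside hydrolysis yields two rare products: it must not pass
        from conftest import make_rule

        glyc = make_rule(
            "R04",
            "[CH3:1][O:2][CH:3]1[CH2:5][CH2:6][CH2:7][O:4]1.[OH2:8]"
            ">>[CH3:1][OH:2].[OH:8][CH:3]1[CH2:5][CH2:6][CH2:7][O:4]1",
        )
        rec = map_single(
            CandidateReaction(
                "g", ("COC1CCCO1", "O"), ("OC1CCCO1", "CO")
            ),
            [glyc],
        )
        retro, _ = build_retro_dataset(oxidase_corpus + [rec], threshold=100)
        assert all("OC1CCCO1" not in r.unmapped_rxn for r in retro)


class TestBuildRegioDataset:
    def test_two_site_diol_two_rows(self, oxidation_rule):
        rec = map_single(
            CandidateReaction(
                "d", ("CCC(O)CC(C)O", "O=O"), ("CCC(O)CC(C)=O", "OO")
            ),
            [oxidation_rule],
        )
        rows = build_regio_dataset([rec])
        assert len(rows) == 2
        assert sum(r.label for r in rows) == 1

    def test_unique_site_yields_no_rows(self, oxidation_rule):
        rec = map_single(
            CandidateReaction("u", ("CC(C)O", "O=O"), ("CC(C)=O", "OO")),
            [oxidation_rule],
        )
        assert build_regio_dataset([rec]) == []

    def test_triol_three_rows(self, oxidation_rule):
        rec = map_single(
            CandidateReaction("t", ("OCC(O)CCO", "O=O"), ("OCC(O)CC=O", "OO")),
            [oxidation_rule],
        )
        rows = build_regio_dataset([rec])
        assert len(rows) == 3
        assert sum(r.label for r in rows) == 1
        assert len({r.group_key for r in rows}) == 1


class TestRegioMetrics:
    def rows(self):
        g1 = ("A>>B", "t1")
        g2 = ("C>>D", "t2")
        return [
            RegioRow("A>>B1", 1, g1),
            RegioRow("A>>B2", 0, g1),
            RegioRow("A>>B3", 0, g1),
            RegioRow("C>>D1", 1, g2),
            RegioRow("C>>D2", 0, g2),
        ]

    def test_perfect_scores(self):
        rows = self.rows()
        scores = [1.0 if r.label else 0.0 for r in rows]
        assert regio_metrics(rows, scores) == (1.0, 1.0)

    def test_partial_scores(self):
        rows = self.rows()
        # thresholding at 0.5: rows 2 and 5 are classified correctly (2/5),
        # yet both groups rank their true outcome first
        scores = [0.9, 0.8, 0.7, 0.2, 0.1]
        flat, top1 = regio_metrics(rows, scores)
        assert flat == pytest.approx(2 / 5)
        assert top1 == pytest.approx(1.0)
        scores = [0.4, 0.8, 0.7, 0.2, 0.1]
        flat, top1 = regio_metrics(rows, scores)
        assert top1 == pytest.approx(0.5)

    def test_tie_counts_as_failure(self):
        rows = self.rows()
        scores = [0.5, 0.5, 0.1, 0.9, 0.1]
        _flat, top1 = regio_metrics(rows, scores)
        assert top1 == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rows = self.rows()
        scores = dict(zip(rows, [0.9, 0.8, 0.7, 0.2, 0.1]))
        shuffled = [rows[i] for i in (4, 2, 0, 3, 1)]
        assert regio_metrics(rows, scores) == regio_metrics(shuffled, scores)

    def test_group_without_positive_rejected(self):
        rows = [RegioRow("A>>B", 0, ("A", "t"))]
        with pytest.raises(ValueError):
            regio_metrics(rows, [0.1])


class TestRandomSplit:
    def test_fractions_and_determinism(self):
        items = list(range(100))
        train, val, test = random_split(items, seed=7)
        assert (len(train), len(val), len(test)) == (80, 10, 10)
        assert sorted(train + val + test) == items
        assert random_split(items, seed=7) == (train, val, test)
        assert random_split(items, seed=8) != (train, val, test)
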