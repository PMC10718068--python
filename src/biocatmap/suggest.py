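"""Product suggestion for unbalanced or unmappable entries.

A recurring database failure mode is a correctly recorded reactant with a
wrongly recorded product (e.g. a ketone listed under an aldehyde name).  When
an entry cannot be balanced or mapped, probable products are proposed from
what the rest of its EC class does: the rules used by mapped classmates are
applied to the query reactants, and the generated outcomes are ranked by the
Tanimoto similarity of their products to the products of the most
reactant-similar classmate, combined with the query's reactant similarity and
the rule's within-class frequency.  Suggested records pass the same gates as
direct ones (balance, atom conservation, round-trip validation) and are
flagged ``source=suggested`` so users can filter them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .balance import check_balance
from .chem import mol_from_smiles, stripped_canonical
from .mapcanon import check_atom_conservation
from .mapping import apply_rule, _record_from
from .records import CandidateReaction, MappedRecord, RawEntry, ReactionRule
from .templates import validate_roundtrip

__all__ = ["tanimoto", "morgan_bits", "side_fingerprint", "suggest_products"]

FP_RADIUS = 2
FP_BITS = 2048

_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_BITS
)


def morgan_bits(smiles: str) -> frozenset[int]:
    """On-bit set of the circular (Morgan) fingerprint, radius 2, 2048 bits."""
    fp = _generator.GetFingerprint(mol_from_smiles(smiles))
    return frozenset(fp.GetOnBits())


def side_fingerprint(smiles_list) -> frozenset[int]:
    """Fingerprint of one reaction side (union over its molecules)."""
    bits: set[int] = set()
    for s in smiles_list:
        bits |= morgan_bits(s)
    return frozenset(bits)


def tanimoto(a, b, n_bits: int | None = None) -> float:
    """|a AND b| / |a OR b| over equal-length bit sets; 1.0 when both empty."""
    a, b = frozenset(a), frozenset(b)
    if n_bits is not None:
        if max(a, default=-1) >= n_bits or max(b, default=-1) >= n_bits:
            raise ValueError("fingerprint length mismatch")
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass
class SuggestionScore:
    """Ranking information for one suggested outcome."""

    mapped_rxn: str
    rule_id: str
    reactant_similarity: float
    product_similarity: float
    rule_frequency: float

    @property
    def combined_score(self) -> float:
        # geometric mean keeps the score monotone in each similarity and
        # zero whenever either side is entirely dissimilar
        return (self.product_similarity * self.reactant_similarity) ** 0.5


def suggest_products(
    r: CandidateReaction,
    class_records: list[MappedRecord],
    rules: list[ReactionRule],
    entry: RawEntry | None = None,
    k: int = 1,
) -> list[MappedRecord]:
    """Top-*k* suggested records for a failed entry, or an empty list.

    ``class_records`` are the already-mapped records of the entry's EC class;
    ``rules`` is the full rule set (only rules used within the class are
    applied).  Ranking is a stable deterministic sort, invariant to input
    order.
    """
    if not class_records:
        return []
    rules_by_id = {ru.rule_id: ru for ru in rules}
    class_rule_counts = Counter(
        rec.rule_id for rec in class_records if rec.rule_id in rules_by_id
    )
    if not class_rule_counts:
        return []

    query_fp = side_fingerprint(r.reactant_smiles)
    # reference = classmate(s) with the most similar reactants
    sims = []
    for rec in class_records:
        lhs = rec.unmapped_rxn.split(">>")[0].split(".")
        sims.append((tanimoto(query_fp, side_fingerprint(lhs)), rec))
    best_sim = max(s for s, _ in sims)
    references = [rec for s, rec in sims if s == best_sim]

    scored: list[tuple[tuple, SuggestionScore, MappedRecord]] = []
    for rule_id, count in sorted(class_rule_counts.items()):
        rule = rules_by_id[rule_id]
        freq = count / len(class_records)
        for outcome in apply_rule(rule, list(r.reactant_smiles)):
            product_smiles = tuple(
                Chem.MolToSmiles(m) for m in outcome.product_mols
            )
            out_fp = side_fingerprint(
                [stripped_canonical(s, stereo=True) for s in product_smiles]
            )
            prod_sim = max(
                tanimoto(
                    out_fp,
                    side_fingerprint(ref.unmapped_rxn.split(">>")[1].split(".")),
                )
                for ref in references
            )
            score = SuggestionScore(
                mapped_rxn=outcome.mapped_rxn,
                rule_id=rule_id,
                reactant_similarity=best_sim,
                product_similarity=prod_sim,
                rule_frequency=freq,
            )
            cand = r.replace_sides(
                r.reactant_smiles,
                tuple(stripped_canonical(s, stereo=True) for s in product_smiles),
            )
            rec = _record_from(entry, cand, outcome.mapped_rxn, rule)
            rec.source = "suggested"
            # same gates as direct records
            if not check_balance(cand).balanced:
                continue
            if not check_atom_conservation(rec.mapped_rxn):
                continue
            if not validate_roundtrip(rec):
                continue
            sort_key = (
                -score.combined_score,
                -score.rule_frequency,
                score.rule_id,
                rec.unmapped_rxn,
            )
            scored.append((sort_key, score, rec))
    scored.sort(key=lambda t: t[0])
    out: list[MappedRecord] = []
    seen: set[str] = set()
    for _key, _score, rec in scored:
        if rec.unmapped_rxn in seen:
            continue
        seen.add(rec.unmapped_rxn)
        out.append(rec)
        if len(out) == k:
            break
    return out
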