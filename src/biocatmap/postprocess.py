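"""Quality scoring, map standardization, reverse reactions, deduplication.

Quality: within each EC class, a record's quality is the relative frequency
of its mapping rule among the class's records.  A rule that maps most of a
class scores near 1; a rule appearing once in a large class flags a likely
database error.

Reverse reactions: entries tagged reversible contribute their backward
reaction directly (source gains ``reversed``); entries with unknown
reversibility contribute it only when the reversed reaction template already
occurs in the EC class (source gains ``reversed_suggested``); irreversible
entries contribute nothing.

Deduplication operates on standardized mapped SMILES under three key modes:
``within-ec`` (mapped SMILES + EC class — the database's primary notion of a
unique reaction), ``global`` (mapped SMILES only), and ``full-provenance``
(additionally natural/organism/protein fields, for users who filter first
and deduplicate after).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .mapcanon import standardize_maps
from .records import MappedRecord

__all__ = [
    "compute_quality",
    "standardize_maps",
    "standardize_records",
    "add_reverse",
    "deduplicate",
]


def compute_quality(records: Sequence[MappedRecord]) -> list[MappedRecord]:
    """Fill ``quality`` = within-EC relative frequency of each record's rule."""
    by_ec: dict[str, list[MappedRecord]] = defaultdict(list)
    for rec in records:
        by_ec[rec.ec].append(rec)
    out = []
    for rec in records:
        group = by_ec[rec.ec]
        count = sum(1 for g in group if g.rule_id == rec.rule_id)
        out.append(rec.copy(quality=count / len(group)))
    return out


def standardize_records(records: Sequence[MappedRecord]) -> list[MappedRecord]:
    """Canonicalize every record's mapped SMILES (drops non-conserving ones)."""
    out = []
    for rec in records:
        out.append(rec.copy(mapped_rxn=standardize_maps(rec.mapped_rxn)))
    return out


def _reverse_rxn(rxn_smiles: str) -> str:
    lhs, rhs = rxn_smiles.split(">>")
    return f"{rhs}>>{lhs}"


def add_reverse(
    records: Sequence[MappedRecord],
    class_templates: dict[str, set[str]] | None = None,
) -> list[MappedRecord]:
    """Append backward reactions according to each record's reversibility tag.

    ``class_templates`` maps EC class -> set of canonical forward templates
    observed in that class; it is consulted for unknown-reversibility
    records.  Reversal swaps the sides and preserves the atom maps, so
    reversing a reversed record regenerates the original standardized string.
    """
    from .templates import canonical_template, extract_template, reverse_template

    if class_templates is None:
        class_templates = defaultdict(set)
        for rec in records:
            class_templates[rec.ec].add(canonical_template(extract_template(rec)))

    out = list(records)
    for rec in records:
        if rec.source.endswith("reversed") or rec.source.endswith("reversed_suggested"):
            continue
        if rec.reversibility == "irreversible":
            continue
        if rec.reversibility == "reversible":
            suffix = "reversed"
        else:  # unknown: likely reversible only if the reverse template is
            # already present in the EC class
            rev_template = canonical_template(
                reverse_template(extract_template(rec))
            )
            if rev_template not in class_templates.get(rec.ec, set()):
                continue
            suffix = "reversed_suggested"
        base = rec.source.split()[0]  # direct | suggested
        out.append(
            rec.copy(
                mapped_rxn=standardize_maps(_reverse_rxn(rec.mapped_rxn)),
                unmapped_rxn=_reverse_rxn(rec.unmapped_rxn),
                source=f"{base} {suffix}",
            )
        )
    return out


def deduplicate(
    records: Sequence[MappedRecord], key_mode: str = "within-ec"
) -> list[MappedRecord]:
    """Remove duplicate records; the first record in stable order survives.

    Records must already be standardized.  Idempotent and insensitive to
    input order (the survivor is chosen by a deterministic sort of the
    records' exported fields, not by arrival order).
    """
    def key(rec: MappedRecord):
        if key_mode == "global":
            return (rec.mapped_rxn,)
        if key_mode == "within-ec":
            return (rec.mapped_rxn, rec.ec)
        if key_mode == "full-provenance":
            return (
                rec.mapped_rxn,
                rec.ec,
                rec.natural,
                rec.organism,
                rec.protein_refs,
                rec.protein_db,
            )
        raise ValueError(f"unknown key mode {key_mode!r}")

    ordered = sorted(
        records,
        key=lambda r: (
            r.mapped_rxn,
            r.ec,
            r.source,
            r.steps,
            r.entry_id,
            r.organism,
        ),
    )
    seen: set = set()
    out = []
    for rec in ordered:
        k = key(rec)
        if k in seen:
            continue
        seen.add(k)
        out.append(rec)
    return out
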