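"""Downstream dataset construction: retrosynthesis and regioselectivity.

Retrosynthesis preparation turns mapped records into single-product
reactions suitable for template-relevance models: products occurring more
than a frequency threshold (default 100) are removed (cofactors, protons and
other ubiquitous molecules), reactant molecules sharing no atom maps with the
remaining products are deleted, duplicates are dropped, and only reactions
with exactly one product molecule are kept.

Regioselectivity data asks which of several chemically possible sites
actually reacted: each record's own template is re-applied to its reactants;
when more than one distinct product set arises, every candidate becomes one
row — label 1 for the recorded outcome, 0 otherwise — grouped by (reactants,
template).  Two metrics evaluate classifiers on such data: flat accuracy over
rows, and top-1 accuracy over groups (the label-1 row must have a strictly
higher raw score than every label-0 row of its group; ties count as
failures).
"""

from __future__ import annotations

import logging
import random
from collections import Counter, defaultdict
from typing import Mapping, Sequence

from rdkit import Chem

from .chem import parse_reaction_smiles, stripped_canonical
from .records import MappedRecord, RegioRow
from .templates import apply_template, canonical_template, extract_template

logger = logging.getLogger(__name__)

__all__ = [
    "build_retro_dataset",
    "build_regio_dataset",
    "regio_metrics",
    "random_split",
]

DEFAULT_PRODUCT_FREQUENCY_THRESHOLD = 100


def build_retro_dataset(
    records: Sequence[MappedRecord],
    threshold: int = DEFAULT_PRODUCT_FREQUENCY_THRESHOLD,
    template_radius: int = 1,
) -> tuple[list[MappedRecord], set[str]]:
    """Single-product reactions plus their template vocabulary.

    Steps, in order: frequent-product removal (> *threshold* occurrences),
    unmatched-reactant deletion (no map shared with the kept products),
    deduplication by the resulting reaction, single-product filter.
    """
    sides = []
    product_freq: Counter = Counter()
    for rec in records:
        reactants, products = parse_reaction_smiles(rec.mapped_rxn)
        sides.append((rec, reactants, products))
        for p in products:
            product_freq[stripped_canonical(p, stereo=True)] += 1

    out: list[MappedRecord] = []
    seen: set[str] = set()
    templates: set[str] = set()
    for rec, reactants, products in sides:
        kept_products = [
            p
            for p in products
            if product_freq[stripped_canonical(p, stereo=True)] <= threshold
        ]
        kept_maps = {
            a.GetAtomMapNum()
            for p in kept_products
            for a in p.GetAtoms()
            if a.GetAtomMapNum()
        }
        kept_reactants = [
            r
            for r in reactants
            if any(a.GetAtomMapNum() in kept_maps for a in r.GetAtoms())
        ]
        if not kept_products or not kept_reactants:
            continue
        mapped = (
            ".".join(Chem.MolToSmiles(m) for m in kept_reactants)
            + ">>"
            + ".".join(Chem.MolToSmiles(m) for m in kept_products)
        )
        unmapped = (
            ".".join(stripped_canonical(m, stereo=True) for m in kept_reactants)
            + ">>"
            + ".".join(stripped_canonical(m, stereo=True) for m in kept_products)
        )
        if unmapped in seen:  # duplicates surface once cofactors are removed
            continue
        seen.add(unmapped)
        if len(kept_products) != 1:
            continue
        new_rec = rec.copy(mapped_rxn=mapped, unmapped_rxn=unmapped)
        out.append(new_rec)
        templates.add(
            canonical_template(extract_template(new_rec, radius=template_radius))
        )
    return out, templates


def build_regio_dataset(
    records: Sequence[MappedRecord], template_radius: int = 1
) -> list[RegioRow]:
    """One row per alternative reaction site of each single-product record.

    Records whose template yields fewer than two distinct product sets are
    dropped (no regiochemical choice to learn); records whose template fails
    on their own reactants violate the upstream round-trip invariant and are
    dropped with a log message.
    """
    rows: list[RegioRow] = []
    for rec in records:
        reactants, products = parse_reaction_smiles(rec.mapped_rxn)
        reactant_side = ".".join(
            stripped_canonical(m, stereo=True) for m in reactants
        )
        recorded_key = ".".join(
            sorted(stripped_canonical(m) for m in products)
        )
        template = extract_template(rec, radius=template_radius)
        from .templates import IDENTITY_TEMPLATE

        if template == IDENTITY_TEMPLATE:
            continue  # stereo-only records carry no regiochemical choice
        try:
            outcomes = apply_template(
                template, [stripped_canonical(m, stereo=True) for m in reactants]
            )
        except Exception as exc:
            logger.warning("template failed for %s: %s", rec.entry_id, exc)
            continue
        candidates: dict[str, str] = {}
        for outcome in outcomes:
            key = ".".join(
                sorted(stripped_canonical(p) for p in outcome.product_mols)
            )
            candidates.setdefault(
                key,
                ".".join(
                    stripped_canonical(p, stereo=True) for p in outcome.product_mols
                ),
            )
        if recorded_key not in candidates:
            logger.warning(
                "template did not regenerate recorded product for %s", rec.entry_id
            )
            continue
        if len(candidates) < 2:
            continue
        group = (reactant_side, canonical_template(template))
        for key in sorted(candidates):
            rows.append(
                RegioRow(
                    rxn_smiles=f"{reactant_side}>>{candidates[key]}",
                    label=1 if key == recorded_key else 0,
                    group_key=group,
                )
            )
    return rows


def regio_metrics(
    rows: Sequence[RegioRow],
    scores: Sequence[float] | Mapping[RegioRow, float],
    threshold: float = 0.5,
) -> tuple[float, float]:
    """(flat accuracy, top-1 accuracy) of raw scores against the rows.

    Flat accuracy thresholds each score at *threshold* (>= predicts 1) and
    compares to the label.  Top-1 accuracy is the fraction of groups whose
    label-1 row scores strictly higher than every label-0 row of the group.
    """
    if not isinstance(scores, Mapping):
        if len(scores) != len(rows):
            raise ValueError("one score per row required")
        scores = dict(zip(rows, scores))
    correct = sum(
        1 for row in rows if (scores[row] >= threshold) == bool(row.label)
    )
    flat = correct / len(rows) if rows else 0.0

    groups: dict[tuple, list[RegioRow]] = defaultdict(list)
    for row in rows:
        groups[row.group_key].append(row)
    top1_hits = 0
    for key, members in groups.items():
        positives = [r for r in members if r.label == 1]
        if len(positives) != 1:
            raise ValueError(f"group {key} must have exactly one label-1 row")
        pos_score = scores[positives[0]]
        if all(scores[r] < pos_score for r in members if r.label == 0):
            top1_hits += 1
    top1 = top1_hits / len(groups) if groups else 0.0
    return flat, top1


def random_split(
    items: Sequence, seed: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[list, list, list]:
    """Deterministic random train/validation/test split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    order = list(items)
    random.Random(seed).shuffle(order)
    n = len(order)
    n_train = round(n * fractions[0])
    n_val = round(n * fractions[1])
    return order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]
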