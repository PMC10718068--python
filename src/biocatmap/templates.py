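"""Reaction-template extraction and round-trip validation.

A template is a reaction SMARTS cut out of a mapped reaction around its
reaction center (plus a configurable bond-radius environment).  Applying the
template to the record's own reactants must regenerate the recorded products;
mappings that fail this round trip are dropped.  Templates are also the
currency of two downstream steps: deciding whether an unknown-reversibility
reaction is "likely reversible" (its reverse template already occurs in the
EC class) and enumerating alternative reaction sites for regioselectivity
data.

Template atoms are written generically as ``[#<Z>;<charge>:<map>]`` — element
and formal charge, with bond orders explicit — so a template extracted at one
site can match chemically equivalent sites elsewhere.  Hydrogen counts on
product atoms are left to valence completion.  Templates are achiral:
round-trip comparison is stereo-stripped, and stereochemical consistency is
enforced by the separate stereo-correction pass.
"""

from __future__ import annotations

import re

from rdkit import Chem

from .chem import parse_reaction_smiles, stripped_canonical
from .mapcanon import standardize_maps
from .mapping import apply_rule
from .records import MappedRecord, ReactionRule
from .stereo import reaction_center

__all__ = [
    "IDENTITY_TEMPLATE",
    "extract_template",
    "apply_template",
    "validate_roundtrip",
    "reverse_template",
    "canonical_template",
]

# degenerate template for records with an empty reaction center
# (stereo-only reactions): the identity transformation
IDENTITY_TEMPLATE = "identity"

_BRACKET = re.compile(r"\[[^\[\]]*:(\d+)\]")


def _generic_atom(atom: Chem.Atom, with_h: bool = False) -> str:
    q = atom.GetFormalCharge()
    charge = "" if q == 0 else (f"+{q}" if q > 0 else str(q))
    h = f";H{atom.GetTotalNumHs()}" if with_h else ""
    return f"[#{atom.GetAtomicNum()}{charge}{h}:{atom.GetAtomMapNum()}]"


def _fragment_smarts(
    mol: Chem.Mol, maps: set[int], radius: int, strict_h: bool = False
) -> str | None:
    """Generic SMARTS for the sub-graph of *mol* around the given map numbers."""
    seed = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in maps]
    if not seed:
        return None
    selected = set(seed)
    frontier = set(seed)
    for _ in range(radius):
        nxt = set()
        for idx in frontier:
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nbr.GetIdx() not in selected:
                    nxt.add(nbr.GetIdx())
        selected |= nxt
        frontier = nxt
    bonds = [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in selected and b.GetEndAtomIdx() in selected
    ]
    # canonical atom ordering must not depend on the record's map-number
    # values: rank a map-free copy, but emit the generic query symbols
    # (which carry the real map numbers) via atomSymbols
    stripped = Chem.Mol(mol)
    for atom in stripped.GetAtoms():
        atom.SetAtomMapNum(0)
    symbols = [
        _generic_atom(a, with_h=strict_h and a.GetAtomMapNum() in maps)
        for a in mol.GetAtoms()
    ]
    smarts = Chem.MolFragmentToSmiles(
        stripped,
        atomsToUse=sorted(selected),
        bondsToUse=bonds or None,
        atomSymbols=symbols,
        canonical=True,
        isomericSmiles=False,
        allBondsExplicit=True,
    )
    # components of one molecule must stay grouped so the pattern matches a
    # single molecule rather than several
    if "." in smarts:
        smarts = f"({smarts})"
    return smarts


def extract_template(
    m: MappedRecord | str, radius: int = 1, strict_h: bool = False
) -> str:
    """Reaction SMARTS around the reaction center with *radius* bonds of
    environment; :data:`IDENTITY_TEMPLATE` for an empty center.

    With ``strict_h`` the center atoms additionally carry their hydrogen
    counts.  Strict templates are used for round-trip validation, where the
    H bookkeeping of the rewrite must be reproducible; the default generic
    form matches chemically equivalent sites with different H environments
    and is used for regioselectivity enumeration and reverse-template
    queries.  The mapped reaction is canonicalized first so equivalent
    mappings give byte-identical templates.
    """
    rxn = m if isinstance(m, str) else m.mapped_rxn
    rxn = standardize_maps(rxn)
    center = reaction_center(rxn)
    if not center:
        return IDENTITY_TEMPLATE
    reactants, products = parse_reaction_smiles(rxn)
    lhs = [
        s
        for mol in reactants
        if (s := _fragment_smarts(mol, center, radius, strict_h))
    ]
    rhs = [
        s
        for mol in products
        if (s := _fragment_smarts(mol, center, radius, strict_h))
    ]
    return ".".join(lhs) + ">>" + ".".join(rhs)


def apply_template(template: str, reactant_smiles: list[str]) -> list:
    """Outcomes of applying a template to a reactant list (spectators kept)."""
    if template == IDENTITY_TEMPLATE:
        return []
    rule = ReactionRule(rule_id="template", transform=template)
    return apply_rule(rule, reactant_smiles)


def validate_roundtrip(m: MappedRecord, radius: int = 1) -> bool:
    """True iff the extracted template regenerates the recorded products.

    Products are compared as stereo-stripped canonical multisets.  A record
    with an empty reaction center validates iff its two sides are identical
    up to stereochemistry (the only way an identity mapping arises).
    """
    try:
        reactants, products = parse_reaction_smiles(m.mapped_rxn)
        target = sorted(stripped_canonical(mol) for mol in products)
        template = extract_template(m, radius=radius, strict_h=True)
    except Exception:
        return False  # corrupted mapping: no template can be cut out
    if template == IDENTITY_TEMPLATE:
        return sorted(stripped_canonical(mol) for mol in reactants) == target
    try:
        outcomes = apply_template(
            template, [stripped_canonical(mol, stereo=True) for mol in reactants]
        )
    except Exception:
        return False
    for outcome in outcomes:
        got = sorted(stripped_canonical(p) for p in outcome.product_mols)
        if got == target:
            return True
    return False


def reverse_template(template: str) -> str:
    if template == IDENTITY_TEMPLATE:
        return IDENTITY_TEMPLATE
    lhs, rhs = template.split(">>")
    return f"{rhs}>>{lhs}"


def canonical_template(template: str) -> str:
    """Comparable form: fragments sorted, map numbers renumbered 1..n.

    Used for exact-string template matching (reverse-template queries and
    template-vocabulary deduplication).
    """
    if template == IDENTITY_TEMPLATE:
        return IDENTITY_TEMPLATE
    lhs, rhs = template.split(">>")

    def sort_side(side: str) -> str:
        frags = side.split(".") if not side.startswith("(") else [side]
        erased = sorted(frags, key=lambda f: _BRACKET.sub("[*]", f))
        return ".".join(erased)

    lhs, rhs = sort_side(lhs), sort_side(rhs)
    renum: dict[str, str] = {}
    for match in _BRACKET.finditer(lhs + ">>" + rhs):
        old = match.group(1)
        if old not in renum:
            renum[old] = str(len(renum) + 1)
    return _BRACKET.sub(
        lambda mt: mt.group(0)[: mt.start(1) - mt.start(0)]
        + renum[mt.group(1)]
        + "]",
        lhs + ">>" + rhs,
    )
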