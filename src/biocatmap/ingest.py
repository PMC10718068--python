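"""Parsing of reaction texts and resolution of trivial names to SMILES.

Raw database reactions are text strings like ``"2 H2O2 = 2 H2O + O2"`` with
substrates and products given by trivial names.  This module extracts names
and stoichiometry, resolves each name to one or more canonical SMILES via a
configurable resolver chain (a local dictionary by default; remote services
can be plugged in), and assembles every combination of resolved structures
into candidate reaction SMILES.
"""

from __future__ import annotations

import itertools
import logging
import re
from typing import Iterable, Mapping, Protocol

from .chem import ChemError, standardize_smiles
from .records import CandidateReaction, ParsedReaction, normalize_reversibility

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "parse_reaction_text",
    "render_reaction_text",
    "DictResolver",
    "resolve_name",
    "assemble_reactions",
    "standardize_smiles",
]

SEPARATOR = "="
TERM_SPLIT = " + "
_COEFF = re.compile(r"^(\d+)\s+(.+)$")

DEFAULT_COMBINATION_CAP = 64


class ParseError(ValueError):
    """Malformed reaction text."""


def _parse_side(side: str) -> tuple[tuple[str, int], ...]:
    terms = []
    for term in side.split(TERM_SPLIT):
        term = term.strip()
        if not term:
            raise ParseError(f"empty term in side {side!r}")
        m = _COEFF.match(term)
        if m:
            coeff, name = int(m.group(1)), m.group(2).strip()
        else:
            coeff, name = 1, term
        if coeff < 1:
            raise ParseError(f"non-positive coefficient in term {term!r}")
        terms.append((name, coeff))
    return tuple(terms)


def parse_reaction_text(text: str, tag: str = "unknown") -> ParsedReaction:
    """Extract names and stoichiometry from one reaction text.

    The text must contain exactly one ``=`` separating two non-empty sides;
    terms are separated by ``" + "`` and may carry a leading integer
    coefficient (default 1).
    """
    if text.count(SEPARATOR) != 1:
        raise ParseError(f"expected exactly one {SEPARATOR!r} in {text!r}")
    lhs, rhs = text.split(SEPARATOR)
    if not lhs.strip() or not rhs.strip():
        raise ParseError(f"empty reaction side in {text!r}")
    return ParsedReaction(
        substrates=_parse_side(lhs),
        products=_parse_side(rhs),
        reversibility=normalize_reversibility(tag),
    )


def render_reaction_text(p: ParsedReaction) -> str:
    """Inverse of :func:`parse_reaction_text` (round-trips)."""

    def side(terms):
        return TERM_SPLIT.join(
            name if c == 1 else f"{c} {name}" for name, c in terms
        )

    return f"{side(p.substrates)} {SEPARATOR} {side(p.products)}"


class Resolver(Protocol):
    """A name -> SMILES-set resolution strategy."""

    def __call__(self, name: str) -> Iterable[str]: ...


class DictResolver:
    """Local ligand-dictionary resolver (the default, offline strategy).

    Names are matched case-sensitively after whitespace normalization:
    d-/l- style prefixes make trivial names case-meaningful.
    """

    def __init__(self, ligands: Mapping[str, Iterable[str]]):
        self._table = {str(k).strip(): list(v) for k, v in ligands.items()}

    def __call__(self, name: str) -> list[str]:
        return list(self._table.get(name.strip(), []))


def resolve_name(name: str, resolvers: Iterable[Resolver]) -> set[str]:
    """Union of standardized answers from every resolver in the chain.

    Resolver I/O failures are logged and treated as no-answer; an empty set
    marks the name (and hence its entry) as unresolved.
    """
    answers: set[str] = set()
    for resolver in resolvers:
        try:
            raw = list(resolver(name))
        except Exception as exc:  # remote resolvers may fail; never fatal
            logger.warning("resolver %r failed on %r: %s", resolver, name, exc)
            continue
        for smiles in raw:
            try:
                answers.add(standardize_smiles(smiles))
            except ChemError:
                logger.warning("dropping unparseable SMILES %r for %r", smiles, name)
    return answers


def assemble_reactions(
    entry_id: str,
    parsed: ParsedReaction,
    names_to_smiles: Mapping[str, set[str] | list[str]],
    cap: int = DEFAULT_COMBINATION_CAP,
) -> list[CandidateReaction]:
    """Cartesian product of per-name SMILES choices into candidate reactions.

    Every name must have at least one SMILES (callers skip unresolved
    entries).  Coefficients are expanded to repeated molecules.  When the
    number of combinations exceeds *cap*, the first *cap* in sorted
    resolution-path order are kept and the truncation logged.
    """
    names = [n for n, _ in parsed.substrates] + [n for n, _ in parsed.products]
    for name in names:
        if not names_to_smiles.get(name):
            raise KeyError(f"unresolved name {name!r}")
    unique_names = list(dict.fromkeys(names))
    choices = [sorted(names_to_smiles[n]) for n in unique_names]
    total = 1
    for c in choices:
        total *= len(c)
    if total > cap:
        logger.warning(
            "entry %s: %d combinations exceed cap %d; truncating", entry_id, total, cap
        )
    out = []
    for combo in itertools.islice(itertools.product(*choices), cap):
        chosen = dict(zip(unique_names, combo))
        reactants = tuple(
            chosen[name] for name, c in parsed.substrates for _ in range(c)
        )
        products = tuple(
            chosen[name] for name, c in parsed.products for _ in range(c)
        )
        out.append(
            CandidateReaction(
                entry_id=entry_id,
                reactant_smiles=reactants,
                product_smiles=products,
                resolution_path=tuple(sorted(chosen.items())),
            )
        )
    return out
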