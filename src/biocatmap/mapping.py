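"""Rule-based atom mapping: apply SMARTS rules while tracking every atom.

A reaction rule is a reaction SMARTS whose templates carry atom maps.  Rule
application enumerates every embedding of the reactant patterns into the
substrate molecules and rewrites the matched subgraph, while this module
tracks each heavy atom through the rewrite: pattern-matched atoms inherit the
rule correspondence, spectator atoms keep their pre-assigned numbers, so every
outcome is a fully atom-mapped reaction.

A rule "succeeds" on a recorded reaction when one of its outcomes reproduces
the recorded product multiset (compared on stereo-stripped canonical SMILES;
stereochemistry is reconciled by a separate correction pass).  When several
rules succeed with different mappings, the rule changing the fewest atoms and
bonds is preferred, then the most frequently applicable one, then the
lexicographically smallest rule id.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import ChemError, mol_from_smiles, stripped_canonical
from .mapcanon import standardize_maps
from .records import (
    STEREO_ONLY_RULE_ID,
    CandidateReaction,
    MappedRecord,
    RawEntry,
    ReactionRule,
)

__all__ = [
    "apply_rule",
    "map_single",
    "map_stereo_only",
    "order_rules",
    "rule_edit_counts",
    "MappedOutcome",
]


@dataclass
class MappedOutcome:
    """One atom-mapped outcome of applying a rule to a set of reactants."""

    mapped_rxn: str
    reactant_mols: list  # mapped copies of every input molecule
    product_mols: list  # rewritten products plus untouched spectators
    reacted_indices: tuple[int, ...]  # which input molecules matched the rule


_rxn_cache: dict[str, AllChem.ChemicalReaction] = {}


def _compile(smarts: str) -> AllChem.ChemicalReaction:
    rxn = _rxn_cache.get(smarts)
    if rxn is None:
        rxn = AllChem.ReactionFromSmarts(smarts)
        if rxn is None:
            raise ChemError(f"unparseable reaction SMARTS: {smarts!r}")
        rxn.Initialize()
        _rxn_cache[smarts] = rxn
    return rxn


def rule_edit_counts(smarts: str) -> tuple[int, int]:
    """(n_atoms_changed, n_bonds_changed) derived from the rule's own pattern.

    A changed bond is one between two mapped template atoms whose presence or
    order differs between the reactant and product patterns; changed atoms are
    those incident to a changed bond or whose formal charge differs.
    """
    rxn = _compile(smarts)

    def side_info(templates):
        bonds: dict[tuple[int, int], float] = {}
        charge: dict[int, int] = {}
        for t in templates:
            for atom in t.GetAtoms():
                if atom.GetAtomMapNum():
                    charge[atom.GetAtomMapNum()] = atom.GetFormalCharge()
            for bond in t.GetBonds():
                m1 = bond.GetBeginAtom().GetAtomMapNum()
                m2 = bond.GetEndAtom().GetAtomMapNum()
                if m1 and m2:
                    bonds[(min(m1, m2), max(m1, m2))] = bond.GetBondTypeAsDouble()
        return bonds, charge

    r_bonds, r_charge = side_info(rxn.GetReactants())
    p_bonds, p_charge = side_info(rxn.GetProducts())
    changed_atoms: set[int] = set()
    n_bonds = 0
    for key in set(r_bonds) | set(p_bonds):
        if r_bonds.get(key) != p_bonds.get(key):
            n_bonds += 1
            changed_atoms.update(key)
    for m in set(r_charge) & set(p_charge):
        if r_charge[m] != p_charge[m]:
            changed_atoms.add(m)
    return len(changed_atoms), n_bonds


def _template_map_index(rxn) -> dict[int, int]:
    """Template atom-map number -> reactant-template position."""
    out = {}
    for ti in range(rxn.GetNumReactantTemplates()):
        for atom in rxn.GetReactantTemplate(ti).GetAtoms():
            if atom.GetAtomMapNum():
                out[atom.GetAtomMapNum()] = ti
    return out


def apply_rule(
    rule: ReactionRule, reactants: Sequence[Chem.Mol | str]
) -> list[MappedOutcome]:
    """All distinct atom-mapped outcomes of *rule* on the reactant set.

    Every heavy atom of every input molecule receives a unique map number
    before application; molecules not consumed by the rule pass through as
    spectators on both sides.  Symmetry-equivalent outcomes are collapsed via
    canonical map standardization.  A rule that does not match returns an
    empty list.
    """
    rxn = _compile(rule.transform)
    nt = rxn.GetNumReactantTemplates()
    tmap = _template_map_index(rxn)

    mols = [
        mol_from_smiles(m) if isinstance(m, str) else Chem.Mol(m) for m in reactants
    ]
    # assign unique map numbers, honouring any numbers already present so that
    # multi-step application can chain outcomes without losing the tracking
    used = {a.GetAtomMapNum() for m in mols for a in m.GetAtoms() if a.GetAtomMapNum()}
    counter = itertools.count(max(used, default=0) + 1)
    premaps: list[list[int]] = []
    for mol in mols:
        maps = []
        for atom in mol.GetAtoms():
            if not atom.GetAtomMapNum():
                atom.SetAtomMapNum(next(counter))
            maps.append(atom.GetAtomMapNum())
        premaps.append(maps)
    fresh_counter = counter

    outcomes: dict[str, MappedOutcome] = {}
    seen_combos: set[tuple[str, ...]] = set()
    canon = [stripped_canonical(m, stereo=True) for m in mols]
    for combo in itertools.permutations(range(len(mols)), nt):
        key = tuple(canon[i] for i in combo)
        if key in seen_combos:
            continue
        seen_combos.add(key)
        try:
            product_sets = rxn.RunReactants(tuple(mols[i] for i in combo))
        except Exception:
            continue
        spectators = [mols[i] for i in range(len(mols)) if i not in combo]
        for prods in product_sets:
            prod_mols = []
            ok = True
            for p in prods:
                try:
                    Chem.SanitizeMol(p)
                except Exception:
                    # explicit-H counts copied from the matched reactant atom
                    # (e.g. a chiral CH) can violate valence after the
                    # rewrite; recompute hydrogens on the changed atoms
                    for atom in p.GetAtoms():
                        if atom.HasProp("old_mapno"):
                            atom.SetNumExplicitHs(0)
                            atom.SetNoImplicit(False)
                            atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
                    try:
                        Chem.SanitizeMol(p)
                    except Exception:
                        ok = False
                        break
                for atom in p.GetAtoms():
                    if atom.GetAtomMapNum():
                        continue  # spectator atom kept its number
                    props = atom.GetPropsAsDict()
                    old_mapno = props.get("old_mapno")
                    if old_mapno is not None and old_mapno in tmap:
                        src = combo[tmap[old_mapno]]
                        atom.SetAtomMapNum(premaps[src][props["react_atom_idx"]])
                    else:  # atom introduced by the product template
                        atom.SetAtomMapNum(next(fresh_counter))
                prod_mols.append(p)
            if not ok:
                continue
            all_products = prod_mols + [Chem.Mol(s) for s in spectators]
            rxn_smiles = (
                ".".join(Chem.MolToSmiles(m) for m in mols)
                + ">>"
                + ".".join(Chem.MolToSmiles(m) for m in all_products)
            )
            try:
                canon_rxn = standardize_maps(rxn_smiles)
            except ChemError:
                continue  # rule not atom-conserving on this embedding
            if canon_rxn not in outcomes:
                outcomes[canon_rxn] = MappedOutcome(
                    mapped_rxn=rxn_smiles,
                    reactant_mols=[Chem.Mol(m) for m in mols],
                    product_mols=all_products,
                    reacted_indices=combo,
                )
    return [outcomes[k] for k in sorted(outcomes)]


def _transfer_recorded_products(
    outcome: MappedOutcome, recorded_products: Sequence[str]
) -> str | None:
    """Rebuild the product side from the recorded product structures.

    The rule outcome fixes the atom correspondence; the recorded products fix
    the structure (including stereocenters as recorded, which a later pass
    corrects outside the reaction center).  Each outcome product is matched to
    a distinct recorded product with the same stereo-free skeleton and the
    outcome's map numbers are copied onto the recorded molecule.
    """
    pool: list[Chem.Mol | None] = [mol_from_smiles(s) for s in recorded_products]
    pool_keys = [stripped_canonical(m) for m in pool]
    new_products = []
    for pm in outcome.product_mols:
        key = stripped_canonical(pm)
        try:
            slot = next(
                i for i, k in enumerate(pool_keys) if k == key and pool[i] is not None
            )
        except StopIteration:
            return None
        recorded = pool[slot]
        pool[slot] = None
        query = Chem.Mol(pm)
        for atom in query.GetAtoms():
            atom.SetAtomMapNum(0)
        Chem.RemoveStereochemistry(query)
        target = Chem.Mol(recorded)
        match = target.GetSubstructMatch(query, useChirality=False)
        if not match and target.GetNumAtoms() > 0:
            return None
        for qi, ti in enumerate(match):
            target.GetAtomWithIdx(ti).SetAtomMapNum(
                pm.GetAtomWithIdx(qi).GetAtomMapNum()
            )
        new_products.append(target)
    lhs = ".".join(Chem.MolToSmiles(m) for m in outcome.reactant_mols)
    rhs = ".".join(Chem.MolToSmiles(m) for m in new_products)
    return f"{lhs}>>{rhs}"


def _record_from(
    entry: RawEntry | None, r: CandidateReaction, mapped_rxn: str, rule: ReactionRule | None
) -> MappedRecord:
    unmapped = (
        ".".join(stripped_canonical(s, stereo=True) for s in r.reactant_smiles)
        + ">>"
        + ".".join(stripped_canonical(s, stereo=True) for s in r.product_smiles)
    )
    rec = MappedRecord(
        entry_id=r.entry_id,
        mapped_rxn=mapped_rxn,
        unmapped_rxn=unmapped,
        rule_id=rule.rule_id if rule else STEREO_ONLY_RULE_ID,
        rule=rule.transform if rule else "",
    )
    if entry is not None:
        rec.ec = entry.ec
        rec.natural = entry.natural
        rec.organism = entry.organism
        rec.protein_refs = entry.protein_refs
        rec.protein_db = entry.protein_db
        rec.orig_rxn_text = entry.rxn_text
        rec.reversibility = entry.reversibility
    return rec


def map_single(
    r: CandidateReaction,
    rules: Sequence[ReactionRule],
    entry: RawEntry | None = None,
) -> MappedRecord | None:
    """Map a balanced reaction via a single rule application, or ``None``.

    Success means some outcome's product multiset equals the recorded product
    multiset on stereo-stripped canonical SMILES.  Rule selection: fewest
    atoms+bonds changed, then highest applicability count, then rule id.
    """
    target = sorted(stripped_canonical(s) for s in r.product_smiles)
    hits: list[tuple[tuple, ReactionRule, MappedOutcome]] = []
    for rule in rules:
        for outcome in apply_rule(rule, list(r.reactant_smiles)):
            got = sorted(stripped_canonical(m) for m in outcome.product_mols)
            if got == target:
                sort_key = (
                    rule.n_atoms_changed + rule.n_bonds_changed,
                    -rule.applicability_count,
                    rule.rule_id,
                )
                hits.append((sort_key, rule, outcome))
    if not hits:
        return None
    hits.sort(key=lambda t: (t[0], standardize_maps(t[2].mapped_rxn)))
    _key, rule, outcome = hits[0]
    mapped = _transfer_recorded_products(outcome, list(r.product_smiles))
    if mapped is None:
        return None
    return _record_from(entry, r, mapped, rule)


def map_stereo_only(
    r: CandidateReaction, entry: RawEntry | None = None
) -> MappedRecord | None:
    """Direct mapping for reactions whose achiral sides are identical.

    Reaction rule sets rarely cover transformations that only move
    stereochemistry (racemases, cis/trans isomerases); those reactions are
    mapped by canonical atom correspondence without any rule.
    """
    r_keys = sorted(stripped_canonical(s) for s in r.reactant_smiles)
    p_keys = sorted(stripped_canonical(s) for s in r.product_smiles)
    if r_keys != p_keys:
        return None
    pool: list[Chem.Mol | None] = [mol_from_smiles(s) for s in r.product_smiles]
    pool_keys = [stripped_canonical(m) for m in pool]
    nxt = 1
    reactant_mols, product_mols = [], []
    for s in r.reactant_smiles:
        rm = mol_from_smiles(s)
        for atom in rm.GetAtoms():
            atom.SetAtomMapNum(nxt)
            nxt += 1
        key = stripped_canonical(rm)
        slot = next(
            i for i, k in enumerate(pool_keys) if k == key and pool[i] is not None
        )
        pm = pool[slot]
        pool[slot] = None
        query = Chem.Mol(rm)
        for atom in query.GetAtoms():
            atom.SetAtomMapNum(0)
        Chem.RemoveStereochemistry(query)
        target = Chem.Mol(pm)
        match = target.GetSubstructMatch(query, useChirality=False)
        if not match and target.GetNumAtoms() > 0:
            return None
        for qi, ti in enumerate(match):
            target.GetAtomWithIdx(ti).SetAtomMapNum(
                rm.GetAtomWithIdx(qi).GetAtomMapNum()
            )
        reactant_mols.append(rm)
        product_mols.append(target)
    mapped = (
        ".".join(Chem.MolToSmiles(m) for m in reactant_mols)
        + ">>"
        + ".".join(Chem.MolToSmiles(m) for m in product_mols)
    )
    return _record_from(entry, r, mapped, None)


def order_rules(
    rules: Iterable[ReactionRule], corpus: Sequence[CandidateReaction]
) -> list[ReactionRule]:
    """Order rules by frequency of applicability over the input corpus.

    A rule is applicable to a reaction when each of its reactant patterns has
    a substructure match among the reaction's reactants.  Ties (including an
    empty corpus, where all counts are zero) preserve a deterministic order:
    descending count, then rule id — except that with an empty corpus the
    original file order is kept.
    """
    rules = list(rules)
    mol_cache: dict[str, Chem.Mol] = {}

    def mol_of(s: str) -> Chem.Mol:
        if s not in mol_cache:
            mol_cache[s] = mol_from_smiles(s)
        return mol_cache[s]

    counts = Counter()
    for rule in rules:
        rxn = _compile(rule.transform)
        templates = [rxn.GetReactantTemplate(i) for i in range(rxn.GetNumReactantTemplates())]
        n = 0
        for cand in corpus:
            mols = [mol_of(s) for s in cand.reactant_smiles]
            if all(any(m.HasSubstructMatch(t) for m in mols) for t in templates):
                n += 1
        counts[rule.rule_id] = n
        rule.applicability_count = n
    if not corpus:
        return rules
    return sorted(rules, key=lambda ru: (-counts[ru.rule_id], ru.rule_id))
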