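"""Canonical renumbering of atom-mapped reaction SMILES.

Two atom mappings of the same reaction can differ in map-number values,
molecule order, atom order, and — for molecules with symmetric atoms or
repeated molecules — in which of several equivalent atoms carries which
number.  :func:`standardize_maps` collapses all of these to one byte-identical
string so mapped reactions can be compared and deduplicated directly.

The approach: renumber maps 1..N along the canonical atom order of the
(map-free) reactant molecules, enumerating the small set of equivalent
assignments (permutations of identical reactant molecules x graph
automorphisms of each molecule) and keeping the lexicographically smallest
rendered reaction string.  Molecule counts in curated enzymatic reactions are
small, so the enumeration is cheap; it is capped defensively.
"""

from __future__ import annotations

import itertools
from collections import Counter

from rdkit import Chem

from .chem import ChemError, parse_reaction_smiles

__all__ = ["standardize_maps", "check_atom_conservation"]

MAX_CANDIDATES = 2000
MAX_AUTOMORPHISMS = 8


def _map_multiset(mols) -> Counter:
    out: Counter = Counter()
    for mol in mols:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum():
                out[(atom.GetSymbol(), atom.GetAtomMapNum())] += 1
    return out


def check_atom_conservation(rxn_smiles: str) -> bool:
    """True iff (element, map-number) multisets agree across the two sides
    and every heavy atom on each side carries a unique positive map number."""
    reactants, products = parse_reaction_smiles(rxn_smiles)
    for mols in (reactants, products):
        seen = set()
        for mol in mols:
            for atom in mol.GetAtoms():
                n = atom.GetAtomMapNum()
                if n <= 0 or n in seen:
                    return False
                seen.add(n)
    return _map_multiset(reactants) == _map_multiset(products)


def _strip(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def _canonical_order(stripped: Chem.Mol) -> list[int]:
    """Atom indices in canonical SMILES output order (map-free molecule)."""
    Chem.MolToSmiles(stripped)
    order = stripped.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"]
    return list(order)


def _automorphisms(stripped: Chem.Mol) -> list[tuple[int, ...]]:
    matches = stripped.GetSubstructMatches(
        stripped, uniquify=False, useChirality=True, maxMatches=MAX_AUTOMORPHISMS
    )
    return list(matches) or [tuple(range(stripped.GetNumAtoms()))]


def _render(mols, old_to_new) -> str:
    parts = []
    for mol in mols:
        m = Chem.Mol(mol)
        for atom in m.GetAtoms():
            n = atom.GetAtomMapNum()
            atom.SetAtomMapNum(old_to_new.get(n, 0) if n else 0)
        parts.append(Chem.MolToSmiles(m))
    return ".".join(sorted(parts))


def standardize_maps(rxn_smiles: str) -> str:
    """Canonical form of an atom-mapped reaction SMILES (idempotent)."""
    if not check_atom_conservation(rxn_smiles):
        raise ChemError(f"mapping does not conserve atoms: {rxn_smiles!r}")
    reactants, products = parse_reaction_smiles(rxn_smiles)

    # sort reactant molecules by map-free canonical SMILES; identical
    # molecules form interchangeable groups
    info = []
    for mol in reactants:
        stripped = _strip(mol)
        key = Chem.MolToSmiles(stripped)
        info.append((key, mol, _canonical_order(stripped), _automorphisms(stripped)))
    info.sort(key=lambda t: t[0])

    groups: list[list[int]] = []
    for i, (key, *_rest) in enumerate(info):
        if groups and info[groups[-1][0]][0] == key:
            groups[-1].append(i)
        else:
            groups.append([i])

    group_perms = []
    for g in groups:
        if len(g) > 4:  # cap factorial blowup; order is then fixed
            group_perms.append([tuple(g)])
        else:
            group_perms.append(list(itertools.permutations(g)))

    best: str | None = None
    n_candidates = 0
    for perm_choice in itertools.product(*group_perms):
        mol_order = [i for g in perm_choice for i in g]
        auto_lists = [info[i][3] for i in mol_order]
        for autos in itertools.product(*auto_lists):
            n_candidates += 1
            if n_candidates > MAX_CANDIDATES:
                break
            old_to_new: dict[int, int] = {}
            nxt = 1
            for mi, auto in zip(mol_order, autos):
                _key, mol, order, _a = info[mi]
                for pos in order:
                    atom = mol.GetAtomWithIdx(auto[pos])
                    old = atom.GetAtomMapNum()
                    old_to_new[old] = nxt
                    nxt += 1
            rendered = (
                _render([info[i][1] for i in mol_order], old_to_new)
                + ">>"
                + _render(products, old_to_new)
            )
            if best is None or rendered < best:
                best = rendered
        if n_candidates > MAX_CANDIDATES:
            break
    assert best is not None
    return best
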