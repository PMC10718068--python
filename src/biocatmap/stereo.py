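"""Reaction centers, stereo correction, and bond-edit counting.

Name resolution often returns the wrong stereoisomer for one side of a
reaction (isomeric SMILES recorded for only one side, or a wrong database
entry).  When a chiral center *outside* the reaction center differs between
the two sides of a mapped reaction, the product parity is overwritten with
the reactant parity — the reactant entry is statistically the more reliable
one.  Stereocenters inside the reaction center are never touched: their
change may be the chemistry itself.

Bond edits (heavy-atom bonds whose presence or order changes under the
mapping) measure how chemically parsimonious a mapping is; among candidate
reactions assembled from alternative name resolutions, only those with the
minimal number of bond edits are kept.
"""

from __future__ import annotations

from rdkit import Chem

from .chem import parse_reaction_smiles
from .records import MappedRecord

__all__ = [
    "reaction_center",
    "correct_stereo",
    "count_bond_edits",
    "select_minimal_edit",
]

_CW = Chem.ChiralType.CHI_TETRAHEDRAL_CW
_CCW = Chem.ChiralType.CHI_TETRAHEDRAL_CCW


def _side_graphs(mols):
    """(bond dict keyed by map-number pair -> order, charge dict, atom index)."""
    bonds: dict[tuple[int, int], float] = {}
    charges: dict[int, int] = {}
    where: dict[int, tuple[int, int]] = {}
    for mi, mol in enumerate(mols):
        for atom in mol.GetAtoms():
            n = atom.GetAtomMapNum()
            if n:
                charges[n] = atom.GetFormalCharge()
                where[n] = (mi, atom.GetIdx())
        for bond in mol.GetBonds():
            m1 = bond.GetBeginAtom().GetAtomMapNum()
            m2 = bond.GetEndAtom().GetAtomMapNum()
            if m1 and m2:
                bonds[(min(m1, m2), max(m1, m2))] = bond.GetBondTypeAsDouble()
    return bonds, charges, where


def _diff(mapped_rxn: str):
    reactants, products = parse_reaction_smiles(mapped_rxn)
    rb, rc, rw = _side_graphs(reactants)
    pb, pc, pw = _side_graphs(products)
    changed_bonds = [k for k in set(rb) | set(pb) if rb.get(k) != pb.get(k)]
    changed_charges = [m for m in set(rc) & set(pc) if rc[m] != pc[m]]
    return reactants, products, rw, pw, changed_bonds, changed_charges


def reaction_center(m: MappedRecord | str) -> set[int]:
    """Map numbers of atoms with any changed bond or changed formal charge."""
    rxn = m if isinstance(m, str) else m.mapped_rxn
    *_heads, changed_bonds, changed_charges = _diff(rxn)
    center: set[int] = set(changed_charges)
    for a, b in changed_bonds:
        center.update((a, b))
    return center


def count_bond_edits(m: MappedRecord | str) -> tuple[int, int]:
    """(number of bond edits, number of atoms touched by at least one edit).

    An edit is one heavy-atom bond whose presence or order differs between
    the sides under the mapping; a bond-order change counts once.
    Hydrogen-count changes are not edits.  Symmetric under reversal.
    """
    rxn = m if isinstance(m, str) else m.mapped_rxn
    *_heads, changed_bonds, _charges = _diff(rxn)
    atoms = {a for pair in changed_bonds for a in pair}
    return len(changed_bonds), len(atoms)


def select_minimal_edit(cands: list[MappedRecord]) -> list[MappedRecord]:
    """Keep every record attaining the group's minimal bond-edit count."""
    if not cands:
        return []
    edits = [count_bond_edits(c)[0] for c in cands]
    best = min(edits)
    return [c for c, e in zip(cands, edits) if e == best]


def _parity(mol_h: Chem.Mol, idx: int) -> int | None:
    """Map-number-normalized tetrahedral parity (0/1) or None.

    Computed on a molecule with explicit hydrogens, so the chiral tag refers
    to the atom's full bond list.  Neighbors are keyed by map number (an
    explicit H, map 0, sorts last); the tag is adjusted by the sign of the
    permutation from bond order to key order, making parities comparable
    between any two molecules that share map numbers.
    """
    atom = mol_h.GetAtomWithIdx(idx)
    tag = atom.GetChiralTag()
    if tag not in (_CW, _CCW):
        return None
    keys = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        keys.append(nbr.GetAtomMapNum() if nbr.GetAtomicNum() > 1 else 10**9)
    if len(keys) != len(set(keys)):
        return None  # two implicit hydrogens: not a resolvable center
    order = sorted(range(len(keys)), key=keys.__getitem__)
    swaps = 0
    order = list(order)
    for i in range(len(order)):
        while order[i] != i:
            j = order[i]
            order[i], order[j] = order[j], order[i]
            swaps += 1
    parity = 0 if tag == _CW else 1
    return parity ^ (swaps & 1)


def correct_stereo(m: MappedRecord) -> MappedRecord:
    """Overwrite wrong stereocenters outside the reaction center.

    For every mapped atom not in the reaction center whose tetrahedral parity
    differs between the sides, the product parity is replaced by the reactant
    parity (cleared when the reactant is unspecified).  Connectivity, map
    numbers, and reaction-center stereo are never altered.

    Records mapped without rule application (stereo-only reactions such as
    racemizations) are returned unchanged: their stereo difference is the
    reaction itself, not an error.
    """
    from .records import STEREO_ONLY_RULE_ID

    if m.rule_id == STEREO_ONLY_RULE_ID:
        return m
    reactants, products, rw, pw, changed_bonds, changed_charges = _diff(m.mapped_rxn)
    center: set[int] = set(changed_charges)
    for a, b in changed_bonds:
        center.update((a, b))

    r_h = [Chem.AddHs(mol) for mol in reactants]
    p_h = [Chem.AddHs(mol) for mol in products]
    # AddHs preserves heavy-atom indices, so rw/pw positions stay valid
    touched = False
    for n, (pmi, pidx) in pw.items():
        if n in center or n not in rw:
            continue
        rmi, ridx = rw[n]
        want = _parity(r_h[rmi], ridx)
        have = _parity(p_h[pmi], pidx)
        if want == have:
            continue
        atom = p_h[pmi].GetAtomWithIdx(pidx)
        if want is None:
            atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
            touched = True
            continue
        if have is None:
            atom.SetChiralTag(_CW)
            have = _parity(p_h[pmi], pidx)
            touched = True
        if have != want:
            atom.SetChiralTag(_CCW if atom.GetChiralTag() == _CW else _CW)
            touched = True
    if not touched:
        return m
    new_products = [Chem.RemoveHs(mol) for mol in p_h]
    lhs = m.mapped_rxn.split(">>")[0]
    rhs = ".".join(Chem.MolToSmiles(mol) for mol in new_products)
    return m.copy(mapped_rxn=f"{lhs}>>{rhs}")
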