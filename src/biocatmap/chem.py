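"""Shared RDKit helpers: canonicalization, element counting, atom-map utilities.

All SMILES handling in the package funnels through this module so that one
standardization policy applies everywhere.  Standardization removes explicit
salt/charge artifacts via RDKit's cleanup, canonicalizes, and deliberately does
*not* canonicalize tautomers: name resolution frequently returns the tautomer
that the database entry meant, and collapsing tautomers was found to corrupt
more reactions than it fixes.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "mol_from_smiles",
    "standardize_smiles",
    "canonical_smiles",
    "strip_maps",
    "stripped_canonical",
    "element_counts",
    "side_counts",
    "multiset",
    "parse_reaction_smiles",
    "reaction_smiles",
]


class ChemError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`ChemError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparseable SMILES: {smiles!r}")
    return mol


_cleanup = rdMolStandardize.CleanupParameters()


def standardize_smiles(smiles: str) -> str:
    """Standardize and canonicalize a SMILES string.

    Applies RDKit's structure cleanup (normalization of functional-group
    drawings, metal disconnection, reionization) followed by canonical
    output.  Idempotent.  Tautomer canonicalization is intentionally omitted.
    """
    mol = mol_from_smiles(smiles)
    mol = rdMolStandardize.Cleanup(mol, _cleanup)
    if mol is None:  # pragma: no cover - Cleanup never returns None in practice
        raise ChemError(f"standardization failed for {smiles!r}")
    return Chem.MolToSmiles(mol)


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES without the standardization pass."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def strip_maps(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy of *mol* with all atom-map numbers removed."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def stripped_canonical(smiles_or_mol, stereo: bool = False) -> str:
    """Canonical SMILES with atom maps removed and (by default) stereo removed.

    The stereo-free form is the comparison key used when deciding whether a
    rule application reproduced the recorded product: stereochemistry is
    handled by a dedicated correction pass, not by the product match.
    """
    mol = (
        mol_from_smiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else Chem.Mol(smiles_or_mol)
    )
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    if not stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def element_counts(mol: Chem.Mol) -> Counter:
    """Element -> count including implicit and explicit hydrogens."""
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    counts += Counter()  # drop zero entries
    return counts


def total_charge(mol: Chem.Mol) -> int:
    return sum(a.GetFormalCharge() for a in mol.GetAtoms())


def side_counts(smiles_list: Iterable[str]) -> tuple[Counter, int]:
    """Summed element counts and total charge over one reaction side."""
    counts: Counter = Counter()
    charge = 0
    for s in smiles_list:
        mol = mol_from_smiles(s)
        counts += element_counts(mol)
        charge += total_charge(mol)
    return counts, charge


def multiset(items: Iterable[str]) -> tuple[str, ...]:
    """Order-free multiset key for a list of strings."""
    return tuple(sorted(items))


def parse_reaction_smiles(rxn_smiles: str) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
    """Split ``reactants>>products`` and parse each dot-separated molecule."""
    try:
        lhs, rhs = rxn_smiles.split(">>")
    except ValueError as exc:
        raise ChemError(f"not a reaction SMILES: {rxn_smiles!r}") from exc
    reactants = [mol_from_smiles(s) for s in lhs.split(".") if s]
    products = [mol_from_smiles(s) for s in rhs.split(".") if s]
    return reactants, products


def reaction_smiles(reactants: Iterable[Chem.Mol], products: Iterable[Chem.Mol]) -> str:
    lhs = ".".join(Chem.MolToSmiles(m) for m in reactants)
    rhs = ".".join(Chem.MolToSmiles(m) for m in products)
    return f"{lhs}>>{rhs}"
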