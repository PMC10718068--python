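"""Element-balance checking, automated correction heuristics, racemic merging.

Database reaction texts frequently omit coefficients, hydrogens, or small
co-substrates (water, O2, hydrogen peroxide, redox cofactors).  The
correction pass tries, in order of increasing intrusiveness:

1. integer re-scaling of coefficients of species already present,
2. adding hydrogen (H+ or H2) to the deficient side,
3. adding copies of one configured small corrective species.

The first change that makes the element and charge report exactly zero wins;
anything else leaves the reaction flagged unbalanced (it stays eligible for
the product-suggestion stage).  Corrections never delete a species the entry
listed — they only add species or raise coefficients, and every change is
recorded in a correction log.
"""

from __future__ import annotations

import itertools
from collections import Counter

from rdkit import Chem

from .chem import mol_from_smiles, side_counts, strip_maps
from .records import CandidateReaction, ImbalanceReport

__all__ = [
    "check_balance",
    "apply_corrections",
    "merge_racemic",
    "CORRECTIVE_SPECIES",
]

# default corrective species (canonical SMILES): proton, dihydrogen, water,
# molecular oxygen, hydrogen peroxide.  Cofactor pairs are deliberately not
# auto-added: swapping e.g. NAD+/NADH is ambiguous without mechanism
# knowledge, so ambiguous swaps are declined.
CORRECTIVE_SPECIES: tuple[str, ...] = ("[H+]", "[H][H]", "O", "O=O", "OO")

MAX_MULTIPLIER = 4


def check_balance(r: CandidateReaction) -> ImbalanceReport:
    """Product-minus-reactant element counts (implicit H included) and charge."""
    rc, rq = side_counts(r.reactant_smiles)
    pc, pq = side_counts(r.product_smiles)
    diff = Counter(pc)
    diff.subtract(rc)
    elements = tuple(sorted((el, n) for el, n in diff.items() if n != 0))
    return ImbalanceReport(elements=elements, charge=pq - rq)


def _side_key(smiles_list) -> Counter:
    return Counter(smiles_list)


def _rebuild(counter: Counter) -> tuple[str, ...]:
    return tuple(itertools.chain.from_iterable([s] * n for s, n in sorted(counter.items())))


def _try_rescale(r: CandidateReaction) -> tuple[CandidateReaction, list[str]] | None:
    """Search coefficient multipliers 1..MAX_MULTIPLIER per distinct species."""
    rcount = _side_key(r.reactant_smiles)
    pcount = _side_key(r.product_smiles)
    species = [("r", s) for s in sorted(rcount)] + [("p", s) for s in sorted(pcount)]
    if len(species) > 8:  # keep the grid search bounded
        species = species[:8]
    grids = [range(1, MAX_MULTIPLIER + 1)] * len(species)
    best = None
    for mults in itertools.product(*grids):
        n_changed = sum(m > 1 for m in mults)
        if n_changed == 0:
            continue
        if best is not None and n_changed >= best[0]:
            continue
        rc, pc = Counter(rcount), Counter(pcount)
        for (side, smi), m in zip(species, mults):
            if side == "r":
                rc[smi] = rcount[smi] * m
            else:
                pc[smi] = pcount[smi] * m
        cand = r.replace_sides(_rebuild(rc), _rebuild(pc))
        if check_balance(cand).balanced:
            log = [
                f"coefficient of {smi} on {'reactant' if side == 'r' else 'product'} "
                f"side scaled x{m}"
                for (side, smi), m in zip(species, mults)
                if m > 1
            ]
            best = (n_changed, cand, log)
    if best is None:
        return None
    return best[1], best[2]


def _try_add(r: CandidateReaction, rep: ImbalanceReport, species: str, log_name: str):
    """Add 1..MAX_MULTIPLIER copies of one species to the deficient side."""
    for side in ("r", "p"):
        for n in range(1, MAX_MULTIPLIER + 1):
            if side == "r":
                cand = r.replace_sides(r.reactant_smiles + (species,) * n, r.product_smiles)
            else:
                cand = r.replace_sides(r.reactant_smiles, r.product_smiles + (species,) * n)
            if check_balance(cand).balanced:
                side_name = "reactant" if side == "r" else "product"
                return cand, [f"added {n} x {log_name} to {side_name} side"]
    return None


def apply_corrections(
    r: CandidateReaction, rep: ImbalanceReport
) -> tuple[CandidateReaction, list[str]] | None:
    """First-exact-fix-wins correction; ``None`` means flag as unbalanced."""
    if rep.balanced:
        return r, []
    fix = _try_rescale(r)
    if fix is not None:
        return fix
    # hydrogen additions: the only corrections allowed to touch charge
    for species, name in (("[H+]", "H+"), ("[H][H]", "H2")):
        fix = _try_add(r, rep, species, name)
        if fix is not None:
            return fix
    for species in CORRECTIVE_SPECIES:
        if species in ("[H+]", "[H][H]"):
            continue
        fix = _try_add(r, rep, species, species)
        if fix is not None:
            return fix
    return None


def _enantiomer(smiles: str) -> str | None:
    """Mirror-image SMILES, or None if the molecule is achiral as drawn."""
    mol = mol_from_smiles(smiles)
    flipped = False
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            flipped = True
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
            flipped = True
    if not flipped:
        return None
    return Chem.MolToSmiles(mol)


def _merge_side(smiles_list: tuple[str, ...]) -> tuple[str, ...]:
    canon = [Chem.MolToSmiles(mol_from_smiles(s)) for s in smiles_list]
    counts = Counter(canon)
    out: Counter = Counter()
    done: set[str] = set()
    merged_any = False
    for smi in sorted(counts):
        if smi in done:
            continue
        mirror = _enantiomer(smi)
        # a meso compound is its own mirror image and is left alone
        if mirror is not None and mirror != smi and mirror in counts:
            # enantiomeric pair on one side: replace by the stereo-free
            # molecule with the pair's combined count
            mol = mol_from_smiles(smi)
            Chem.RemoveStereochemistry(mol)
            flat = Chem.MolToSmiles(strip_maps(mol))
            out[flat] += counts[smi] + counts[mirror]
            done.update({smi, mirror})
            merged_any = True
        else:
            out[smi] += counts[smi]
            done.add(smi)
    if not merged_any:
        return tuple(smiles_list)  # no pair: leave the side untouched
    return _rebuild(out)


def merge_racemic(r: CandidateReaction) -> CandidateReaction:
    """Combine enantiomeric pairs on one side into a single stereo-free species.

    Diastereomers (stereoisomers that are not mirror images) are left alone.
    Idempotent: the merged, stereo-free molecule has no enantiomer.
    """
    return r.replace_sides(
        _merge_side(r.reactant_smiles), _merge_side(r.product_smiles)
    )
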