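"""Multi-step mapping: reactions requiring more than one rule application.

Some recorded reactions condense several rule applications into one entry —
for example the oxidation of both hydroxyl groups of a diol.  This module
exhaustively enumerates sequences of up to ``max_steps`` rule applications
(same or different rule, any site) until the recorded product multiset is
reproduced.  Because the order of the individual steps is unknown, every
successful ordering is retained; each route is additionally split into
standalone single-step reactions (spectators of that step removed) flagged
``single from multi``, with symmetry duplicates dropped.

To keep the enumeration cheap on large corpora, callers restrict the rule
set to rules already used successfully within the same EC class (falling
back to the full set when the class has none yet).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from rdkit import Chem

from .chem import stripped_canonical
from .mapcanon import standardize_maps
from .mapping import _record_from, _transfer_recorded_products, MappedOutcome, apply_rule
from .records import CandidateReaction, MappedRecord, RawEntry, ReactionRule

__all__ = ["Route", "map_multi", "split_multistep"]

DEFAULT_MAX_STEPS = 2


@dataclass
class Route:
    """One successful ordering of rule applications."""

    record: MappedRecord  # overall reaction, steps="multi"
    step_rxns: list[str]  # mapped reaction SMILES per step (full state)
    step_rules: list[ReactionRule]
    entry: RawEntry | None = None


def map_multi(
    r: CandidateReaction,
    rules: Sequence[ReactionRule],
    max_steps: int = DEFAULT_MAX_STEPS,
    entry: RawEntry | None = None,
) -> list[Route]:
    """All successful orderings of <= *max_steps* rule applications.

    Deterministic and seed-free: the search is exhaustive, with memoization
    on the canonical intermediate state.  Routes are deduplicated by their
    standardized step sequences; overall records for different orderings
    that share one mapping collapse later via standardization.
    """
    target = sorted(stripped_canonical(s) for s in r.product_smiles)

    # tag the initial state once so maps persist across steps
    from .chem import mol_from_smiles

    init_mols = []
    nxt = 1
    for s in r.reactant_smiles:
        mol = mol_from_smiles(s)
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(nxt)
            nxt += 1
        init_mols.append(mol)

    routes: list[Route] = []
    seen_routes: set[tuple[str, ...]] = set()
    visited: set[tuple[int, str]] = set()

    def state_key(mols) -> str:
        return ".".join(sorted(Chem.MolToSmiles(m) for m in mols))

    def dfs(mols, depth, steps_rxn, steps_rule):
        if depth >= max_steps:
            return
        key = (depth, state_key(mols))
        if key in visited:
            return
        visited.add(key)
        for rule in rules:
            for outcome in apply_rule(rule, mols):
                step = standardize_maps(outcome.mapped_rxn)
                new_mols = outcome.product_mols
                got = sorted(stripped_canonical(m) for m in new_mols)
                new_steps_rxn = steps_rxn + [outcome.mapped_rxn]
                new_steps_rule = steps_rule + [rule]
                if got == target and len(new_steps_rxn) > 1:
                    sig = tuple(standardize_maps(s) for s in new_steps_rxn)
                    if sig not in seen_routes:
                        seen_routes.add(sig)
                        overall = MappedOutcome(
                            mapped_rxn="",
                            reactant_mols=[Chem.Mol(m) for m in init_mols],
                            product_mols=[Chem.Mol(m) for m in new_mols],
                            reacted_indices=(),
                        )
                        mapped = _transfer_recorded_products(
                            overall, list(r.product_smiles)
                        )
                        if mapped is not None:
                            rec = _record_from(entry, r, mapped, new_steps_rule[0])
                            rec.steps = "multi"
                            routes.append(
                                Route(
                                    record=rec,
                                    step_rxns=new_steps_rxn,
                                    step_rules=new_steps_rule,
                                    entry=entry,
                                )
                            )
                elif got != target:
                    dfs(new_mols, depth + 1, new_steps_rxn, new_steps_rule)

    dfs(init_mols, 0, [], [])
    routes.sort(key=lambda rt: standardize_maps(rt.record.mapped_rxn))
    return routes


def _drop_spectators(step_rxn: str) -> str:
    """Remove molecules appearing unchanged (same mapped SMILES) on both sides."""
    lhs, rhs = step_rxn.split(">>")
    left = lhs.split(".")
    right = rhs.split(".")
    left_canon = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in left]
    right_canon = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in right]
    spectators = []
    used_right: set[int] = set()
    keep_left = []
    for i, lc in enumerate(left_canon):
        hit = next(
            (j for j, rc in enumerate(right_canon) if j not in used_right and rc == lc),
            None,
        )
        if hit is not None:
            used_right.add(hit)
            spectators.append(lc)
        else:
            keep_left.append(left[i])
    keep_right = [right[j] for j in range(len(right)) if j not in used_right]
    return ".".join(keep_left) + ">>" + ".".join(keep_right)


def split_multistep(route: Route) -> list[MappedRecord]:
    """Standalone single-step records for each step of a route.

    Spectator molecules of a step are omitted; duplicates within the route
    (possible when sites are symmetric) are dropped by standardized mapped
    SMILES.
    """
    out: list[MappedRecord] = []
    seen: set[str] = set()
    for step_rxn, rule in zip(route.step_rxns, route.step_rules):
        reduced = _drop_spectators(step_rxn)
        canon = standardize_maps(reduced)
        if canon in seen:
            continue
        seen.add(canon)
        rec = route.record.copy(
            mapped_rxn=reduced,
            unmapped_rxn=_strip_rxn(reduced),
            rule_id=rule.rule_id,
            rule=rule.transform,
            steps="single from multi",
        )
        out.append(rec)
    return out


def _strip_rxn(rxn_smiles: str) -> str:
    lhs, rhs = rxn_smiles.split(">>")
    strip = lambda side: ".".join(
        stripped_canonical(s, stereo=True) for s in side.split(".")
    )
    return f"{strip(lhs)}>>{strip(rhs)}"
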