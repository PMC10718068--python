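"""Deterministic toy fixture bundle exercising every pipeline branch.

The bundle contains a small ligand dictionary, a toy rule set (alkyne
hydration, alcohol oxidation by O2 and by a quinone cofactor pair, glycoside
hydrolysis in ring-retaining and ring-opening variants), and archetype
entries covering the curation failure modes the pipeline handles:

1. a balanced reversible hydration (maps directly, gains a reverse record);
2. a two-site double oxidation with a missing stoichiometric coefficient
   (corrected, then mapped in two steps and split);
3. a wrong-product oxidation (ketone recorded as an aldehyde with an extra
   carbon: unbalanceable, corrected by product suggestion from EC classmates);
4. a wrong stereocenter outside the reaction center (reset to the reactant
   parity);
5. a name resolving to both an open and a closed ring form (the consistent
   variant wins by minimal bond edits);
6. an uncorrectable carbon imbalance (stays unbalanced);
7. a racemization with unknown reversibility (stereo-only mapping; the
   reverse is suggested because the reverse template exists in the class).

All molecules stay small enough that brute-force oracles (embedding
enumeration, graph diffs, random relabelings) run in milliseconds.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .records import RawEntry, ReactionRule, write_ligand_dict, write_rules

__all__ = ["FixtureBundle", "make_fixture_bundle"]

LIGANDS: dict[str, list[str]] = {
    "acetylene": ["C#C"],
    "H2O": ["O"],
    "acetaldehyde": ["CC=O"],
    "1,2-butanediol": ["CCC(O)CO"],
    "O2": ["O=O"],
    "H2O2": ["OO"],
    "2-oxobutanal": ["CCC(=O)C=O"],
    "propan-2-ol": ["CC(C)O"],
    "2-methylpropanal": ["CC(C)C=O"],
    "butan-2-ol": ["CCC(C)O"],
    "butan-2-one": ["CCC(C)=O"],
    "pentan-2-ol": ["CCCC(C)O"],
    "pentan-2-one": ["CCCC(C)=O"],
    "(2R,4R)-pentane-2,4-diol": ["C[C@@H](O)C[C@@H](O)C"],
    "(S)-4-hydroxypentan-2-one": ["C[C@H](O)CC(C)=O"],
    "methyl toyoside": ["COC1CCCO1"],
    # conflicting database records: open and closed hemiacetal form
    "toyose": ["OC1CCCO1", "O=CCCCO"],
    "methanol": ["CO"],
    "ethanol": ["CCO"],
    "(R)-butan-2-ol": ["CC[C@@H](C)O"],
    "(S)-butan-2-ol": ["CC[C@H](C)O"],
    "1,4-benzoquinone": ["O=C1C=CC(=O)C=C1"],
    "hydroquinone": ["Oc1ccc(O)cc1"],
}

RULES: list[tuple[str, str]] = [
    ("R01_alkyne_hydration", "[CH:1]#[CH:2].[OH2:3]>>[CH3:1][CH:2]=[O:3]"),
    (
        "R02_alcohol_oxidase",
        "[C;!$(C=O):1][OX2H1:2].[O:3]=[O:4]>>[C:1]=[O:2].[OH:3][OH:4]",
    ),
    (
        "R03_alcohol_quinone_oxidation",
        "[C;!$(C=O):1][OX2H1:2].[O:3]=[C:4]1[CH:5]=[CH:6][C:7](=[O:8])[CH:9]=[CH:10]1"
        ">>[C:1]=[O:2].[OH:3][c:4]1[cH:5][cH:6][c:7]([OH:8])[cH:9][cH:10]1",
    ),
    (
        "R04_glycoside_hydrolysis",
        "[CH3:1][O:2][CH:3]1[CH2:5][CH2:6][CH2:7][O:4]1.[OH2:8]"
        ">>[CH3:1][OH:2].[OH:8][CH:3]1[CH2:5][CH2:6][CH2:7][O:4]1",
    ),
    (
        "R05_glycoside_ring_opening_hydrolysis",
        "[CH3:1][O:2][CH:3]1[CH2:5][CH2:6][CH2:7][O:4]1.[OH2:8]"
        ">>[CH3:1][OH:2].[O:8]=[CH:3][CH2:5][CH2:6][CH2:7][OH:4]",
    ),
]

ENTRIES: list[RawEntry] = [
    RawEntry(
        entry_id="E1",
        ec="4.2.1.112",
        rxn_text="acetylene + H2O = acetaldehyde",
        reversibility="r",
        natural=True,
        organism="Pelobacter acetylenicus",
        protein_refs=("P0A01",),
        protein_db="uniprot",
    ),
    RawEntry(
        entry_id="E2",
        ec="1.1.3.41",
        rxn_text="1,2-butanediol + O2 = 2-oxobutanal + 2 H2O2",
        reversibility="ir",
        organism="Gluconobacter oxydans",
    ),
    RawEntry(
        entry_id="E3",
        ec="1.1.3.18",
        rxn_text="propan-2-ol + O2 = 2-methylpropanal + H2O2",
        reversibility="ir",
        organism="Candida boidinii",
    ),
    RawEntry(
        entry_id="E3a",
        ec="1.1.3.18",
        rxn_text="butan-2-ol + O2 = butan-2-one + H2O2",
        reversibility="ir",
        natural=True,
        organism="Candida boidinii",
    ),
    RawEntry(
        entry_id="E3b",
        ec="1.1.3.18",
        rxn_text="pentan-2-ol + O2 = pentan-2-one + H2O2",
        reversibility="ir",
        organism="Pichia pastoris",
    ),
    RawEntry(
        entry_id="E4",
        ec="1.1.3.76",
        rxn_text="(2R,4R)-pentane-2,4-diol + O2 = (S)-4-hydroxypentan-2-one + H2O2",
        reversibility="ir",
        organism="Arthrobacter sp.",
    ),
    RawEntry(
        entry_id="E5",
        ec="3.2.1.22",
        rxn_text="methyl toyoside + H2O = toyose + methanol",
        reversibility="ir",
        organism="Escherichia coli",
    ),
    RawEntry(
        entry_id="E6",
        ec="1.1.99.1",
        rxn_text="ethanol = 2-methylpropanal",
        reversibility="ir",
        organism="unknown organism",
    ),
    RawEntry(
        entry_id="E7",
        ec="5.1.99.4",
        rxn_text="(R)-butan-2-ol = (S)-butan-2-ol",
        reversibility="?",
        organism="Lactobacillus brevis",
    ),
]

# pinned expected pipeline outcome per entry: (terminal state, record count)
MANIFEST: dict[str, tuple[str, int]] = {
    "E1": ("mapped-direct", 2),  # forward + direct reversed
    "E2": ("mapped-multi", 5),  # 1 multi + 4 single from multi
    "E3": ("mapped-suggested", 1),
    "E3a": ("mapped-direct", 1),
    "E3b": ("mapped-direct", 1),
    "E4": ("mapped-direct", 1),
    "E5": ("mapped-direct", 1),  # minimal-edit variant only
    "E6": ("unbalanced", 0),
    "E7": ("mapped-direct", 2),  # forward + direct reversed_suggested
}


@dataclass
class FixtureBundle:
    ligands: dict[str, list[str]]
    rules: list[ReactionRule]
    entries: list[RawEntry]
    manifest: dict[str, tuple[str, int]] = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ligand_dict(directory / "ligands.tsv", self.ligands)
        write_rules(directory / "rules.tsv", self.rules)
        lines = ["entry_id,ec_num,rxn_text,reversibility,natural,organism,protein_refs,protein_db"]
        for e in self.entries:
            lines.append(
                ",".join(
                    [
                        e.entry_id,
                        e.ec,
                        f'"{e.rxn_text}"',
                        e.reversibility,
                        str(e.natural).lower(),
                        e.organism,
                        ";".join(e.protein_refs),
                        e.protein_db,
                    ]
                )
            )
        (directory / "entries.csv").write_text("\n".join(lines) + "\n")


def make_fixture_bundle(seed: int = 0) -> FixtureBundle:
    """Build the archetype bundle; *seed* only permutes entry order."""
    from .mapping import rule_edit_counts

    rules = [
        ReactionRule(rule_id, smarts, *rule_edit_counts(smarts))
        for rule_id, smarts in RULES
    ]
    entries = list(ENTRIES)
    random.Random(seed).shuffle(entries)
    return FixtureBundle(
        ligands={k: list(v) for k, v in LIGANDS.items()},
        rules=rules,
        entries=entries,
        manifest=dict(MANIFEST),
    )
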