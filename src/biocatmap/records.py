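"""Domain records and file IO for the curation pipeline.

The record types mirror the stages of the pipeline: a :class:`RawEntry` is one
database line (reaction text + EC number + reversibility tag + provenance), a
:class:`CandidateReaction` is one concrete unmapped reaction SMILES assembled
from resolved names, and a :class:`MappedRecord` is one exported row of the
final table (atom-mapped reaction, rule, provenance flags, quality score).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RawEntry",
    "ParsedReaction",
    "CandidateReaction",
    "ImbalanceReport",
    "ReactionRule",
    "MappedRecord",
    "RegioRow",
    "read_entries",
    "read_ligand_dict",
    "read_rules",
    "records_to_frame",
    "EXPORT_COLUMNS",
]

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")

REVERSIBILITY_SYNONYMS = {
    "r": "reversible",
    "rev": "reversible",
    "reversible": "reversible",
    "ir": "irreversible",
    "irr": "irreversible",
    "irreversible": "irreversible",
    "?": "unknown",
    "": "unknown",
    "unknown": "unknown",
}

# reserved rule id for reactions mapped without rule application (same achiral
# reactants and products, e.g. racemases and cis/trans isomerases)
STEREO_ONLY_RULE_ID = "stereo_only"


def normalize_reversibility(tag: str) -> str:
    return REVERSIBILITY_SYNONYMS.get(str(tag).strip().lower(), "unknown")


@dataclass(frozen=True)
class RawEntry:
    """One raw database line before any processing."""

    entry_id: str
    ec: str
    rxn_text: str
    reversibility: str = "unknown"
    natural: bool = False
    organism: str = ""
    protein_refs: tuple[str, ...] = ()
    protein_db: str = ""

    def __post_init__(self):
        if not EC_PATTERN.match(self.ec):
            raise ValueError(f"entry {self.entry_id}: bad EC number {self.ec!r}")
        object.__setattr__(
            self, "reversibility", normalize_reversibility(self.reversibility)
        )


@dataclass(frozen=True)
class ParsedReaction:
    """Names and stoichiometry extracted from one reaction text."""

    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    reversibility: str = "unknown"


@dataclass(frozen=True)
class CandidateReaction:
    """One unmapped reaction SMILES assembled from resolved names.

    Stoichiometric multiplicity is represented by repeated list entries, so a
    coefficient-2 species appears twice on its side.
    """

    entry_id: str
    reactant_smiles: tuple[str, ...]
    product_smiles: tuple[str, ...]
    resolution_path: tuple[tuple[str, str], ...] = ()

    def replace_sides(self, reactants, products) -> "CandidateReaction":
        return replace(
            self, reactant_smiles=tuple(reactants), product_smiles=tuple(products)
        )


@dataclass(frozen=True)
class ImbalanceReport:
    """Per-element count difference (products minus reactants) plus charge."""

    elements: tuple[tuple[str, int], ...]
    charge: int = 0

    @property
    def balanced(self) -> bool:
        return not self.elements and self.charge == 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.elements)


@dataclass
class ReactionRule:
    """A SMARTS transformation with edit statistics and a corpus frequency."""

    rule_id: str
    transform: str
    n_atoms_changed: int = 0
    n_bonds_changed: int = 0
    applicability_count: int = 0


@dataclass
class MappedRecord:
    """One exported row: atom-mapped, validated, quality-scored reaction."""

    entry_id: str
    mapped_rxn: str
    unmapped_rxn: str
    rule_id: str
    rule: str = ""
    steps: str = "single"  # single | multi | single from multi
    source: str = "direct"  # Table-1 source vocabulary
    quality: float = 1.0
    ec: str = ""
    natural: bool = False
    organism: str = ""
    protein_refs: tuple[str, ...] = ()
    protein_db: str = ""
    orig_rxn_text: str = ""
    reversibility: str = "unknown"

    def copy(self, **changes) -> "MappedRecord":
        out = replace(self)
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class RegioRow:
    """One candidate outcome for a regioselectivity group."""

    rxn_smiles: str
    label: int
    group_key: tuple[str, str]


EXPORT_COLUMNS = [
    "rxn_idx",
    "mapped",
    "unmapped",
    "orig_rxn_text",
    "rule",
    "rule_id",
    "source",
    "steps",
    "quality",
    "ec_num",
    "natural",
    "organism",
    "protein_refs",
    "protein_db",
]


def records_to_frame(records: Sequence[MappedRecord]) -> pd.DataFrame:
    """Render records as the distribution CSV table."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "rxn_idx": r.entry_id,
                "mapped": r.mapped_rxn,
                "unmapped": r.unmapped_rxn,
                "orig_rxn_text": r.orig_rxn_text,
                "rule": r.rule,
                "rule_id": r.rule_id,
                "source": r.source,
                "steps": r.steps,
                "quality": r.quality,
                "ec_num": r.ec,
                "natural": r.natural,
                "organism": r.organism,
                "protein_refs": ";".join(r.protein_refs),
                "protein_db": r.protein_db,
            }
        )
    return pd.DataFrame(rows, columns=EXPORT_COLUMNS)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str).fillna("")


def read_entries(path: str | Path) -> list[RawEntry]:
    """Read an entry table (CSV/TSV with the documented headers)."""
    df = _read_table(path)
    entries = []
    for row in df.to_dict("records"):
        entries.append(
            RawEntry(
                entry_id=row["entry_id"],
                ec=row["ec_num"],
                rxn_text=row["rxn_text"],
                reversibility=row.get("reversibility", "unknown"),
                natural=str(row.get("natural", "")).strip().lower()
                in {"1", "true", "yes"},
                organism=row.get("organism", ""),
                protein_refs=tuple(
                    p for p in str(row.get("protein_refs", "")).split(";") if p
                ),
                protein_db=row.get("protein_db", ""),
            )
        )
    return entries


def read_ligand_dict(path: str | Path) -> dict[str, list[str]]:
    """Read a ligand dictionary: ``name<TAB>smiles``, one row per structure."""
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smiles = line.split("\t")[:2]
        out.setdefault(name, [])
        if smiles not in out[name]:
            out[name].append(smiles)
    return out


def read_rules(path: str | Path) -> list[ReactionRule]:
    """Read a rule set from TSV (rule_id<TAB>smarts) or JSON."""
    from .mapping import rule_edit_counts  # deferred: avoids import cycle

    path = Path(path)
    raw: list[tuple[str, str]] = []
    if path.suffix.lower() == ".json":
        for item in json.loads(path.read_text()):
            raw.append((item["rule_id"], item["smarts"]))
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rule_id, smarts = line.split("\t")[:2]
            raw.append((rule_id, smarts))
    rules = []
    for rule_id, smarts in raw:
        n_atoms, n_bonds = rule_edit_counts(smarts)
        rules.append(
            ReactionRule(
                rule_id=rule_id,
                transform=smarts,
                n_atoms_changed=n_atoms,
                n_bonds_changed=n_bonds,
            )
        )
    return rules


def write_ligand_dict(path: str | Path, ligands: dict[str, Iterable[str]]) -> None:
    lines = [
        f"{name}\t{smi}" for name, smis in ligands.items() for smi in smis
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_rules(path: str | Path, rules: Sequence[ReactionRule]) -> None:
    lines = [f"{r.rule_id}\t{r.transform}" for r in rules]
    Path(path).write_text("\n".join(lines) + "\n")
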