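"""End-to-end orchestration: parse -> resolve -> balance -> map -> suggest ->
post-process -> export.

Every entry finishes in exactly one terminal state:

- ``mapped-direct``    mapped by one rule application (or stereo-only),
- ``mapped-multi``     mapped by several rule applications,
- ``mapped-suggested`` products proposed from EC-class statistics,
- ``unbalanced``       balance could not be restored,
- ``unmapped``         balanced but no rule reproduces the products,
- ``unresolved``       reaction text unparseable or a name without SMILES.

All stages are pure functions of their inputs: two runs on identical inputs
produce byte-identical outputs, and :func:`run_stage` re-runs any stage in
isolation from JSON state files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .balance import apply_corrections, check_balance, merge_racemic
from .ingest import (
    DictResolver,
    ParseError,
    assemble_reactions,
    parse_reaction_text,
    resolve_name,
)
from .mapcanon import check_atom_conservation
from .mapping import map_single, map_stereo_only, order_rules
from .multistep import map_multi, split_multistep
from .postprocess import add_reverse, deduplicate, standardize_records
from .records import (
    CandidateReaction,
    MappedRecord,
    RawEntry,
    ReactionRule,
    records_to_frame,
)
from .stereo import correct_stereo, select_minimal_edit
from .suggest import suggest_products
from .templates import canonical_template, extract_template, validate_roundtrip

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "run_stage", "STAGES"]

TERMINAL_STATES = (
    "mapped-direct",
    "mapped-multi",
    "mapped-suggested",
    "unbalanced",
    "unmapped",
    "unresolved",
)


@dataclass
class PipelineConfig:
    max_steps: int = 2
    combination_cap: int = 64
    suggestions_k: int = 1
    template_radius: int = 1
    include_suggested_in_quality: bool = False
    dedup_mode: str = "within-ec"


@dataclass
class RunReport:
    """Per-entry terminal states plus an auditable per-stage event log."""

    states: dict[str, str] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)

    def log(self, entry_id: str, stage: str, outcome: str, reason: str = "") -> None:
        self.events.append(
            {"entry_id": entry_id, "stage": stage, "outcome": outcome, "reason": reason}
        )

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.states.values())
        return {state: c.get(state, 0) for state in TERMINAL_STATES}


def _resolve_entries(entries, ligands, config, report):
    """Stage 1+2: text parsing and name resolution into candidates."""
    resolver_chain = [DictResolver(ligands)]
    candidates: dict[str, list[CandidateReaction]] = {}
    for entry in entries:
        try:
            parsed = parse_reaction_text(entry.rxn_text, entry.reversibility)
        except ParseError as exc:
            report.states[entry.entry_id] = "unresolved"
            report.log(entry.entry_id, "resolve", "parse-error", str(exc))
            continue
        names = {n for n, _ in parsed.substrates} | {n for n, _ in parsed.products}
        table = {name: resolve_name(name, resolver_chain) for name in names}
        missing = sorted(n for n, smis in table.items() if not smis)
        if missing:
            report.states[entry.entry_id] = "unresolved"
            report.log(entry.entry_id, "resolve", "unresolved", ",".join(missing))
            continue
        cands = assemble_reactions(
            entry.entry_id, parsed, table, cap=config.combination_cap
        )
        candidates[entry.entry_id] = cands
        report.log(entry.entry_id, "resolve", "ok", f"{len(cands)} candidate(s)")
    return candidates


def _balance_candidates(candidates, report):
    """Stage 3: racemic merging, balance checks, correction heuristics."""
    balanced: dict[str, list[CandidateReaction]] = defaultdict(list)
    for entry_id, cands in candidates.items():
        for cand in cands:
            cand = merge_racemic(cand)
            rep = check_balance(cand)
            if rep.balanced:
                balanced[entry_id].append(cand)
                continue
            fix = apply_corrections(cand, rep)
            if fix is None:
                report.log(
                    entry_id, "balance", "unbalanced", json.dumps(rep.as_dict())
                )
                continue
            fixed, log = fix
            report.log(entry_id, "balance", "corrected", "; ".join(log))
            balanced[entry_id].append(fixed)
        if entry_id not in balanced:
            report.states[entry_id] = "unbalanced"
    return balanced


def _map_direct(entries_by_id, balanced, rules, config, report):
    """Stage 4A: stereo-only and single-rule mapping, minimal-edit pruning."""
    records: dict[str, list[MappedRecord]] = defaultdict(list)
    ec_rules: dict[str, set[str]] = defaultdict(set)
    for entry_id in sorted(balanced):
        entry = entries_by_id[entry_id]
        mapped = []
        for cand in balanced[entry_id]:
            rec = map_stereo_only(cand, entry)
            if rec is None:
                rec = map_single(cand, rules, entry)
            if rec is not None:
                mapped.append(rec)
        mapped = select_minimal_edit(mapped)
        kept = []
        for rec in mapped:
            rec = correct_stereo(rec)
            if not check_atom_conservation(rec.mapped_rxn):
                report.log(entry_id, "map", "dropped", "atom conservation failed")
                continue
            if not validate_roundtrip(rec, radius=config.template_radius):
                report.log(entry_id, "map", "dropped", "round trip failed")
                continue
            kept.append(rec)
        if kept:
            records[entry_id] = kept
            report.states[entry_id] = "mapped-direct"
            report.log(entry_id, "map", "mapped-direct", f"{len(kept)} record(s)")
            for rec in kept:
                ec_rules[entry.ec].add(rec.rule_id)
    return records, ec_rules


def _map_multistep(entries_by_id, balanced, rules, ec_rules, config, report):
    """Stage 4B: multi-step mapping and splitting for still-unmapped entries."""
    from .mapcanon import standardize_maps

    records: dict[str, list[MappedRecord]] = defaultdict(list)
    rules_by_id = {r.rule_id: r for r in rules}
    for entry_id in sorted(balanced):
        if entry_id in report.states:
            continue
        entry = entries_by_id[entry_id]
        subset_ids = ec_rules.get(entry.ec)
        subset = (
            [rules_by_id[i] for i in sorted(subset_ids) if i in rules_by_id]
            if subset_ids
            else list(rules)
        )
        overall: dict[str, MappedRecord] = {}
        splits: dict[str, MappedRecord] = {}
        for cand in balanced[entry_id]:
            for route in map_multi(cand, subset, max_steps=config.max_steps, entry=entry):
                rec = correct_stereo(route.record)
                if not check_atom_conservation(rec.mapped_rxn):
                    continue
                if not validate_roundtrip(rec, radius=config.template_radius):
                    continue
                overall[standardize_maps(rec.mapped_rxn)] = rec
                for srec in split_multistep(route):
                    srec = correct_stereo(srec)
                    if not check_atom_conservation(srec.mapped_rxn):
                        continue
                    if not validate_roundtrip(srec, radius=config.template_radius):
                        continue
                    splits[standardize_maps(srec.mapped_rxn)] = srec
        if overall:
            kept = [overall[k] for k in sorted(overall)] + [
                splits[k] for k in sorted(splits)
            ]
            records[entry_id] = kept
            report.states[entry_id] = "mapped-multi"
            report.log(
                entry_id,
                "map-multi",
                "mapped-multi",
                f"{len(overall)} route mapping(s), {len(splits)} split record(s)",
            )
            for rec in records[entry_id]:
                ec_rules[entry.ec].add(rec.rule_id)
    return records


def _suggest(entries_by_id, candidates, balanced, direct_records, rules, config, report):
    """Stage 5: product suggestion for unbalanced/unmapped entries."""
    by_ec: dict[str, list[MappedRecord]] = defaultdict(list)
    for recs in direct_records.values():
        for rec in recs:
            by_ec[rec.ec].append(rec)
    records: dict[str, list[MappedRecord]] = {}
    for entry_id in sorted(candidates):
        state = report.states.get(entry_id)
        if state not in (None, "unbalanced"):
            continue
        entry = entries_by_id[entry_id]
        # prefer balanced candidates; fall back to the raw assembly for
        # unbalanced entries (their reactant side is still usable)
        pool = balanced.get(entry_id) or candidates[entry_id]
        suggestions: list[MappedRecord] = []
        for cand in pool:
            suggestions = suggest_products(
                cand,
                by_ec.get(entry.ec, []),
                rules,
                entry=entry,
                k=config.suggestions_k,
            )
            if suggestions:
                break
        if suggestions:
            records[entry_id] = suggestions
            report.states[entry_id] = "mapped-suggested"
            report.log(
                entry_id, "suggest", "mapped-suggested", f"{len(suggestions)} record(s)"
            )
        elif state is None:
            report.states[entry_id] = "unmapped"
            report.log(entry_id, "suggest", "unmapped", "no rule reproduces products")
    return records


def _postprocess(direct, multi, suggested, config, report):
    """Stage 6: standardize, reverse, quality, dedup."""
    base: list[MappedRecord] = []
    for group in (direct, multi):
        for entry_id in sorted(group):
            base.extend(group[entry_id])
    sugg: list[MappedRecord] = []
    for entry_id in sorted(suggested):
        sugg.extend(suggested[entry_id])

    base = standardize_records(base)
    sugg = standardize_records(sugg)

    class_templates: dict[str, set[str]] = defaultdict(set)
    for rec in base + sugg:
        class_templates[rec.ec].add(
            canonical_template(extract_template(rec, radius=config.template_radius))
        )
    base = add_reverse(base, class_templates)
    sugg = add_reverse(sugg, class_templates)

    # quality: rule frequencies within an EC class, computed on the
    # direct/split/reversed family (suggested records optionally included),
    # then written onto every record of the class
    freq_pool = base + sugg if config.include_suggested_in_quality else base
    group_rule_counts: dict[str, Counter] = defaultdict(Counter)
    group_sizes: Counter = Counter()
    for rec in freq_pool:
        group_rule_counts[rec.ec][rec.rule_id] += 1
        group_sizes[rec.ec] += 1
    out = []
    for rec in base + sugg:
        size = group_sizes.get(rec.ec, 0)
        count = group_rule_counts[rec.ec].get(rec.rule_id, 0)
        quality = count / size if size and count else 1.0
        out.append(rec.copy(quality=quality))

    return deduplicate(out, key_mode=config.dedup_mode)


def run_pipeline(
    entries: Sequence[RawEntry],
    ligands: dict[str, list[str]],
    rules: Sequence[ReactionRule],
    config: PipelineConfig | None = None,
) -> tuple[list[MappedRecord], RunReport]:
    """Run every stage; returns the final records and the run report."""
    config = config or PipelineConfig()
    report = RunReport()
    entries_by_id = {e.entry_id: e for e in entries}

    candidates = _resolve_entries(entries, ligands, config, report)
    balanced = _balance_candidates(candidates, report)
    corpus = [c for cands in balanced.values() for c in cands]
    ordered_rules = order_rules(list(rules), corpus)
    direct, ec_rules = _map_direct(entries_by_id, balanced, ordered_rules, config, report)
    multi = _map_multistep(entries_by_id, balanced, ordered_rules, ec_rules, config, report)
    direct_and_multi = {**direct, **multi}
    suggested = _suggest(
        entries_by_id, candidates, balanced, direct_and_multi, ordered_rules, config, report
    )
    records = _postprocess(direct, multi, suggested, config, report)
    for entry in entries:
        report.states.setdefault(entry.entry_id, "unresolved")
    return records, report


# ---------------------------------------------------------------------------
# stage-wise execution with on-disk state

STAGES = ("resolve", "balance", "map", "suggest", "postprocess", "export")


def _dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_encode) + "\n")


def _encode(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"cannot encode {type(obj)}")


def _load_records(raw) -> dict[str, list[MappedRecord]]:
    out: dict[str, list[MappedRecord]] = {}
    for entry_id, recs in raw.items():
        out[entry_id] = []
        for d in recs:
            d = dict(d)
            d["protein_refs"] = tuple(d.get("protein_refs", ()))
            out[entry_id].append(MappedRecord(**d))
    return out


def _load_candidates(raw) -> dict[str, list[CandidateReaction]]:
    out: dict[str, list[CandidateReaction]] = {}
    for entry_id, cands in raw.items():
        out[entry_id] = [
            CandidateReaction(
                entry_id=c["entry_id"],
                reactant_smiles=tuple(c["reactant_smiles"]),
                product_smiles=tuple(c["product_smiles"]),
                resolution_path=tuple(map(tuple, c["resolution_path"])),
            )
            for c in cands
        ]
    return out


def run_stage(
    stage: str,
    state_dir: str | Path,
    entries: Sequence[RawEntry] | None = None,
    ligands: dict[str, list[str]] | None = None,
    rules: Sequence[ReactionRule] | None = None,
    config: PipelineConfig | None = None,
) -> Path:
    """Run one pipeline stage against a JSON state directory.

    Each stage reads the outputs of the previous one and writes its own,
    so any stage can be rerun in isolation; rerunning a completed stage
    rewrites identical bytes.  Raises ``FileNotFoundError`` naming the
    missing upstream stage.
    """
    state_dir = Path(state_dir)
    state_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    report = RunReport()

    def need(name: str, produced_by: str) -> dict:
        path = state_dir / name
        if not path.exists():
            raise FileNotFoundError(
                f"state file {name} missing: run stage {produced_by!r} first"
            )
        return json.loads(path.read_text())

    if stage == "resolve":
        if entries is None or ligands is None:
            raise ValueError("resolve stage needs entries and ligands")
        candidates = _resolve_entries(entries, ligands, config, report)
        _dump(state_dir / "candidates.json", candidates)
        _dump(state_dir / "resolve_report.json", report)
        return state_dir / "candidates.json"
    if stage == "balance":
        candidates = _load_candidates(need("candidates.json", "resolve"))
        balanced = _balance_candidates(candidates, report)
        _dump(state_dir / "balanced.json", balanced)
        _dump(state_dir / "balance_report.json", report)
        return state_dir / "balanced.json"
    if stage == "map":
        if entries is None or rules is None:
            raise ValueError("map stage needs entries and rules")
        entries_by_id = {e.entry_id: e for e in entries}
        balanced = _load_candidates(need("balanced.json", "balance"))
        corpus = [c for cands in balanced.values() for c in cands]
        ordered = order_rules(list(rules), corpus)
        direct, ec_rules = _map_direct(entries_by_id, balanced, ordered, config, report)
        multi = _map_multistep(entries_by_id, balanced, ordered, ec_rules, config, report)
        _dump(state_dir / "direct.json", direct)
        _dump(state_dir / "multi.json", multi)
        _dump(state_dir / "map_report.json", report)
        return state_dir / "direct.json"
    if stage == "suggest":
        if entries is None or rules is None:
            raise ValueError("suggest stage needs entries and rules")
        entries_by_id = {e.entry_id: e for e in entries}
        candidates = _load_candidates(need("candidates.json", "resolve"))
        balanced = _load_candidates(need("balanced.json", "balance"))
        direct = _load_records(need("direct.json", "map"))
        multi = _load_records(need("multi.json", "map"))
        prior = json.loads((state_dir / "map_report.json").read_text())
        report.states.update(prior["states"])
        for entry_id, cands in balanced.items():
            if not cands:
                report.states.setdefault(entry_id, "unbalanced")
        for entry_id in candidates:
            if entry_id not in balanced:
                report.states.setdefault(entry_id, "unbalanced")
        ordered = order_rules(
            list(rules), [c for cands in balanced.values() for c in cands]
        )
        suggested = _suggest(
            entries_by_id, candidates, balanced, {**direct, **multi}, ordered, config, report
        )
        _dump(state_dir / "suggested.json", suggested)
        _dump(state_dir / "suggest_report.json", report)
        return state_dir / "suggested.json"
    if stage == "postprocess":
        direct = _load_records(need("direct.json", "map"))
        multi = _load_records(need("multi.json", "map"))
        suggested = _load_records(need("suggested.json", "suggest"))
        records = _postprocess(direct, multi, suggested, config, report)
        _dump(state_dir / "records.json", {"records": records})
        return state_dir / "records.json"
    if stage == "export":
        raw = need("records.json", "postprocess")
        records = _load_records({"all": raw["records"]})["all"]
        frame = records_to_frame(records)
        out = state_dir / "records.csv"
        frame.to_csv(out, index=False)
        return out
    raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
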