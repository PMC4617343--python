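"""Gene-level comparison of memory conditioning types.

Significant transcript calls are pooled over time points per
conditioning type and summarised per gene. A gene differentially
expressed (DE) in a long-term-memory (LTM) conditioning type is kept as
an LTM candidate when, relative to the anesthesia-resistant-memory
(ARM) control type, it

1. has no DE transcript in ARM at all (``absent_in_arm``); or
2. has every transcript DE in both the LTM type and ARM changed in
   opposite directions (``opposing``); or
3. has entirely different splice variants DE in the LTM type than in
   ARM (``splice_variant`` — the two DE transcript sets are disjoint).

Retention is the disjunction of the three rules; the recorded rule
follows the precedence 1 > 2 > 3 and affects reporting only. Rule 2
requires at least one shared DE transcript — genes whose DE variant
sets are disjoint fall to rule 3. Splice-variant discrimination
(rule 3) is only meaningful within one species' assembly, so it can be
restricted to the conditioning types sharing a species with ARM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .de import DECall


class CompareError(ValueError):
    pass


@dataclass
class GeneDESummary:
    """Per-gene pooled DE evidence: for each conditioning type, the
    significant (transcript, direction) pairs with the contributing
    time points."""

    gene_id: str
    # conditioning_type -> {(transcript_id, direction): set of time points}
    by_type: dict[str, dict[tuple[str, str], set[str]]] = field(default_factory=dict)

    def de_types(self) -> set[str]:
        return {t for t, entries in self.by_type.items() if entries}

    def transcripts(self, conditioning_type: str) -> set[str]:
        return {tx for tx, _ in self.by_type.get(conditioning_type, {})}

    def directions(self, conditioning_type: str, transcript_id: str) -> set[str]:
        return {
            d
            for (tx, d) in self.by_type.get(conditioning_type, {})
            if tx == transcript_id
        }


@dataclass
class LTMCandidate:
    gene_id: str
    retained_for: set[str]
    rule: str                      # absent_in_arm | opposing | splice_variant
    evidence: dict[str, dict[tuple[str, str], set[str]]]


@dataclass
class VennTable:
    """Counts of every region of the inclusion-exclusion partition of a
    family of sets; region keys are frozensets of member labels."""

    labels: list[str]
    regions: dict[frozenset[str], int]

    def count(self, *labels: str) -> int:
        return self.regions.get(frozenset(labels), 0)

    def total(self) -> int:
        return sum(self.regions.values())


def summarize_gene_de(
    calls: Iterable[DECall], gene_map: Mapping[str, str]
) -> list[GeneDESummary]:
    """Pool significant calls over time points, per gene and
    conditioning type. Only significant calls contribute; a transcript
    significant in both directions at different time points keeps both
    direction entries."""
    summaries: dict[str, GeneDESummary] = {}
    for call in calls:
        if not call.significant:
            continue
        if call.transcript_id not in gene_map:
            raise CompareError(
                f"transcript {call.transcript_id!r} has no gene mapping"
            )
        gene = gene_map[call.transcript_id]
        summ = summaries.setdefault(gene, GeneDESummary(gene_id=gene))
        entries = summ.by_type.setdefault(call.conditioning_type, {})
        entries.setdefault((call.transcript_id, call.direction), set()).add(
            call.time_point
        )
    return [summaries[g] for g in sorted(summaries)]


def detect_opposing(summary: GeneDESummary, type_a: str, type_b: str) -> bool:
    """True when the gene is DE in both types and every transcript DE in
    both has strictly opposite directions (at least one such shared
    transcript must exist)."""
    tx_a = summary.transcripts(type_a)
    tx_b = summary.transcripts(type_b)
    if not tx_a or not tx_b:
        return False
    shared = tx_a & tx_b
    if not shared:
        return False
    for tx in shared:
        da = summary.directions(type_a, tx)
        db = summary.directions(type_b, tx)
        if da & db:               # same direction somewhere
            return False
        if len(da) > 1 or len(db) > 1:
            # both directions within one type blocks the opposing rule
            return False
    return True


def apply_ltm_filter(
    summaries: Sequence[GeneDESummary],
    ltm_types: Iterable[str],
    arm_type: str,
    splice_aware_types: Iterable[str] | None = None,
) -> list[LTMCandidate]:
    """Retain genes that distinguish LTM from ARM conditioning.

    A gene DE in an LTM type is retained for that type if any of the
    three rules holds; ``splice_aware_types`` limits rule 3 to the LTM
    types whose splice variants are comparable with ARM's (default:
    all). Each retained gene carries the single highest-precedence rule
    that fired for any of its retained types, plus the supporting
    ARM/LTM evidence.
    """
    ltm_types = list(ltm_types)
    splice_ok = set(ltm_types if splice_aware_types is None else splice_aware_types)
    candidates: list[LTMCandidate] = []
    for summ in summaries:
        retained: dict[str, str] = {}
        arm_tx = summ.transcripts(arm_type)
        for lt in ltm_types:
            ltm_tx = summ.transcripts(lt)
            if not ltm_tx:
                continue
            if not arm_tx:
                retained[lt] = "absent_in_arm"
            elif detect_opposing(summ, lt, arm_type):
                retained[lt] = "opposing"
            elif lt in splice_ok and not (ltm_tx & arm_tx):
                retained[lt] = "splice_variant"
        if retained:
            precedence = {"absent_in_arm": 0, "opposing": 1, "splice_variant": 2}
            rule = min(retained.values(), key=precedence.__getitem__)
            evidence = {
                t: {k: set(v) for k, v in summ.by_type.get(t, {}).items()}
                for t in sorted(set(retained) | {arm_type})
            }
            candidates.append(
                LTMCandidate(
                    gene_id=summ.gene_id,
                    retained_for=set(retained),
                    rule=rule,
                    evidence=evidence,
                )
            )
    return candidates


def project_orthologs(
    gene_sets: Mapping[str, set[str]], ortholog_map: Mapping[str, str]
) -> dict[str, set[str]]:
    """Replace gene ids by ortholog-group ids where mapped; unmapped
    genes keep their own id (counted as species-unique)."""
    return {
        label: {ortholog_map.get(g, g) for g in genes}
        for label, genes in gene_sets.items()
    }


def compute_overlaps(
    gene_sets: Mapping[str, Iterable[str]],
    ortholog_map: Mapping[str, str] | None = None,
) -> VennTable:
    """Inclusion-exclusion region counts over labelled gene sets,
    optionally after projecting genes through an ortholog map (both
    members of an ortholog pair project to the group id)."""
    sets = {label: set(v) for label, v in gene_sets.items()}
    if ortholog_map is not None:
        sets = project_orthologs(sets, ortholog_map)
    labels = list(sets)
    regions: dict[frozenset[str], int] = {}
    for flags in product([False, True], repeat=len(labels)):
        inside = [l for l, f in zip(labels, flags) if f]
        if not inside:
            continue
        outside = [l for l, f in zip(labels, flags) if not f]
        members = set.intersection(*(sets[l] for l in inside))
        for l in outside:
            members -= sets[l]
        regions[frozenset(inside)] = len(members)
    return VennTable(labels=labels, regions=regions)


def venn_to_dataframe(venn: VennTable) -> pd.DataFrame:
    rows = [
        {"region": "&".join(sorted(k)), "count": v}
        for k, v in sorted(venn.regions.items(), key=lambda kv: sorted(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "count"])


def candidates_to_dataframe(candidates: Sequence[LTMCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        ev = []
        for ctype in sorted(c.evidence):
            for (tx, d) in sorted(c.evidence[ctype]):
                tps = ",".join(sorted(c.evidence[ctype][(tx, d)]))
                ev.append(f"{ctype}:{tx}:{d}:{tps}")
        rows.append(
            {
                "gene_id": c.gene_id,
                "retained_for": ",".join(sorted(c.retained_for)),
                "rule": c.rule,
                "evidence": ";".join(ev),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "retained_for", "rule", "evidence"])
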