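"""Strand-aware structural annotation of a de novo transcriptome.

Transcripts are classified by a sequential sieve over orientation-aware
alignment evidence:

1. **sense** — any sense-orientation protein hit (reference proteome or
   nr) covering more than 60% of the protein;
2. **antisense** — any antisense-orientation protein hit covering more
   than 50% of the protein (*antisense-to-protein*), and/or any
   antisense-orientation hit to an established sense transcript of the
   same transcriptome covering more than 80% of the query at more than
   95% identity (*antisense-to-sense*; both flags may be set);
3. **lncRNA** — otherwise, a genome or nt hit covering more than 80% of
   the query at more than 95% identity;
4. **unknown** — no qualifying evidence.

All threshold comparisons are strict ("more than"). Antisense-to-sense
transcripts whose sense partner is covered by a protein hit over more
than 90% of the protein are additionally assigned to the 5'UTR / CDS /
3'UTR zones of the partner that their alignment interval intersects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

PROTEIN_DBS = frozenset({"proteome", "nr"})
NUCLEOTIDE_DBS = frozenset({"genome", "nt"})
SELF_DB = "self_transcriptome"
ZONES = ("five_prime_utr", "cds", "three_prime_utr")

HITS_COLUMNS = [
    "query_id",
    "subject_id",
    "subject_db",
    "orientation",
    "identity",
    "query_cov",
    "subject_cov",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
]


class AnnotationError(ValueError):
    """Raised on malformed alignment input."""


@dataclass(frozen=True)
class AlignmentHit:
    """One orientation-aware local alignment between a transcript (query)
    and a protein / transcript / genome subject.

    ``subject_cov`` is the fraction of the subject covered (the "protein
    alignment length" for protein subjects); ``query_cov`` the fraction
    of the query covered. Intervals are 0-based half-open; for
    self-transcriptome subjects the subject interval is the projection
    of the alignment onto the sense partner's coordinates.
    """

    query_id: str
    subject_id: str
    subject_db: str
    orientation: str
    identity: float
    query_cov: float
    subject_cov: float
    q_start: int = 0
    q_end: int = 1
    s_start: int = 0
    s_end: int = 1

    def __post_init__(self):
        for name in ("identity", "query_cov", "subject_cov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(f"{name}={v!r} outside [0,1] for {self.query_id}")
        if self.q_start >= self.q_end or self.s_start >= self.s_end:
            raise AnnotationError(f"empty alignment interval for {self.query_id}")
        if self.orientation not in ("sense", "antisense"):
            raise AnnotationError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class AnnotationThresholds:
    """Classification cut-offs; every comparison against them is strict."""

    sense_protein_cov: float = 0.60
    antisense_protein_cov: float = 0.50
    antisense_sense_query_cov: float = 0.80
    antisense_sense_identity: float = 0.95
    lnc_cov: float = 0.80
    lnc_identity: float = 0.95
    zone_protein_cov: float = 0.90
    orf_min_aa: int = 30
    translate_min_aa: int = 60

    def __post_init__(self):
        for name in (
            "sense_protein_cov",
            "antisense_protein_cov",
            "antisense_sense_query_cov",
            "antisense_sense_identity",
            "lnc_cov",
            "lnc_identity",
            "zone_protein_cov",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise AnnotationError(f"{name} must lie in (0,1]")
        if self.orf_min_aa < 1:
            raise AnnotationError("orf_min_aa must be >= 1")


@dataclass
class TranscriptAnnotation:
    transcript_id: str
    gene_id: str = ""
    structural_class: str = "unknown"
    antisense_to_protein: bool = False
    antisense_to_sense: bool = False
    sense_partners: list[str] = field(default_factory=list)
    has_putative_orf: bool = False
    zone_set: frozenset[str] = frozenset()


def classify_transcript(
    hits: Sequence[AlignmentHit],
    thresholds: AnnotationThresholds = AnnotationThresholds(),
    sense_set: frozenset[str] | set[str] = frozenset(),
) -> TranscriptAnnotation:
    """Classify one transcript from its alignment hits.

    ``sense_set`` is the set of transcripts already established as sense
    (the antisense-to-sense rule is evaluated against it). Returns class
    and antisense flags only; zone assignment is a separate step.
    """
    qids = {h.query_id for h in hits}
    if len(qids) > 1:
        raise AnnotationError(f"hits span multiple query ids: {sorted(qids)}")
    tid = next(iter(qids)) if qids else ""
    ann = TranscriptAnnotation(transcript_id=tid)

    t = thresholds
    if any(
        h.orientation == "sense"
        and h.subject_db in PROTEIN_DBS
        and h.subject_cov > t.sense_protein_cov
        for h in hits
    ):
        ann.structural_class = "sense"
        return ann

    partners = sorted(
        {
            h.subject_id
            for h in hits
            if h.orientation == "antisense"
            and h.subject_db == SELF_DB
            and h.subject_id in sense_set
            and h.query_cov > t.antisense_sense_query_cov
            and h.identity > t.antisense_sense_identity
        }
    )
    a2p = any(
        h.orientation == "antisense"
        and h.subject_db in PROTEIN_DBS
        and h.subject_cov > t.antisense_protein_cov
        for h in hits
    )
    if a2p or partners:
        ann.structural_class = "antisense"
        ann.antisense_to_protein = a2p
        ann.antisense_to_sense = bool(partners)
        ann.sense_partners = partners
        return ann

    for db in ("genome", "nt"):
        if any(
            h.subject_db == db
            and h.query_cov > t.lnc_cov
            and h.identity > t.lnc_identity
            for h in hits
        ):
            ann.structural_class = "lncRNA"
            return ann
    return ann


def hits_to_dataframe(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits], columns=HITS_COLUMNS)


def dataframe_to_hits(df: pd.DataFrame) -> list[AlignmentHit]:
    missing = [c for c in HITS_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"hits table missing columns: {missing}")
    return [
        AlignmentHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            subject_db=str(r.subject_db),
            orientation=str(r.orientation),
            identity=float(r.identity),
            query_cov=float(r.query_cov),
            subject_cov=float(r.subject_cov),
            q_start=int(r.q_start),
            q_end=int(r.q_end),
            s_start=int(r.s_start),
            s_end=int(r.s_end),
        )
        for r in df.itertuples(index=False)
    ]


def annotate_transcriptome(
    hits: Sequence[AlignmentHit] | pd.DataFrame,
    gene_map: Mapping[str, str],
    thresholds: AnnotationThresholds = AnnotationThresholds(),
    transcript_lengths: Mapping[str, int] | None = None,
    sequences: Mapping[str, str] | None = None,
) -> list[TranscriptAnnotation]:
    """Two-pass annotation of a whole transcriptome.

    Pass 1 fixes the sense set from protein evidence alone; pass 2
    classifies every transcript against that frozen sense set, so
    antisense-to-sense assignment does not depend on processing order.
    Every transcript in ``gene_map`` receives exactly one annotation
    (transcripts without hits are ``unknown``).

    Zone sets are filled when ``transcript_lengths`` covers the sense
    partners; ``sequences`` (sense-strand nucleotides) enables the
    putative-ORF flag for lncRNA/unknown transcripts.
    """
    if isinstance(hits, pd.DataFrame):
        hits = dataframe_to_hits(hits)
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.query_id not in gene_map:
            raise AnnotationError(
                f"transcript {h.query_id!r} in hits but absent from gene map"
            )
        by_query.setdefault(h.query_id, []).append(h)

    t = thresholds
    sense_set = frozenset(
        tid
        for tid, hh in by_query.items()
        if any(
            h.orientation == "sense"
            and h.subject_db in PROTEIN_DBS
            and h.subject_cov > t.sense_protein_cov
            for h in hh
        )
    )

    annotations = []
    for tid in gene_map:
        hh = by_query.get(tid, [])
        ann = classify_transcript(hh, t, sense_set) if hh else TranscriptAnnotation(tid)
        ann.transcript_id = tid
        ann.gene_id = gene_map[tid]
        if ann.antisense_to_sense:
            ann.zone_set = _zones_for_antisense(
                hh, ann.sense_partners, by_query, t, transcript_lengths
            )
        if sequences is not None and ann.structural_class in ("lncRNA", "unknown"):
            seq = sequences.get(tid)
            if seq:
                ann.has_putative_orf = bool(find_orfs(seq, t.orf_min_aa))
        annotations.append(ann)
    return annotations


def _best_protein_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    prot = [
        h
        for h in hits
        if h.orientation == "sense" and h.subject_db in PROTEIN_DBS
    ]
    return max(prot, key=lambda h: h.subject_cov) if prot else None


def _zones_for_antisense(
    hits: Sequence[AlignmentHit],
    partners: Sequence[str],
    by_query: Mapping[str, Sequence[AlignmentHit]],
    t: AnnotationThresholds,
    transcript_lengths: Mapping[str, int] | None,
) -> frozenset[str]:
    """Union of zones over eligible sense partners.

    A partner is eligible when its best sense protein hit covers more
    than ``zone_protein_cov`` of the protein; its CDS on the transcript
    is taken as that hit's query interval, the UTRs as the flanks."""
    if transcript_lengths is None:
        return frozenset()
    zones: set[str] = set()
    for h in hits:
        if (
            h.orientation != "antisense"
            or h.subject_db != SELF_DB
            or h.subject_id not in partners
        ):
            continue
        partner_hits = by_query.get(h.subject_id, [])
        best = _best_protein_hit(partner_hits)
        if best is None or best.subject_cov <= t.zone_protein_cov:
            continue
        length = transcript_lengths.get(h.subject_id)
        if length is None:
            continue
        zones |= classify_antisense_zones(
            (h.s_start, h.s_end), (best.q_start, best.q_end), length
        )
    return frozenset(zones)


def classify_antisense_zones(
    antisense_interval: tuple[int, int],
    cds_interval: tuple[int, int],
    transcript_length: int,
) -> frozenset[str]:
    """Zones of a sense transcript intersected by a projected antisense
    alignment interval. Coordinates are 0-based half-open on the sense
    transcript: 5'UTR = [0, cds_start), CDS = [cds_start, cds_end),
    3'UTR = [cds_end, length)."""
    a0, a1 = antisense_interval
    c0, c1 = cds_interval
    if not (0 <= c0 < c1 <= transcript_length):
        raise AnnotationError(f"invalid CDS interval {cds_interval!r}")
    if not (0 <= a0 < a1 <= transcript_length):
        raise AnnotationError(f"invalid antisense interval {antisense_interval!r}")
    bounds = {
        "five_prime_utr": (0, c0),
        "cds": (c0, c1),
        "three_prime_utr": (c1, transcript_length),
    }
    return frozenset(
        z for z, (z0, z1) in bounds.items() if max(a0, z0) < min(a1, z1)
    )


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(sequence: str, min_aa: int = 30) -> list[tuple[int, tuple[int, int], int]]:
    """Maximal start-to-stop open reading frames on the given strand.

    Scans the three forward frames for ATG...stop spans with at least
    ``min_aa`` codons between start and stop (the start codon counts as
    the first amino acid; the comparison is inclusive). Per frame, a new
    ORF may start only after the previous stop, which yields the maximal
    non-nested set. Returns (frame, (start, end), length_aa) with the
    interval covering the stop codon, 0-based half-open.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise AnnotationError("sequence contains non-nucleotide characters")
    orfs = []
    n = len(seq)
    for frame in range(3):
        pos = frame
        start = None
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                length_aa = (pos - start) // 3
                if length_aa >= min_aa:
                    orfs.append((frame, (start, pos + 3), length_aa))
                start = None
            pos += 3
    return orfs


def annotations_to_dataframe(annotations: Iterable[TranscriptAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "transcript_id": a.transcript_id,
                "gene_id": a.gene_id,
                "structural_class": a.structural_class,
                "antisense_to_protein": a.antisense_to_protein,
                "antisense_to_sense": a.antisense_to_sense,
                "sense_partners": ",".join(a.sense_partners),
                "has_putative_orf": a.has_putative_orf,
                "zone_set": ",".join(z for z in ZONES if z in a.zone_set),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "structural_class",
            "antisense_to_protein",
            "antisense_to_sense",
            "sense_partners",
            "has_putative_orf",
            "zone_set",
        ],
    )
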