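"""Structural annotation: the sequential sieve, strict thresholds, ORF
scanning and UTR-zone assignment, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memorydiff as md
from memorydiff.annotate import (
    AlignmentHit,
    AnnotationError,
    AnnotationThresholds,
    annotate_transcriptome,
    classify_antisense_zones,
    classify_transcript,
    find_orfs,
)

T = AnnotationThresholds()


def hit(q="t1", s="p1", db="proteome", ori="sense", ident=0.9, qcov=0.5, scov=0.7):
    return AlignmentHit(
        query_id=q,
        subject_id=s,
        subject_db=db,
        orientation=ori,
        identity=ident,
        query_cov=qcov,
        subject_cov=scov,
        q_start=0,
        q_end=100,
        s_start=0,
        s_end=100,
    )


class TestClassifyTranscript:
    def test_sense_from_protein_coverage(self):
        ann = classify_transcript([hit(scov=0.75)], T)
        assert ann.structural_class == "sense"

    def test_no_hits_is_unknown(self):
        ann = classify_transcript([], T)
        assert ann.structural_class == "unknown"

    def test_both_antisense_flags_can_be_set(self):
        hits = [
            hit(ori="antisense", scov=0.55),
            hit(s="sense1", db="self_transcriptome", ori="antisense", qcov=0.85, ident=0.96),
        ]
        ann = classify_transcript(hits, T, sense_set={"sense1"})
        assert ann.structural_class == "antisense"
        assert ann.antisense_to_protein and ann.antisense_to_sense
        assert ann.sense_partners == ["sense1"]

    def test_exact_threshold_does_not_qualify(self):
        # coverage exactly 0.50 fails the strict antisense rule and the
        # transcript falls through to the lncRNA/unknown stage
        ann = classify_transcript([hit(ori="antisense", scov=0.50)], T)
        assert ann.structural_class == "unknown"

    @pytest.mark.parametrize(
        "kwargs, sense_set, expected",
        [
            (dict(scov=0.60), set(), "unknown"),                        # sense bound
            (dict(scov=0.601), set(), "sense"),
            (dict(ori="antisense", scov=0.501), set(), "antisense"),
            (
                dict(s="x", db="self_transcriptome", ori="antisense", qcov=0.80, ident=0.99),
                {"x"},
                "unknown",
            ),                                                           # qcov bound
            (
                dict(s="x", db="self_transcriptome", ori="antisense", qcov=0.81, ident=0.95),
                {"x"},
                "unknown",
            ),                                                           # identity bound
            (dict(db="genome", qcov=0.85, ident=0.95), set(), "unknown"),
            (dict(db="genome", qcov=0.85, ident=0.951), set(), "lncRNA"),
            (dict(db="nt", qcov=0.801, ident=0.96), set(), "lncRNA"),
        ],
    )
    def test_strict_boundaries(self, kwargs, sense_set, expected):
        ann = classify_transcript([hit(**kwargs)], T, sense_set)
        assert ann.structural_class == expected

    def test_sense_precedence_over_antisense(self):
        hits = [hit(scov=0.7), hit(ori="antisense", scov=0.9)]
        assert classify_transcript(hits, T).structural_class == "sense"

    def test_mixed_query_ids_rejected(self):
        with pytest.raises(AnnotationError):
            classify_transcript([hit(q="a"), hit(q="b")], T)


def _naive_classify(hits, thresholds, sense_set):
    """Independent re-evaluation of the rule text, one rule at a time."""
    t = thresholds
    ok_sense = [
        h
        for h in hits
        if h.subject_db in ("proteome", "nr")
        and h.orientation == "sense"
        and h.subject_cov > t.sense_protein_cov
    ]
    if ok_sense:
        return "sense"
    a2p = [
        h
        for h in hits
        if h.subject_db in ("proteome", "nr")
        and h.orientation == "antisense"
        and h.subject_cov > t.antisense_protein_cov
    ]
    a2s = [
        h
        for h in hits
        if h.subject_db == "self_transcriptome"
        and h.orientation == "antisense"
        and h.subject_id in sense_set
        and h.query_cov > t.antisense_sense_query_cov
        and h.identity > t.antisense_sense_identity
    ]
    if a2p or a2s:
        return "antisense"
    lnc = [
        h
        for h in hits
        if h.subject_db in ("genome", "nt")
        and h.query_cov > t.lnc_cov
        and h.identity > t.lnc_identity
    ]
    if lnc:
        return "lncRNA"
    return "unknown"


def test_classifier_matches_naive_oracle_on_random_instances(rng):
    dbs = ["proteome", "nr", "self_transcriptome", "genome", "nt"]
    for _ in range(30):
        n_tx = int(rng.integers(1, 50))
        tids = [f"t{i}" for i in range(n_tx)]
        gene_map = {t: t for t in tids}
        hits = []
        for tid in tids:
            for _ in range(int(rng.integers(0, 4))):
                hits.append(
                    AlignmentHit(
                        query_id=tid,
                        subject_id=str(rng.choice(tids + ["p1", "p2"])),
                        subject_db=str(rng.choice(dbs)),
                        orientation=str(rng.choice(["sense", "antisense"])),
                        identity=float(rng.uniform(0.5, 1.0)),
                        query_cov=float(rng.uniform(0.3, 1.0)),
                        subject_cov=float(rng.uniform(0.3, 1.0)),
                        q_start=0,
                        q_end=10,
                        s_start=0,
                        s_end=10,
                    )
                )
        anns = annotate_transcriptome(hits, gene_map, T)
        # oracle pass 1: sense set from protein evidence only
        by_q = {}
        for h in hits:
            by_q.setdefault(h.query_id, []).append(h)
        sense_set = {
            t for t in tids if _naive_classify(by_q.get(t, []), T, set()) == "sense"
        }
        for ann in anns:
            expected = _naive_classify(by_q.get(ann.transcript_id, []), T, sense_set)
            assert ann.structural_class == expected, ann.transcript_id


def test_round_trip_recovers_planted_classes(small_bundle):
    truth = small_bundle["truth"]
    anns = annotate_transcriptome(
        small_bundle["hits"],
        small_bundle["gene_map"],
        T,
        transcript_lengths=truth.transcript_length,
    )
    for ann in anns:
        assert ann.structural_class == truth.transcript_class[ann.transcript_id]
        if truth.planted_class[ann.transcript_id] == "antisense_to_sense":
            assert ann.zone_set == truth.zone_truth[ann.transcript_id]
            assert ann.sense_partners == [truth.sense_partner[ann.transcript_id]]


def test_empty_hits_table_gives_all_unknown():
    gene_map = {f"t{i}": f"g{i}" for i in range(7)}
    anns = annotate_transcriptome([], gene_map, T)
    assert len(anns) == 7
    assert all(a.structural_class == "unknown" for a in anns)


def test_class_fractions_partition(small_bundle):
    anns = annotate_transcriptome(small_bundle["hits"], small_bundle["gene_map"], T)
    counts = {}
    for a in anns:
        counts[a.structural_class] = counts.get(a.structural_class, 0) + 1
    assert sum(counts.values()) == len(anns)
    assert sum(v / len(anns) for v in counts.values()) == pytest.approx(1.0)


def test_sense_count_monotone_in_threshold(small_bundle):
    prev = None
    for cov in (0.55, 0.60, 0.70, 0.85, 0.95):
        t = AnnotationThresholds(sense_protein_cov=cov)
        anns = annotate_transcriptome(small_bundle["hits"], small_bundle["gene_map"], t)
        n_sense = sum(a.structural_class == "sense" for a in anns)
        if prev is not None:
            assert n_sense <= prev
        prev = n_sense


def test_unknown_transcript_in_hits_but_not_map_rejected():
    with pytest.raises(AnnotationError):
        annotate_transcriptome([hit(q="ghost")], {"t1": "g1"}, T)


class TestFindOrfs:
    def test_minimum_length_is_inclusive(self, rng):
        codons = "".join(
            np.random.default_rng(4).choice(
                [c for c in ("GCT", "GAA", "TTC", "GGA")], size=29
            )
        )
        seq = "CC" + "ATG" + codons + "TAA" + "GGTT"
        orfs = find_orfs(seq, min_aa=30)
        assert len(orfs) == 1
        frame, (start, end), length_aa = orfs[0]
        assert length_aa == 30
        assert seq[start : start + 3] == "ATG"
        assert seq[end - 3 : end] == "TAA"

    def test_below_minimum_excluded(self):
        codons = "GCT" * 28
        seq = "ATG" + codons + "TAA"
        assert find_orfs(seq, min_aa=30) == []
        assert len(find_orfs(seq, min_aa=28)) == 1

    def test_matches_exhaustive_scan(self, rng):
        def brute(seq, min_aa):
            found = []
            for start in range(len(seq) - 2):
                if seq[start : start + 3] != "ATG":
                    continue
                pos = start + 3
                while pos + 3 <= len(seq):
                    if seq[pos : pos + 3] in ("TAA", "TAG", "TGA"):
                        if (pos - start) // 3 >= min_aa:
                            found.append((start, pos + 3))
                        break
                    pos += 3
            # keep only the 5'-most start per stop within each frame
            best = {}
            for s, e in found:
                key = (s % 3, e)
                if key not in best or s < best[key][0]:
                    best[key] = (s, e)
            return sorted(best.values())

        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            got = sorted(iv for _, iv, _ in find_orfs(seq, min_aa=5))
            assert got == brute(seq, 5)

    def test_non_nucleotide_rejected(self):
        with pytest.raises(AnnotationError):
            find_orfs("ATGXXTAA")


class TestZones:
    @pytest.mark.parametrize(
        "interval, expected",
        [
            ((850, 1000), {"three_prime_utr"}),
            ((0, 1000), {"five_prime_utr", "cds", "three_prime_utr"}),
            ((150, 250), {"five_prime_utr", "cds"}),
            ((200, 800), {"cds"}),
            ((0, 200), {"five_prime_utr"}),
            ((799, 801), {"cds", "three_prime_utr"}),
        ],
    )
    def test_interval_intersections(self, interval, expected):
        got = classify_antisense_zones(interval, (200, 800), 1000)
        assert got == frozenset(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(AnnotationError):
            classify_antisense_zones((0, 10), (800, 200), 1000)
        with pytest.raises(AnnotationError):
            classify_antisense_zones((990, 1100), (200, 800), 1000)

    @given(
        split=st.integers(min_value=1, max_value=999),
        a=st.integers(min_value=0, max_value=998),
        span=st.integers(min_value=2, max_value=500),
    )
    @settings(max_examples=60, deadline=None)
    def test_partitioned_interval_zones_union_to_whole(self, split, a, span):
        b = min(a + span, 1000)
        mid = a + (b - a) // 2
        if mid == a or mid == b or not (0 < split < 999):
            return
        cds = (min(split, 998), 999)
        whole = classify_antisense_zones((a, b), cds, 1000)
        left = classify_antisense_zones((a, mid), cds, 1000)
        right = classify_antisense_zones((mid, b), cds, 1000)
        assert left | right == whole
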