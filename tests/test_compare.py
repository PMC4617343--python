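"""Gene-level pooling, the three-rule LTM-vs-ARM filter and Venn
overlap accounting."""

import numpy as np
import pytest

from memorydiff.compare import (
    CompareError,
    apply_ltm_filter,
    compute_overlaps,
    detect_opposing,
    summarize_gene_de,
)
from memorydiff.de import DECall

LTM = ["Glo-LTM-short", "Glo-LTM-long"]
ARM = "Glo-ARM"


def call(tx, ct, tp="1h", direction="up", sig=True):
    return DECall(
        transcript_id=tx,
        conditioning_type=ct,
        time_point=tp,
        logfc=1.0 if direction == "up" else -1.0,
        p_value=0.01 if sig else 0.5,
        direction=direction,
        significant=sig,
    )


class TestSummarize:
    def test_time_points_pool_into_one_entry(self):
        calls = [call("t1", "Glo-LTM-long", "15m"), call("t1", "Glo-LTM-long", "4h")]
        (summ,) = summarize_gene_de(calls, {"t1": "g1"})
        assert summ.by_type["Glo-LTM-long"] == {("t1", "up"): {"15m", "4h"}}

    def test_variants_keep_their_conditioning_types(self):
        calls = [call("t1", "Glo-LTM-short"), call("t2", "Glo-ARM", direction="down")]
        (summ,) = summarize_gene_de(calls, {"t1": "g1", "t2": "g1"})
        assert summ.transcripts("Glo-LTM-short") == {"t1"}
        assert summ.transcripts("Glo-ARM") == {"t2"}

    def test_non_significant_calls_ignored(self):
        calls = [call("t1", "Glo-LTM-short", sig=False)]
        assert summarize_gene_de(calls, {"t1": "g1"}) == []

    def test_unmapped_transcript_rejected(self):
        with pytest.raises(CompareError):
            summarize_gene_de([call("t9", "Glo-ARM")], {"t1": "g1"})


class TestDetectOpposing:
    def _summary(self, calls, gene_map):
        (summ,) = summarize_gene_de(calls, gene_map)
        return summ

    def test_opposite_directions_detected(self):
        s = self._summary(
            [call("t1", "A", direction="up"), call("t1", "B", direction="down")],
            {"t1": "g"},
        )
        assert detect_opposing(s, "A", "B")

    def test_same_direction_rejected(self):
        s = self._summary(
            [call("t1", "A", direction="up"), call("t1", "B", direction="up")],
            {"t1": "g"},
        )
        assert not detect_opposing(s, "A", "B")

    def test_universal_quantifier_over_shared_transcripts(self):
        s = self._summary(
            [
                call("t1", "A", direction="up"),
                call("t1", "B", direction="up"),
                call("t2", "A", direction="up"),
                call("t2", "B", direction="down"),
            ],
            {"t1": "g", "t2": "g"},
        )
        assert not detect_opposing(s, "A", "B")

    def test_disjoint_variant_sets_are_not_opposing(self):
        s = self._summary(
            [call("t1", "A", direction="up"), call("t2", "B", direction="down")],
            {"t1": "g", "t2": "g"},
        )
        assert not detect_opposing(s, "A", "B")

    def test_single_type_gene_is_false(self):
        s = self._summary([call("t1", "A")], {"t1": "g"})
        assert not detect_opposing(s, "A", "B")


class TestLtmFilter:
    def _run(self, calls, gene_map):
        return apply_ltm_filter(summarize_gene_de(calls, gene_map), LTM, ARM)

    def test_absent_in_arm_retained(self):
        (cand,) = self._run([call("t1", "Glo-LTM-long")], {"t1": "g1"})
        assert cand.rule == "absent_in_arm"
        assert cand.retained_for == {"Glo-LTM-long"}

    def test_opposing_retained(self):
        (cand,) = self._run(
            [call("t1", "Glo-LTM-long", direction="up"),
             call("t1", ARM, direction="down")],
            {"t1": "g1"},
        )
        assert cand.rule == "opposing"

    def test_splice_variant_discrimination(self):
        # variant A down in short LTM and ARM, variant B down in long LTM:
        # excluded for the short type, retained for the long one
        calls = [
            call("vA", "Glo-LTM-short", direction="down"),
            call("vA", ARM, direction="down"),
            call("vB", "Glo-LTM-long", direction="down"),
        ]
        (cand,) = self._run(calls, {"vA": "g1", "vB": "g1"})
        assert cand.retained_for == {"Glo-LTM-long"}
        assert cand.rule == "splice_variant"

    def test_shared_same_direction_excluded(self):
        cands = self._run(
            [call("t1", "Glo-LTM-long", direction="down"),
             call("t1", ARM, direction="down")],
            {"t1": "g1"},
        )
        assert cands == []

    def test_arm_only_gene_not_a_candidate(self):
        assert self._run([call("t1", ARM)], {"t1": "g1"}) == []

    def test_splice_rule_can_be_restricted(self):
        calls = [call("vA", "Glo-LTM-long"), call("vB", ARM)]
        gene_map = {"vA": "g1", "vB": "g1"}
        with_rule = apply_ltm_filter(
            summarize_gene_de(calls, gene_map), LTM, ARM
        )
        without = apply_ltm_filter(
            summarize_gene_de(calls, gene_map), LTM, ARM, splice_aware_types=[]
        )
        assert len(with_rule) == 1 and with_rule[0].rule == "splice_variant"
        assert without == []

    def test_rule_labels_reproducible_from_evidence(self, rng):
        """Rule partition invariant: re-evaluating the predicates on the
        stored evidence reproduces each candidate's label."""
        types = LTM + [ARM]
        for _ in range(50):
            calls = []
            gene_map = {}
            for g in range(6):
                for v in range(int(rng.integers(1, 3))):
                    tx = f"g{g}v{v}"
                    gene_map[tx] = f"g{g}"
                    for ct in types:
                        if rng.random() < 0.4:
                            calls.append(
                                call(tx, ct, direction=str(rng.choice(["up", "down"])))
                            )
            summaries = summarize_gene_de(calls, gene_map)
            by_gene = {s.gene_id: s for s in summaries}
            for cand in apply_ltm_filter(summaries, LTM, ARM):
                s = by_gene[cand.gene_id]
                arm_tx = s.transcripts(ARM)
                rules = set()
                for lt in cand.retained_for:
                    ltm_tx = s.transcripts(lt)
                    assert ltm_tx, "retained type must be DE"
                    if not arm_tx:
                        rules.add("absent_in_arm")
                    elif detect_opposing(s, lt, ARM):
                        rules.add("opposing")
                    else:
                        assert not (ltm_tx & arm_tx)
                        rules.add("splice_variant")
                order = ["absent_in_arm", "opposing", "splice_variant"]
                assert cand.rule == min(rules, key=order.index)


class TestVenn:
    def test_two_set_regions(self):
        venn = compute_overlaps({"one": {"A", "B"}, "two": {"B", "C"}})
        assert venn.count("one") == 1
        assert venn.count("two") == 1
        assert venn.count("one", "two") == 1

    def test_three_identical_sets(self):
        s = {f"x{i}" for i in range(9)}
        venn = compute_overlaps({"a": s, "b": set(s), "c": set(s)})
        assert venn.count("a", "b", "c") == 9
        assert venn.total() == 9

    def test_matches_membership_tabulation_oracle(self, rng):
        universe = [f"g{i}" for i in range(120)]
        sets = {
            label: set(rng.choice(universe, size=size, replace=False))
            for label, size in (("a", 50), ("b", 60), ("c", 70))
        }
        venn = compute_overlaps(sets)
        # oracle: tabulate each element's membership pattern directly
        from collections import Counter

        patterns = Counter()
        for g in universe:
            inside = frozenset(l for l, s in sets.items() if g in s)
            if inside:
                patterns[inside] += 1
        for region, n in venn.regions.items():
            assert n == patterns.get(region, 0)
        assert venn.total() == len(set().union(*sets.values()))

    def test_ordering_and_duplicates_do_not_matter(self):
        venn1 = compute_overlaps({"a": ["x", "y", "x"], "b": ["y", "z"]})
        venn2 = compute_overlaps({"a": {"y", "x"}, "b": {"z", "y"}})
        assert venn1.regions == venn2.regions

    def test_ortholog_projection_merges_cross_species_genes(self):
        venn = compute_overlaps(
            {"spA": {"gA1", "gA2"}, "spB": {"gB1", "gB9"}},
            ortholog_map={"gA1": "OG1", "gB1": "OG1"},
        )
        assert venn.count("spA", "spB") == 1
        assert venn.count("spA") == 1 and venn.count("spB") == 1


def test_truth_bypassed_recovery_on_planted_roles(small_bundle):
    """With noise-free calls the filter reproduces the planted roles
    exactly: ltm_only -> absent_in_arm, opposing -> opposing,
    splice_specific -> splice_variant, others excluded."""
    from memorydiff.simulate import expected_candidates, truth_calls

    truth = small_bundle["truth"]
    cfg = small_bundle["config"]
    calls = truth_calls(truth, cfg)
    summaries = summarize_gene_de(calls, small_bundle["gene_map"])
    cands = {c.gene_id: c for c in apply_ltm_filter(summaries, LTM, ARM)}
    expected = expected_candidates(truth)
    for gene, rule in expected.items():
        if rule is None:
            assert gene not in cands, (gene, truth.gene_role[gene])
        else:
            assert gene in cands and cands[gene].rule == rule
    # no gene outside the planted roles can be a candidate
    assert set(cands) <= {g for g, r in expected.items() if r is not None}
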