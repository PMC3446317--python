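import numpy as np
import pandas as pd
import pytest

from tevland import calling
from tevland.calling import CallerParams, Candidate

from conftest import clean_breakpoint_anchors, make_anchor_frame


PARAMS = CallerParams()


def anchors_at(pos_list, orientation, strain="s1", chrom="chr1",
               mapq=60, family="IAP"):
    return [(strain, chrom, p, orientation, mapq, family) for p in pos_list]


class TestClusterAnchors:
    @pytest.mark.parametrize("n,expect", [(9, 0), (10, 1)])
    def test_support_pair_threshold(self, n, expect):
        """At least 10 independent read pairs are required for a call."""
        reads = make_anchor_frame(anchors_at(range(1000, 1000 + n * 10, 10),
                                             "F"))
        assert len(calling.cluster_anchors(reads, PARAMS)) == expect

    @pytest.mark.parametrize("mapq,expect", [(29, 0), (30, 1)])
    def test_mapping_quality_threshold(self, mapq, expect):
        reads = make_anchor_frame(
            anchors_at(range(1000, 1100, 10), "F", mapq=mapq))
        assert len(calling.cluster_anchors(reads, PARAMS)) == expect

    def test_mate_without_te_hit_is_not_support(self):
        rows = anchors_at(range(1000, 1100, 10), "F", family=None)
        reads = make_anchor_frame(rows)
        assert calling.cluster_anchors(reads, PARAMS) == []

    def test_unsorted_input_rejected(self):
        reads = make_anchor_frame(anchors_at(range(1000, 1100, 10), "F"))
        reads = reads.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            calling.cluster_anchors(reads, PARAMS)

    def test_distant_anchors_split_clusters(self):
        rows = (anchors_at(range(1000, 1100, 10), "F")
                + anchors_at(range(9000, 9100, 10), "F"))
        reads = make_anchor_frame(rows)
        cands = calling.cluster_anchors(reads, PARAMS)
        assert len(cands) == 2


class TestRefineBreakpoint:
    def _gap_fixture(self, gap):
        """10 F anchors ending at x, 10 R anchors starting at x + gap."""
        x = 10_000
        rows = (anchors_at(range(x - 90, x + 1, 10), "F")
                + anchors_at(range(x + gap, x + gap + 91, 10), "R"))
        reads = make_anchor_frame(rows)
        cand = calling.cluster_anchors(reads, PARAMS)[0]
        return calling.refine_breakpoint(cand, reads, PARAMS)

    def test_gap_119_accepted(self):
        res = self._gap_fixture(119)
        assert res.accepted

    def test_gap_120_rejected(self):
        res = self._gap_fixture(120)
        assert not res.accepted and res.reason == "gap"

    def _ratio_fixture(self, n_f, n_r):
        x = 10_000
        rows = (anchors_at(np.linspace(x - 400, x - 1, n_f).astype(int), "F")
                + anchors_at(np.linspace(x, x + 400, n_r).astype(int), "R"))
        reads = make_anchor_frame(rows)
        cand = calling.cluster_anchors(reads, PARAMS)[0]
        return calling.refine_breakpoint(cand, reads, PARAMS)

    def test_unbalanced_flank_support_rejected(self):
        """25 forward vs 10 reverse anchors is a 2.5:1 imbalance."""
        res = self._ratio_fixture(25, 10)
        assert not res.accepted and res.reason == "ratio"

    def test_balanced_flank_support_accepted(self):
        res = self._ratio_fixture(19, 10)  # 1.9 : 1 < 2
        assert res.accepted

    def test_exact_two_to_one_rejected(self):
        res = self._ratio_fixture(20, 10)  # exactly 2 : 1, bound exclusive
        assert not res.accepted and res.reason == "ratio"

    def _repeat_fixture(self, distance):
        reads = clean_breakpoint_anchors(bp=10_000)
        cand = calling.cluster_anchors(reads, PARAMS)[0]
        base = calling.refine_breakpoint(cand, reads, PARAMS)
        assert base.accepted
        repeats = pd.DataFrame({
            "chrom": ["chr1"], "start": [base.breakpoint + distance],
            "end": [base.breakpoint + distance + 200], "strand": ["+"],
            "te_class": ["SINE"], "family": ["B1"], "divergence_pct": [5.0],
        })
        return calling.refine_breakpoint(cand, reads, PARAMS, repeats)

    def test_repeat_within_50bp_rejected(self):
        res = self._repeat_fixture(50)
        assert not res.accepted and res.reason == "repeat_proximity"

    def test_repeat_at_51bp_kept(self):
        res = self._repeat_fixture(51)
        assert res.accepted

    def test_non_excluded_repeat_class_ignored(self):
        reads = clean_breakpoint_anchors(bp=10_000)
        cand = calling.cluster_anchors(reads, PARAMS)[0]
        repeats = pd.DataFrame({
            "chrom": ["chr1"], "start": [10_000], "end": [10_050],
            "strand": ["+"], "te_class": ["DNA"], "family": ["x"],
            "divergence_pct": [0.0]})
        assert calling.refine_breakpoint(cand, reads, PARAMS,
                                         repeats).accepted

    def test_leftmost_qualifying_position(self):
        """Two runs of the same fixture give the same (leftmost) breakpoint."""
        reads = clean_breakpoint_anchors(bp=20_000)
        cand = calling.cluster_anchors(reads, PARAMS)[0]
        r1 = calling.refine_breakpoint(cand, reads, PARAMS)
        r2 = calling.refine_breakpoint(cand, reads, PARAMS)
        assert r1.accepted and r1.breakpoint == r2.breakpoint
        assert r1.breakpoint <= 20_000


class TestGenotype:
    def _fixture(self, n_f, n_r):
        call = calling.RefinedCall("s1", "chr1", 10_000, "IAP", 15, 15)
        rows = (anchors_at(range(10_000 - 10 * n_f, 10_000, 10), "F",
                           strain="s2")
                + anchors_at(range(10_000, 10_000 + 10 * n_r, 10), "R",
                             strain="s2"))
        reads = make_anchor_frame(rows)
        return calling.genotype(call, reads, ["s1", "s2"], PARAMS)

    def test_five_and_five_present(self):
        assert self._fixture(5, 5)["s2"] == "present"

    def test_four_and_five_absent(self):
        assert self._fixture(4, 5)["s2"] == "absent"

    def test_discovery_strain_always_present(self):
        assert self._fixture(0, 0)["s1"] == "present"

    def test_monotone_in_evidence(self):
        """Adding qualifying anchors never flips present -> absent."""
        call = calling.RefinedCall("s1", "chr1", 10_000, "IAP", 15, 15)
        rows = (anchors_at(range(9_940, 10_000, 10), "F", strain="s2")
                + anchors_at(range(10_000, 10_060, 10), "R", strain="s2"))
        base = make_anchor_frame(rows)
        assert calling.genotype(call, base, ["s2"], PARAMS)["s2"] == "present"
        more = make_anchor_frame(
            rows + anchors_at([9_905, 9_915], "F", strain="s2")
            + anchors_at([10_085, 10_095], "R", strain="s2"))
        assert calling.genotype(call, more, ["s2"], PARAMS)["s2"] == "present"


class TestSizeClass:
    @pytest.mark.parametrize("spanning,expect",
                             [(3, "gt3kb"), (2, "le3kb"), (0, "le3kb")])
    def test_literal_rule(self, spanning, expect):
        assert calling.estimate_size_class(spanning) == expect

    def test_physical_reading_switch(self):
        params = CallerParams(spanning_literal=False)
        assert calling.estimate_size_class(3, params) == "le3kb"
        assert calling.estimate_size_class(0, params) == "gt3kb"

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            calling.estimate_size_class(-1)


def repeat_rows(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "te_class", "family"])
    df["divergence_pct"] = 1.0
    return df


class TestClassifyB6Plus:
    def test_canonical_provirus(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 7000}
        reps = repeat_rows([
            ("chr1", 1000, 1400, "+", "ERV", "IAP"),
            ("chr1", 1400, 6600, "+", "ERV", "IAP-int"),
            ("chr1", 6600, 7000, "+", "ERV", "IAP"),
        ])
        res = calling.classify_b6plus(sv, reps)
        assert res["accepted"] and res["structure"] == "provirus"
        assert res["family"] == "IAP"

    def test_solo_ltr(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 1400}
        reps = repeat_rows([("chr1", 1000, 1400, "-", "ERV", "IAP")])
        res = calling.classify_b6plus(sv, reps)
        assert res["structure"] == "solo_LTR" and res["strand"] == "-"

    def test_ltr_int_only(self):
        sv = {"chrom": "chr1", "start": 1400, "end": 6600}
        reps = repeat_rows([("chr1", 1400, 6600, "+", "ERV", "IAP-int")])
        assert calling.classify_b6plus(sv, reps)["structure"] == "LTR_int"

    def test_hybrid_provirus(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 7000}
        reps = repeat_rows([
            ("chr1", 1000, 1400, "+", "ERV", "IAP"),
            ("chr1", 1400, 6600, "+", "ERV", "ETn-int"),
            ("chr1", 6600, 7000, "+", "ERV", "IAP"),
        ])
        assert calling.classify_b6plus(sv, reps)["structure"] == \
            "hybrid_provirus"

    def test_pseudoelement_partial_ltr(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 1200}
        reps = repeat_rows([("chr1", 1000, 1200, "+", "ERV", "IAP")])
        reps["partial"] = [1]
        assert calling.classify_b6plus(sv, reps)["structure"] == \
            "pseudoelement"

    @pytest.mark.parametrize("length,expect",
                             [(4_999, "LINE_frag"), (5_000, "LINE")])
    def test_line_fragment_cutoff(self, length, expect):
        sv = {"chrom": "chr1", "start": 1000, "end": 1000 + length}
        reps = repeat_rows([("chr1", 1000, 1000 + length, "+", "LINE", "L1")])
        assert calling.classify_b6plus(sv, reps)["te_class"] == expect

    def test_te_far_from_both_breakpoints_rejected(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 2000}
        reps = repeat_rows([("chr1", 1060, 1940, "+", "SINE", "B1")])
        res = calling.classify_b6plus(sv, reps)
        assert not res["accepted"] and res["reason"] == "breakpoint_distance"

    def test_te_near_one_breakpoint_accepted(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 2000}
        reps = repeat_rows([("chr1", 1040, 1940, "+", "SINE", "B1")])
        assert calling.classify_b6plus(sv, reps)["accepted"]

    def test_no_te_rejected(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 2000}
        res = calling.classify_b6plus(sv, repeat_rows([]))
        assert not res["accepted"] and res["reason"] == "no_te"

    def test_simple_repeat_content_is_complex(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 2000}
        reps = repeat_rows([
            ("chr1", 1000, 1400, "+", "SINE", "B1"),
            ("chr1", 1500, 1600, "+", "simple_repeat", "(CA)n"),
        ])
        res = calling.classify_b6plus(sv, reps)
        assert not res["accepted"] and res["reason"] == "complex"

    def test_two_separate_elements_are_complex(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 3000}
        reps = repeat_rows([
            ("chr1", 1000, 1200, "+", "SINE", "B1"),
            ("chr1", 2800, 3000, "+", "LINE", "L1"),
        ])
        res = calling.classify_b6plus(sv, reps)
        assert not res["accepted"] and res["reason"] == "complex"

    def test_malformed_sv_rejected(self):
        with pytest.raises(ValueError):
            calling.classify_b6plus({"chrom": "chr1", "start": 10, "end": 10},
                                    repeat_rows([]))

    def test_batch_conserves_inputs(self):
        svs = pd.DataFrame({
            "strain": ["s"] * 3, "chrom": ["chr1"] * 3,
            "start": [1000, 5000, 9000], "end": [1400, 5100, 9400]})
        reps = repeat_rows([("chr1", 1000, 1400, "+", "ERV", "IAP")])
        acc, rej = calling.classify_b6plus_batch(svs, reps)
        assert len(acc) + len(rej) == len(svs)

    def test_strand_mirror_symmetry(self):
        sv = {"chrom": "chr1", "start": 1000, "end": 7000}
        rows = [
            ("chr1", 1000, 1400, "+", "ERV", "IAP"),
            ("chr1", 1400, 6600, "+", "ERV", "IAP-int"),
            ("chr1", 6600, 7000, "+", "ERV", "IAP"),
        ]
        fwd = calling.classify_b6plus(sv, repeat_rows(rows))
        L = 8000  # mirror the fixture through the chromosome
        mirrored = [("chr1", L - e, L - s, "-", c, f)
                    for _, s, e, _, c, f in rows][::-1]
        sv_m = {"chrom": "chr1", "start": L - 7000, "end": L - 1000}
        rev = calling.classify_b6plus(sv_m, repeat_rows(mirrored))
        assert fwd["structure"] == rev["structure"]
        assert fwd["te_class"] == rev["te_class"]


class TestErrorRates:
    def _presence(self, patterns):
        return pd.DataFrame(patterns, columns=["t1", "t2", "t3", "other"])

    def test_all_three_of_three(self):
        pres = self._presence([[1, 1, 1, 0]] * 10)
        fnr, counts = calling.estimate_error_rates(pres, ("t1", "t2", "t3"))
        assert fnr == 0.0 and counts["sites"] == 10

    def test_one_two_of_three_site(self):
        pres = self._presence([[1, 1, 1, 0]] * 9 + [[1, 1, 0, 0]])
        fnr, counts = calling.estimate_error_rates(pres, ("t1", "t2", "t3"))
        assert fnr == pytest.approx(1 / 30)
        assert counts == {"sites": 10, "absent_calls": 1,
                          "expected_calls": 30}

    def test_all_two_of_three(self):
        pres = self._presence([[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 1, 0]])
        fnr, _ = calling.estimate_error_rates(pres, ("t1", "t2", "t3"))
        assert fnr == pytest.approx(1 / 3)

    def test_missing_trio_strain(self):
        pres = self._presence([[1, 1, 1, 0]])
        with pytest.raises(ValueError):
            calling.estimate_error_rates(pres, ("t1", "t2", "nope"))
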