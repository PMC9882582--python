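import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from quantalign.aligner import Alignment
from quantalign.sv import (
    MatchResult,
    SVCall,
    breakpoint_score,
    exclude_regions,
    extract_sv_candidates,
    f1_score,
    is_well_aligned,
    length_similarity,
    match_calls,
    normalized_alignment_length,
    normalized_edit_distance,
    prf,
    regression_fit,
    union_calls,
)


def mk_aln(cigar, t_start=0, strand="+", q_len=None):
    from quantalign.aligner import cigar_consumed

    qc, tc = cigar_consumed(cigar)
    return Alignment(
        query_id="r",
        target_id="chr1",
        strand=strand,
        q_start=0,
        q_end=qc,
        t_start=t_start,
        t_end=t_start + tc,
        cigar=cigar,
        score=qc,
        edit_dist=0,
        mapq=60,
        query_length=q_len or qc,
    )


def sv(chrom, start, end, svtype, length, **kw):
    return SVCall(chrom, start, end, svtype, length, **kw)


class TestWellAligned:
    def test_cases(self):
        a = mk_aln("950=", q_len=1000)
        assert is_well_aligned(a, 1000)
        a.mapq = 20
        assert not is_well_aligned(a, 1000)  # strictly greater than 20
        b = mk_aln("890=", q_len=1000)
        assert not is_well_aligned(b, 1000)


class TestAlignmentMetrics:
    def test_exact_alignment_has_zero_ned(self):
        genome = {"chr1": "ACGTACGTACGTACGT"}
        assert normalized_edit_distance("ACGTACGT", genome, "chr1", 4, 12) == 0.0

    def test_single_substitution(self):
        genome = {"chr1": "ACGAACGT"}
        assert normalized_edit_distance("ACGTACGT", genome, "chr1", 0, 8) == 1 / 8

    def test_minus_strand_orients_the_slice(self):
        from quantalign.quantize import reverse_complement

        genome = {"chr1": "AAACCCGGGTTTAAA"}
        read = reverse_complement(genome["chr1"][3:12])
        assert normalized_edit_distance(read, genome, "chr1", 3, 12, strand="-") == 0.0

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            normalized_edit_distance("ACGT", {"chr1": "ACGT"}, "chr1", 2, 2)

    def test_matches_dp_oracle(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 500))}
        for _ in range(20):
            s, e = sorted(rng.integers(0, 500, 2))
            if e - s < 5:
                continue
            read = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 80))))
            got = normalized_edit_distance(read, genome, "chr1", s, e)
            assert got == oracles.dp_edit_distance(read, genome["chr1"][s:e]) / len(read)

    def test_normalized_alignment_length(self):
        assert normalized_alignment_length(100, 1100, 1000) == 1.0
        assert normalized_alignment_length(0, 500, 1000) == 0.5
        assert normalized_alignment_length(0, 1500, 1000) > 1  # deletion span


class TestExtraction:
    def test_deletion_run_becomes_call(self):
        alns = [[mk_aln("100=60D40=", t_start=1000)]]
        calls = extract_sv_candidates(alns, min_support=1)
        assert [(c.svtype, c.start, c.length) for c in calls] == [("DEL", 1100, 60)]

    def test_sub_threshold_insertion_ignored(self):
        alns = [[mk_aln("100=49I100=", t_start=0)]]
        assert extract_sv_candidates(alns, min_support=1) == []

    def test_insertion_run_becomes_call(self):
        alns = [[mk_aln("100=75I100=", t_start=500)]] * 3
        calls = extract_sv_candidates(alns, min_support=3)
        assert [(c.svtype, c.start, c.length) for c in calls] == [("INS", 600, 75)]

    def test_opposite_strand_split_segments_become_inversion(self):
        flank_l = mk_aln("1000=", t_start=0)
        mid = mk_aln("800=", t_start=1010, strand="-")
        flank_r = mk_aln("900=", t_start=1820)
        calls = extract_sv_candidates([[flank_l, mid, flank_r]] * 3, min_support=3)
        assert [(c.svtype, c.start, c.end) for c in calls] == [("INV", 1010, 1810)]


class TestPairScores:
    def test_breakpoint_score_arithmetic(self):
        t = sv("chr1", 100, 200, "DEL", 100)
        assert breakpoint_score(sv("chr1", 100, 200, "DEL", 100), t) == 0
        assert breakpoint_score(sv("chr1", 110, 210, "DEL", 100), t) == 10
        assert breakpoint_score(sv("chr1", 100, 230, "DEL", 130), t) == 15

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError):
            breakpoint_score(
                sv("chr1", 0, 10, "DEL", 10), sv("chr2", 0, 10, "DEL", 10)
            )

    def test_length_similarity_values(self):
        a = sv("chr1", 0, 80, "DEL", 80)
        b = sv("chr1", 0, 100, "DEL", 100)
        assert length_similarity(a, b) == pytest.approx(0.8)
        assert length_similarity(a, a) == 1.0

    @given(st.integers(50, 5000), st.integers(50, 5000))
    @settings(max_examples=50, deadline=None)
    def test_length_similarity_symmetric(self, la, lb):
        a = sv("chr1", 0, la, "DEL", la)
        b = sv("chr1", 0, lb, "DEL", lb)
        assert length_similarity(a, b) == length_similarity(b, a)


class TestMatching:
    def test_exact_match_is_tp(self):
        t = [sv("chr1", 100, 200, "DEL", 100)]
        m = match_calls([sv("chr1", 100, 200, "DEL", 100, source="x")], t)
        assert (len(m.pairs), len(m.fp), len(m.fn)) == (1, 0, 0)

    def test_low_length_similarity_is_rejected(self):
        # similarity 0.6 < the 0.7 default
        t = [sv("chr1", 100, 200, "DEL", 100)]
        m = match_calls([sv("chr1", 100, 160, "DEL", 60)], t)
        assert (len(m.pairs), len(m.fp), len(m.fn)) == (0, 1, 1)

    def test_type_must_agree(self):
        t = [sv("chr1", 100, 200, "INV", 100)]
        m = match_calls([sv("chr1", 100, 200, "DEL", 100)], t)
        assert len(m.pairs) == 0

    def test_greedy_equals_exhaustive_on_realistic_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            truths, calls = [], []
            for _ in range(int(rng.integers(1, 7))):
                pos = int(rng.integers(0, 1_000_000))
                ln = int(rng.integers(50, 2000))
                svtype = ["DEL", "INS", "INV"][rng.integers(0, 3)]
                end = pos if svtype == "INS" else pos + ln
                truths.append(sv("chr1", pos, end, svtype, ln))
                if rng.random() < 0.8:  # most truths get a perturbed call
                    dp = int(rng.integers(-300, 300))
                    dl = int(ln * rng.uniform(0.75, 1.3))
                    cend = pos + dp if svtype == "INS" else pos + dp + dl
                    calls.append(sv("chr1", pos + dp, cend, svtype, dl))
            got = len(match_calls(calls, truths).pairs)
            want = oracles.best_matching_tp(
                [(c.svtype, c.start, c.end, c.length) for c in calls],
                [(t.svtype, t.start, t.end, t.length) for t in truths],
                refdist=500,
                pctsize=0.7,
            )
            assert got == want


class TestPrf:
    def test_harmonic_mean_cases(self):
        assert f1_score(0.94, 0.94) == pytest.approx(0.94)
        assert f1_score(0.0, 0.5) == 0.0
        assert f1_score(1.0, 0.5) == pytest.approx(2 / 3)

    def test_counting_invariants(self):
        t = [sv("chr1", i * 10_000, i * 10_000 + 100, "DEL", 100) for i in range(4)]
        calls = [sv("chr1", 5, 105, "DEL", 100), sv("chr1", 500_000, 500_100, "DEL", 100)]
        scores = prf(match_calls(calls, t))
        assert scores.tp + scores.fp == len(calls)
        assert scores.tp + scores.fn == len(t)
        assert scores.precision == scores.tp / len(calls)

    def test_empty_call_set_warns(self):
        with pytest.warns(UserWarning):
            scores = prf(match_calls([], [sv("chr1", 0, 100, "DEL", 100)]))
        assert scores.precision == 0.0 and scores.f1 == 0.0


class TestUnion:
    def test_disjoint_sets_concatenate(self):
        a = [sv("chr1", 1000, 1100, "DEL", 100)]
        b = [sv("chr1", 900_000, 900_000, "INS", 70)]
        assert len(union_calls(a, b)) == 2

    def test_identical_sets_collapse_to_a(self):
        a = [sv("chr1", 1000, 1100, "DEL", 100, source="A")]
        b = [sv("chr1", 1000, 1100, "DEL", 100, source="B")]
        u = union_calls(a, b)
        assert len(u) == 1 and u[0].source == "A"

    def test_union_never_reduces_tp_or_recall(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            truths = [
                sv("chr1", int(p), int(p) + 100, "DEL", 100)
                for p in rng.integers(0, 10_000_000, int(rng.integers(3, 10)))
            ]
            def subset():
                out = []
                for t in truths:
                    if rng.random() >= 0.6:
                        continue
                    start = t.start + int(rng.integers(-50, 50))
                    length = t.length + int(rng.integers(-10, 10))
                    out.append(sv("chr1", start, start + length, "DEL", length))
                return out
            a, b = subset(), subset()
            u = union_calls(a, b)
            tp = lambda c: len(match_calls(c, truths).pairs)
            assert tp(u) >= max(tp(a), tp(b))


class TestRegression:
    def test_identity_line(self):
        slope, intercept = regression_fit([0, 1, 2, 3], [0, 1, 2, 3])
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)

    def test_constant_response(self):
        slope, _ = regression_fit([0, 1, 2, 3], [5, 5, 5, 5])
        assert slope == pytest.approx(0.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        xs = rng.normal(size=40)
        ys = 0.7 * xs + rng.normal(scale=0.1, size=40)
        assert regression_fit(xs, ys) == pytest.approx(oracles.ols_fit(xs, ys))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            regression_fit([1, 1, 1], [2, 3, 4])


class TestExcludeRegions:
    def test_rules(self):
        calls = [
            sv("chr1", 100, 200, "DEL", 100),
            sv("chr1", 5000, 5300, "INV", 300),
            sv("chr1", 9000, 9000, "INS", 80),
        ]
        bed = [("chr1", 150, 160), ("chr1", 8000, 9500)]
        kept = exclude_regions(calls, bed)
        assert [(c.start, c.svtype) for c in kept] == [(5000, "INV")]

    def test_no_overlap_is_identity(self):
        calls = [sv("chr1", 100, 200, "DEL", 100)]
        assert exclude_regions(calls, [("chr2", 0, 10**6)]) == calls
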