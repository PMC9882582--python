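import numpy as np
import pytest

import oracles
import quantalign as qa
from quantalign.aligner import (
    Anchor,
    NUCLEOTIDE_PARAMS,
    QUANTIZED_PARAMS,
    AlignParams,
    TargetIndex,
    align,
    banded_global,
    chain_anchors,
    cigar_consumed,
    compute_mapq,
    edit_distance,
    extend_chain,
    extract_minimizers,
    seq_to_codes,
)
from quantalign.quantize import reverse_complement


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("ACGT", "AGT", 1), ("", "AAAA", 4)]
    )
    def test_known_values(self, a, b, d):
        assert edit_distance(a, b) == d

    def test_matches_quadratic_dp_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = random_dna(rng, int(rng.integers(1, 60)))
            b = random_dna(rng, int(rng.integers(1, 60)))
            assert edit_distance(a, b) == oracles.dp_edit_distance(a, b)


class TestBandedGlobal:
    def test_equals_full_dp_when_band_suffices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(10, 120)))
            b = random_dna(rng, int(rng.integers(10, 120)))
            d, cigar = banded_global(a, b, band=8)
            assert d == oracles.dp_edit_distance(a, b)
            qc, tc = cigar_consumed(cigar)
            assert qc == len(a) and tc == len(b)

    def test_empty_sides(self):
        assert banded_global("", "ACG", 4) == (3, "3D")
        assert banded_global("ACG", "", 4) == (3, "3I")


class TestMinimizers:
    def test_window_one_reports_every_kmer(self):
        params = AlignParams(k=5, w=1, canonical=False)
        codes = seq_to_codes("ACGTACGTACGT", params)
        pos, hashes, strands = extract_minimizers(codes, params)
        assert pos.tolist() == list(range(len(codes) - 5 + 1))

    def test_homopolymer_has_single_hash(self):
        params = AlignParams(k=5, w=4, canonical=False)
        pos, hashes, _ = extract_minimizers(seq_to_codes("A" * 40, params), params)
        assert len(set(hashes.tolist())) == 1

    def test_short_sequence_yields_nothing(self):
        params = AlignParams(k=15, w=10)
        out = extract_minimizers(seq_to_codes("ACGT", params), params)
        assert out[0].size == 0

    def test_canonical_hashes_strand_symmetric(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 300)
        params = NUCLEOTIDE_PARAMS
        h_fwd = set(extract_minimizers(seq_to_codes(seq, params), params)[1].tolist())
        rc = reverse_complement(seq)
        h_rc = set(extract_minimizers(seq_to_codes(rc, params), params)[1].tolist())
        assert h_fwd == h_rc


class TestChaining:
    def test_colinear_anchors_form_one_chain(self):
        params = AlignParams(k=10)
        anchors = [Anchor(100 + 20 * i, 5 + 20 * i, 10) for i in range(20)]
        chains = chain_anchors(anchors, params)
        assert len(chains[0]) == 20

    def test_empty_input(self):
        assert chain_anchors([], NUCLEOTIDE_PARAMS) == []

    def test_matches_exhaustive_best_chain(self):
        params = AlignParams(k=10, min_chain_score=0.0, max_chains=1)
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            anchors = [
                Anchor(int(rng.integers(0, 400)), int(rng.integers(0, 400)), 10)
                for _ in range(n)
            ]
            anchors = list({(a.target_pos, a.query_pos): a for a in anchors}.values())
            chains = chain_anchors(anchors, params)
            got = chains[0].score if chains else 0.0
            want = oracles.best_chain_exhaustive(
                [(a.target_pos, a.query_pos) for a in anchors],
                params.k,
                params.gap_gamma,
                params.gap_open,
                params.gap_open_thresh,
                params.max_gap,
            )
            assert got == pytest.approx(want)


class TestExtension:
    def test_exact_substring_is_all_match(self):
        rng = np.random.default_rng(5)
        target = random_dna(rng, 2000)
        query = target[400:900]
        alns = align(query, {"t": target}, NUCLEOTIDE_PARAMS)
        a = alns[0]
        assert (a.q_start, a.q_end) == (0, 500)
        assert (a.t_start, a.t_end) == (400, 900)
        assert a.edit_dist == 0 and a.cigar == "500="

    def test_cigar_consumption_invariants_on_noisy_reads(self):
        rng = np.random.default_rng(6)
        target = random_dna(rng, 3000)
        for _ in range(5):
            s = int(rng.integers(0, 2000))
            read = list(target[s : s + 800])
            for p in rng.integers(0, 800, 60):
                read[p] = "ACGT"[rng.integers(0, 4)]
            for a in align("".join(read), {"t": target}, NUCLEOTIDE_PARAMS):
                qc, tc = cigar_consumed(a.cigar)
                assert qc == a.q_end - a.q_start
                assert tc == a.t_end - a.t_start


class TestMapq:
    def test_unchallenged_is_sixty(self):
        assert compute_mapq(100.0, None, 50) == 60

    def test_tied_runner_up_is_zero(self):
        assert compute_mapq(100.0, 100.0, 50) == 0

    def test_monotone_in_second_score(self):
        vals = [compute_mapq(100.0, s, 50) for s in np.linspace(0, 100, 21)]
        assert vals == sorted(vals, reverse=True)


class TestAlign:
    def test_reverse_complement_read_maps_minus(self):
        rng = np.random.default_rng(9)
        target = random_dna(rng, 5000)
        read = reverse_complement(target[1000:1600])
        a = align(read, {"t": target}, NUCLEOTIDE_PARAMS)[0]
        assert a.strand == "-"
        assert (a.t_start, a.t_end) == (1000, 1600)
        assert a.mapq == 60

    def test_duplicated_target_reports_secondary_and_low_mapq(self):
        rng = np.random.default_rng(10)
        unit = random_dna(rng, 1000)
        spacer = random_dna(rng, 1500)
        target = unit + spacer + unit + random_dna(rng, 500)
        alns = align(unit, {"t": target}, NUCLEOTIDE_PARAMS)
        assert len(alns) == 2
        starts = sorted((a.t_start, a.t_end) for a in alns)
        assert starts == [(0, 1000), (2500, 3500)]
        primary = [a for a in alns if a.primary][0]
        assert primary.mapq <= 5

    def test_unrelated_query_is_unmapped(self):
        rng = np.random.default_rng(12)
        target = random_dna(rng, 5000)
        query = random_dna(rng, 400)
        assert align(query, {"t": target}, NUCLEOTIDE_PARAMS) == []

    def test_error_free_sampling_recovers_truth(self):
        rng = np.random.default_rng(13)
        target = random_dna(rng, 20000)
        index = TargetIndex({"t": target}, NUCLEOTIDE_PARAMS)
        k, w = NUCLEOTIDE_PARAMS.k, NUCLEOTIDE_PARAMS.w
        for _ in range(10):
            s = int(rng.integers(0, 18000))
            ln = int(rng.integers(500, 2000))
            ln = min(ln, 20000 - s)
            a = align(target[s : s + ln], index)[0]
            assert abs(a.t_start - s) <= k + w
            assert abs(a.t_end - (s + ln)) <= k + w
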