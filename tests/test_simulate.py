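import numpy as np
import pytest

import quantalign as qa
from quantalign.quantize import reverse_complement
from quantalign.simulate import (
    SimConfig,
    confusable_pair,
    plant_svs,
    simulate_genome,
    simulate_reads,
    verify_confusable,
)


class TestGenome:
    def test_reproducible_per_seed(self):
        cfg = SimConfig(genome_length=10_000, seed=7)
        a = simulate_genome(cfg)["chr1"]
        b = simulate_genome(cfg)["chr1"]
        assert a == b and len(a) == 10_000
        c = simulate_genome(SimConfig(genome_length=10_000, seed=8))["chr1"]
        assert a != c

    def test_gc_content_near_target(self):
        n = 100_000
        g = simulate_genome(SimConfig(genome_length=n, seed=1, gc=0.5))["chr1"]
        gc = sum(b in "GC" for b in g) / n
        # binomial 3-sigma bound
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / n)


class TestPlantSvs:
    def test_zero_svs_is_identity(self):
        cfg = SimConfig(genome_length=20_000, seed=2, n_ins=0, n_del=0, n_inv=0)
        g = simulate_genome(cfg)
        mutated, truth = plant_svs(g, cfg)
        assert mutated == g and truth == []

    def test_deletion_conserves_length_exactly(self):
        cfg = SimConfig(
            genome_length=50_000, seed=3, n_ins=0, n_del=1, n_inv=0,
            sv_length_range=(100, 100),
        )
        g = simulate_genome(cfg)
        mutated, truth = plant_svs(g, cfg)
        assert len(mutated["chr1"]) == len(g["chr1"]) - 100
        assert truth[0].svtype == "DEL" and truth[0].length == 100

    def test_lengths_within_range_and_placements_separated(self):
        cfg = SimConfig(
            genome_length=200_000, seed=4, n_ins=5, n_del=5, n_inv=3,
            sv_length_range=(50, 2000),
        )
        g = simulate_genome(cfg)
        _, truth = plant_svs(g, cfg)
        assert all(50 <= t.length <= 2000 for t in truth)
        spans = sorted((t.start, t.end) for t in truth)
        assert all(b[0] - a[1] >= cfg.min_sv_separation for a, b in zip(spans, spans[1:]))

    def test_sequence_conserved_outside_svs(self):
        cfg = SimConfig(
            genome_length=50_000, seed=5, n_ins=0, n_del=0, n_inv=1,
            sv_length_range=(500, 500),
        )
        g = simulate_genome(cfg)
        mutated, truth = plant_svs(g, cfg)
        t = truth[0]
        assert mutated["chr1"][: t.start] == g["chr1"][: t.start]
        assert mutated["chr1"][t.end :] == g["chr1"][t.end :]
        assert mutated["chr1"][t.start : t.end] == reverse_complement(
            g["chr1"][t.start : t.end]
        )

    def test_impossible_layout_raises(self):
        cfg = SimConfig(
            genome_length=5000, seed=6, n_ins=0, n_del=40, n_inv=0,
            sv_length_range=(500, 500), min_sv_separation=1000,
        )
        g = {"chr1": simulate_genome(SimConfig(genome_length=5000, seed=6))["chr1"]}
        with pytest.raises(ValueError):
            plant_svs(g, cfg)


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, model6):
        cfg = SimConfig(
            genome_length=30_000, seed=9, coverage=1.0,
            sub_rate=0, ins_rate=0, del_rate=0,
        )
        g = simulate_genome(cfg)
        reads, truths = simulate_reads(g, cfg, model6)
        assert reads
        for (rid, seq), t in zip(reads, truths):
            frag = g["chr1"][t.start : t.end]
            if t.strand == "-":
                frag = reverse_complement(frag)
            assert seq == frag

    def test_realized_coverage_near_target(self, model6):
        cfg = SimConfig(genome_length=100_000, seed=10, coverage=8.0)
        g = simulate_genome(cfg)
        reads, _ = simulate_reads(g, cfg, model6)
        total = sum(len(s) for _, s in reads)
        assert abs(total / 100_000 - 8.0) / 8.0 < 0.10

    def test_overall_error_rate_near_config(self, model6):
        import edlib

        cfg = SimConfig(genome_length=60_000, seed=12, coverage=2.0, burst_rate=0.0)
        g = simulate_genome(cfg)
        reads, truths = simulate_reads(g, cfg, model6)
        rates = []
        for (rid, seq), t in zip(reads, truths):
            frag = g["chr1"][t.start : t.end]
            if t.strand == "-":
                frag = reverse_complement(frag)
            rates.append(edlib.align(seq, frag, mode="NW")["editDistance"] / len(seq))
        # sub 4% + ins 3% + del 3%, minus alignment slack
        assert 0.06 < np.mean(rates) < 0.12

    def test_confusion_bias_lowers_quantized_distance(self, model6, qcfg3):
        import edlib

        g = simulate_genome(SimConfig(genome_length=40_000, seed=13))

        def mean_qdist(weight):
            cfg = SimConfig(
                genome_length=40_000, seed=13, coverage=1.0,
                sub_rate=0.1, ins_rate=0, del_rate=0,
                confusion_weight=weight, burst_rate=0.0,
            )
            reads, truths = simulate_reads(g, cfg, model6)
            out = []
            for (rid, seq), t in zip(reads, truths):
                frag = g["chr1"][t.start : t.end]
                if t.strand == "-":
                    frag = reverse_complement(frag)
                q1 = qa.quantize_sequence(seq, model6, qcfg3).to_text()
                q2 = qa.quantize_sequence(frag, model6, qcfg3).to_text()
                out.append(edlib.align(q1, q2, mode="NW")["editDistance"] / len(q1))
            return np.mean(out)

        assert mean_qdist(1.0) < mean_qdist(0.0)


class TestConfusablePair:
    def test_postcondition(self, model6, qcfg3):
        a, b = confusable_pair(model6, qcfg3, length=20, seed=3)
        assert a != b
        assert verify_confusable(a, b, model6, qcfg3)

    def test_pair_exists_at_short_length_on_toy_model(self, model2, qcfg2):
        a, b = confusable_pair(model2, qcfg2, length=4, seed=1, budget=20_000)
        assert verify_confusable(a, b, model2, qcfg2)


def test_truth_vcf_round_trips(tmp_path, model6):
    from quantalign import io as qio

    cfg = SimConfig(
        genome_length=100_000, seed=14, n_ins=3, n_del=3, n_inv=2,
        sv_length_range=(50, 1500),
    )
    g = simulate_genome(cfg)
    _, truth = plant_svs(g, cfg)
    path = tmp_path / "truth.vcf"
    qio.write_vcf_sv(truth, {"chr1": 100_000}, path)
    back = qio.read_vcf_sv(path)
    key = lambda c: (c.chrom, c.start, c.svtype)
    for a, b in zip(sorted(truth, key=key), sorted(back, key=key)):
        assert (a.chrom, a.start, a.end, a.svtype, a.length) == (
            b.chrom, b.start, b.end, b.svtype, b.length,
        )
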