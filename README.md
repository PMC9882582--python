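# quantalign

Hybrid quantized alignment of nanopore long reads, built for
structural-variant (SV) discovery.

## The problem

Nanopore sequencers measure an ionic current that depends on the *Q*
consecutive bases in the pore (a *Q*-mer, here Q = 6), and many distinct
Q-mers produce nearly the same median current. Basecallers therefore make
*biased* errors: they confuse sequences whose current profiles are similar.
A conventional aligner treats those errors as independent noise and pays
full edit-distance price for them; near SV breakpoints and in repeats this
breaks alignments and ruins breakpoint accuracy.

`quantalign` exploits the bias instead of suffering it. Every nucleotide
sequence is translated through a **Q-mer pore model** (a table of
`4^Q` median currents in pA) into per-window current levels, which are
hard-thresholded into a **ternary quantized sequence** (three symbols,
equal-mass thresholds). Confusable sequences collapse onto the same symbol
string, so alignment in the quantized domain sees through exactly the
errors the pore physics makes. No raw signal is used — only the basecalled
sequence and the table.

## The method

Alignment is a two-stage hybrid:

1. **Nucleotide stage** — a minimizer seed–chain–extend pass
   (k = 15, w = 10, canonical seeds over both strands) locates regions of
   interest. A stage-1 hit covering target interval `[s, e)` of a read of
   length `n` with aligned fraction `f = (e − s)/n` is widened by

       b = (1 − f + 0.25) · n ,    s_q = s − b ,    e_q = e + b

   so a placement truncated by errors or an SV still fits in the window.
2. **Quantized stage** — the window and the read are quantized and
   re-aligned with the same engine over the ternary alphabet (k = 18,
   forward-only seeds). A symbol alphabet has no complement, so the
   **quantized reverse complement** of the read — which cannot be derived
   from the forward symbols — is aligned as a separate query. That is what
   makes *inversions* visible as opposite-strand split segments. Quantized
   coordinates are mapped back to nucleotides and the emitted CIGAR is
   re-derived by anchored nucleotide alignment (affine-gap fills keep long
   deletions/insertions as single runs).

Evaluation follows the standard SV-benchmarking metrics: a read is
**well-aligned** when its genome span covers ≥ 90% of the read with mapping
quality > 20; **normalized edit distance** is
`edit(read, G[i:j]) / len(read)` (always computed on nucleotides — only the
coordinates come from the quantized stage); the **breakpoint score** of a
call against a matched truth SV is `(|Δstart| + |Δend|)/2`; **length
similarity** is `min(L, L′)/max(L, L′)`; calls are matched Truvari-style
(same type, breakpoint score ≤ 500, length similarity ≥ 0.7, greedy by
breakpoint score) and summarized as precision/recall/F1; the **union
model** merges two call sets duplicate-aware to trade precision for recall.

A synthetic-data module generates the whole study bench: a structured
synthetic pore model (current-similar base pairs, the source of
confusability), genomes, planted INS/DEL/INV, and nanopore-like reads with
~10% errors whose substitutions are biased toward current-similar Q-mers,
including occasional current-equivalent "confusion bursts".

## Worked example

```python
import quantalign as qa

model = qa.synthetic_qmer_model(Q=6, seed=1)     # 4096 currents, ~90 pA
cfg   = qa.compute_thresholds(model, levels=3)   # ternary thresholds
print([round(t, 2) for t in cfg.thresholds])     # [81.46, 94.12]

# two different nucleotide sequences, identical in the quantized domain
a, b = qa.confusable_pair(model, cfg, length=20, seed=2)
print(a)                                         # CAGCGGTCAGTTTGCCAACC
print(b)                                         # CAGCGGTCAGTCTGCCAACC
print(qa.quantize_sequence(a, model, cfg).to_text())  # 112221012222100
print(qa.quantize_sequence(b, model, cfg).to_text())  # 112221012222100

# align a read carrying a planted inversion
genome = qa.simulate_genome(qa.SimConfig(genome_length=50_000, seed=3))
g = genome["chr1"]
read = g[20_000:21_000] + qa.reverse_complement(g[21_000:22_000]) + g[22_000:23_000]
aligner = qa.HybridAligner(genome, model, cfg)
for seg in aligner.align_read(read, "inv_read").alignments:
    print(seg.strand, seg.q_start, seg.q_end, seg.t_start, seg.t_end)
# + 0    1000  20000 21000
# + 2001 3000  22001 23000
# - 1005 2003  20997 21995     <- the inverted segment, opposite strand
```

The three segments recover the planted inversion: the middle of the read
aligns on the minus strand exactly over the inverted interval (21000–22000,
breakpoints within a few bases), which is the evidence the SV extractor
turns into an INV call.

A command-line surface wraps the same functions:

```bash
quantalign simulate --outdir sim/ --seed 5 --genome-length 60000 --coverage 8
quantalign align   --reads sim/reads.fastq --ref sim/genome.fa --model sim/model.tsv --out out.sam
quantalign call-sv --reads sim/reads.fastq --ref sim/genome.fa --model sim/model.tsv --out calls.vcf
quantalign eval-sv --calls calls.vcf --truth sim/truth.vcf --report report.tsv
```

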