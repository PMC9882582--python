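# Methods

## Quantization model

A pore model assigns each of the `4^Q` possible Q-mers (Q = 6 by default) a
median current in picoamperes. A nucleotide sequence of length `n` yields
`n − Q + 1` overlapping windows; window `i` is looked up in the table and
the resulting current series is hard-thresholded into `levels` symbols
(default 3). Thresholds are the equal-mass quantiles of the multiset of
`4^Q` currents — for three levels, the 1/3 and 2/3 empirical quantiles
(lower-quantile convention: the sorted value at index `floor(m·p)`). This
maximum-entropy choice is a documented stand-in: any strictly increasing
thresholds can be supplied through `QuantizerConfig`. A current exactly
equal to a threshold falls in the lower bin (arbitrary but fixed and
tested). Per-Q-mer standard deviations are stored when present in a model
file but are never used by quantization; no raw-signal information enters
anywhere.

Two consequences drive the whole design. First, quantization deliberately
loses information: distinct nucleotide sequences share a symbol string
whenever their current profiles agree, which is precisely the error mode of
a basecaller. Second, complementation does not commute with the Q-mer map,
so the quantized reverse complement of a read must be computed from the
nucleotides and aligned as a separate query; a symbol alphabet has no
strand symmetry.

Sequences containing non-ACGT characters are split into maximal ACGT runs
(runs shorter than Q are dropped) and each run is handled independently;
Q-mer lookup is undefined on ambiguity codes.

## Alignment engine

One alphabet-generic minimizer seed–chain–extend engine serves both
domains.

* **Seeding.** Window-minimum minimizers (leftmost minimum on ties) over an
  invertible 64-bit mixer of the base-`|alphabet|` k-mer code. Nucleotide
  mode: k = 15, w = 10, canonical (the lexicographically smaller of k-mer
  and reverse complement is hashed, strand recorded). Quantized mode:
  k = 18 — a ternary symbol carries less information than a base, so the
  seed is longer — w = 10, forward-only. Seeds hitting more than 200 index
  positions are skipped.
* **Chaining.** Exact dynamic program over anchors sorted by target then
  query position, with a 64-anchor look-back window. A link of gaps
  `(dt, dq)` earns `min(k, dt, dq)` and pays `0.02·|dt − dq|`, plus a flat
  opening penalty of 25 when `|dt − dq| > 25`. The concave (open + linear)
  form matters: one structural jump must beat a staircase of small spurious
  off-diagonal steps, which low-complexity ternary sequence offers in
  abundance. Links with `max(dt, dq) > 5000` are forbidden. Secondary
  chains are re-derived after removing used anchors (up to 5 chains, chain
  score ≥ 40 nucleotide / 36 quantized).
* **Block trimming.** Before extension, anchor blocks separated by diagonal
  jumps (> 25) are dropped unless they hold at least 3 anchors *and* at
  least one anchor per ~100 symbols of span; the largest block always
  survives. This removes stray anchors that max-sum chaining drags in
  across fake structural jumps.
* **Extension.** Inter-anchor gaps are bridged by banded global alignment
  (edlib; band starts at 64 or the length difference, doubles on overflow
  to a 4096 cap, then falls back to unbanded — so the reported distance
  equals the full dynamic program whenever the band suffices). A gap long
  on *both* axes whose edit excess over `|dt − dq|` exceeds 0.35 of the
  shorter side — or whose alignment contains a ≥ 200-column window that is
  ≥ 40% non-match, long indel runs not counted — splits the chain: such
  regions are rearranged (typically inverted), not merely divergent, and
  gluing them would hide the breakpoint. Ends are extended chunk-wise
  (256 symbols): each chunk must align within an edit rate of 0.30 or the
  extension stops, so a locally foreign block terminates the alignment
  instead of being averaged away by good flanks.
* **Scores and MAPQ.** Alignment score is +1 per match, −2 per mismatch,
  and an affine `4 + 0.05·len` per indel run, so a clean long deletion does
  not make a spanning alignment look worse than a short spurious one.
  Reported alignments are selected by chain score: candidates duplicating
  an already-kept placement (substantial overlap on both query and target)
  are dropped; new query segments become supplementary; re-placements of a
  kept segment become secondary and drive
  `mapq = clip(round(40·(1 − second/best))·min(1, anchors/10), 0, 60)`
  (60 when unchallenged).

## Hybrid pipeline

Stage 1 maps the nucleotide read and converts each alignment (primary and
secondaries, possibly on several chromosomes) into a region of interest
extended by `b = (1 − f + 0.25)·n`, where `f` is the aligned fraction
capped at 1 — a genome span inflated by a deletion must not produce a
negative extension, so `b ≥ 0.25·n` always. `b` is rounded to the nearest
integer and the window clamped to the target; overlapping windows on one
target are merged to avoid duplicate work.

Stage 2 quantizes each window once (cached) and aligns the forward
quantized read and its quantized reverse complement against it. Quantized
coordinates map back to nucleotides by widening with `Q − 1` (a symbol at
position `i` covers bases `[i, i + Q)`); reverse-orientation intervals are
mirrored within their window. Candidate segments shorter than 35 symbols or
with a small-edit rate above 0.35 (long indel runs excluded — a clean
alignment across a large deletion is evidence, not noise) are discarded as
the spurious mini-chains the repetitive ternary space produces.

The emitted nucleotide CIGAR is *stitched* through the quantized chain's
anchors: anchor runs become match/mismatch columns (compared base by
base), balanced gaps are filled with banded unit-cost alignment, and gaps
imbalanced by ≥ 40 bases are filled with an affine-gap alignment
(match 2, mismatch −4, open −12, extend −0.2, Biopython's PairwiseAligner)
so a structural indel stays one contiguous D/I run — unit-cost alignment
would shred it with spurious one-base matches, and the SV extractor
consumes contiguous runs. The stitched alignment's target boundaries float
freely at both ends, which settles the back-mapped interval (ambiguous to
within ~Q − 1) on its local edit-distance optimum.

Two conservative repairs follow. Tails the quantized stage left unaligned —
and that no other split segment claims — are retried with the nucleotide
chunked extension. Primaries without structural runs are re-placed by one
free-boundary alignment in a ±16 bp window, accepted only if the edit
distance does not increase. Breakpoint-carrying alignments are never
re-aligned. If stage 2 produces nothing at all, the stage-1 alignments are
returned flagged as fallback: a read mapped by the nucleotide stage is
never lost.

MAPQ of the final primary comes from quantized-stage chain competition
across all windows and both orientations.

## SV extraction, matching, union

Per-read evidence: CIGAR D/I runs ≥ 50 bp become DEL/INS candidates;
opposite-strand split segments of one read whose target intervals are
adjacent or overlapping (gap ≤ 1 kb) become INV candidates with the
minus-segment's interval; same-strand segment pairs with a one-sided gap
contribute split-read DEL/INS. Candidates are clustered per type and
chromosome (start within 500 bp of the cluster origin, or interval overlap
for span types). Within a cluster the *dominant length mode* — the largest
subgroup of mutually similar lengths (ratio ≥ 0.7), longer on ties — is
taken, because clipped segments and split runs contribute partial lengths
that would bias a plain median; a call requires ≥ 3 supporting reads and
reports the subgroup's median start and length.

Matching is simplified Truvari: candidate pairs need the same SV type,
breakpoint score ≤ 500 (`refdist`) and length similarity ≥ 0.7
(`pctsize`); pairs are assigned greedily in ascending breakpoint score,
each record once. Insertions compare by insertion-point distance and
inserted length. Genotypes are ignored throughout. Precision, recall and
F1 follow directly; an empty call set defines precision 0 with a warning.
The union model keeps all of set A plus every member of B not matching any
member of A (duplicates collapse to the A representative). Exclusion
regions (BED) drop calls on any overlap.

## Synthetic data

The generator is the study bench; its defaults are the conditions every
end-to-end result in this repository is computed under.

* **Pore model.** Real Q-mer maps are structured, not i.i.d.: the current
  is dominated by the bases nearest the constriction, and some base
  substitutions barely disturb it. The synthetic table is a position-
  weighted sum of base contributions — weights peaked off-center (the
  asymmetry keeps a reverse complement's profile unrelated to the forward
  one), with two base classes separated strongly and the two bases within
  a class nearly degenerate — plus an idiosyncratic noise term (30% of the
  12 pA spread) keyed on the class-reduced word, so an in-class swap leaves
  it unchanged. Under this table ~90% of positions admit a substitution
  that preserves the ternary quantization exactly: confusability is a
  property of the physics being emulated, not of table randomness. The
  trade-off is deliberate: the quantized alphabet cannot distinguish
  in-class bases, which is the information loss the method is designed to
  tolerate.
* **Genome and SVs.** I.i.d. bases at configurable GC (default 0.5).
  INS/DEL/INV placements are rejection-sampled with ≥ 1 kb separation
  (ambiguous overlapping truth intervals have no agreed matching
  convention); lengths uniform on a configurable range (50–10000 bp
  default, following the study design); truth coordinates are reported on
  the original reference so alignment-based calls are directly comparable.
  Inversions are reverse-complemented in place; insertions are random
  sequence.
* **Reads.** Uniform sampling, random strand, log-normal lengths (desk
  default: median 3 kb, σ = 0.5, minimum 1 kb). Errors total ~10%:
  substitutions 4%, insertions 3%, deletions 3%, applied per base.
  With probability `confusion_weight` (default 1) a substitution is the
  alternative minimizing the total current disturbance across all Q windows
  containing the base — evaluated against the clean read, sites treated
  independently. On top of the uniform background, rare **confusion
  bursts** (start probability 1e-4 per base, geometric mean length 300 bp,
  in-burst substitution density 0.5, always current-biased) emulate the
  documented phenomenon of whole segments basecalled as current-equivalent
  but heavily substituted words; ~3% of read bases fall in bursts. Bursts
  are what separates the two stages on hard reads: the nucleotide stage
  clips at a burst, the quantized stage aligns through it. Reads with all
  error rates zero are exact substrings. Quality strings are constant
  placeholders.
* **What the bench does not model.** Homopolymer-specific error inflation,
  base-quality information, diploidy/genotypes, raw signal, real R9.4
  currents, and real-genome repeat structure are all absent. Passing tests
  therefore demonstrate the pipeline's mechanics — ROI extension,
  inversion-aware quantized re-alignment, SV recovery and the metric
  definitions — under controlled confusable errors, not performance on
  real human data.

## Problem sizes and determinism

End-to-end experiments run at desk scale: SV recovery on a 200 kb genome
with 10 DEL + 10 INS + 5 INV (50–2000 bp) at 20× coverage (~1200 reads);
alignment-quality comparison on 150 kb at 5× with 10% substitution-only
confusable errors. Everything is driven by integer seeds through
`numpy.random.default_rng`; identical inputs give byte-identical SAM/PAF
output. Oracle tests pin the algorithmic cores to independent
implementations: banded extension against a quadratic edit-distance DP,
chaining against exhaustive best-chain search, greedy matching against
exhaustive optimal assignment, OLS against the closed form.

## Known limitations

The built-in engine is a readable reimplementation, not a performance
match for a production aligner; it is single-threaded Python/numpy with C
kernels only for base-level alignment. Quantized-stage specificity is
bounded by the reduced effective alphabet; highly repetitive real genomes
would need occurrence filtering beyond the per-seed cap used here. The SV
extractor is deliberately minimal plumbing (CIGAR runs plus split reads
with mode-based clustering) — it stands where a full SV caller would sit
in a production pipeline, and its calls are only as good as desk-scale
coverage allows. VCF output follows the htslib convention END = POS +
|SVLEN| for symbolic alleles; the reader treats SVLEN as authoritative for
span types.
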