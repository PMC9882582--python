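"""Structural-variant extraction and benchmarking.

Covers the evaluation layer around the aligner: alignment-quality metrics
(well-aligned fraction, normalized edit distance and alignment length), a
lightweight CIGAR/split-read SV extractor (plumbing standing in for a full
SV caller), simplified Truvari-style matching of call sets to a truth set,
breakpoint score, SV length similarity, precision/recall/F1, and the union
model that merges two methods' call sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .aligner import Alignment, cigar_ops, edit_distance


@dataclass
class SVCall:
    """One structural variant in 0-based half-open genome coordinates.

    For DEL/INV, length == end - start. For INS the inserted sequence does
    not exist on the reference, so end == start and length is the inserted
    length.
    """

    chrom: str
    start: int
    end: int
    svtype: str  # INS | DEL | INV
    length: int
    source: str = ""
    support: int = 1

    def __post_init__(self):
        assert self.svtype in ("INS", "DEL", "INV"), self.svtype
        assert self.end >= self.start
        if self.svtype == "INS":
            assert self.end == self.start
        else:
            assert self.length == self.end - self.start


@dataclass
class MatchResult:
    pairs: list[tuple[SVCall, SVCall]] = field(default_factory=list)  # (call, truth)
    fp: list[SVCall] = field(default_factory=list)
    fn: list[SVCall] = field(default_factory=list)


@dataclass
class PRFScores:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


# ---------------------------------------------------------------------------
# alignment-quality metrics


def is_well_aligned(alignment: Alignment, read_length: int) -> bool:
    """A read is well-aligned when its genome span covers at least 90% of
    the read length AND mapping quality exceeds 20 (strict)."""
    span = alignment.t_end - alignment.t_start
    return span >= 0.9 * read_length and alignment.mapq > 20


def normalized_edit_distance(
    read: str,
    genome: dict[str, str],
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    domain: str = "nucleotide",
) -> float:
    """edit_distance(entire read, genome slice) / read length.

    Always computed on nucleotide sequences; ``domain`` only records whether
    the (start, end) coordinates came from the nucleotide or the quantized
    alignment stage. For a minus-strand alignment the slice is
    reverse-complemented so both sequences are in read orientation.
    """
    from .quantize import reverse_complement

    if end <= start:
        raise ValueError("empty genome interval")
    del domain  # coordinates' provenance; the distance is always nucleotide
    sl = genome[chrom][start:end]
    if strand == "-":
        sl = reverse_complement(sl)
    return edit_distance(read, sl) / len(read)


def normalized_alignment_length(start: int, end: int, read_length: int) -> float:
    """Genome span of the alignment over read length; 1 means a contiguous
    full-length alignment, > 1 is possible when a deletion inflates the
    genome span."""
    assert read_length > 0
    return (end - start) / read_length


def regression_fit(xs, ys) -> tuple[float, float]:
    """Ordinary least-squares line; returns (slope, intercept)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or np.all(xs == xs[0]):
        raise ValueError("need >= 2 points with varying x")
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# SV candidate extraction (plumbing: CIGAR + split-read evidence)


def _cigar_events(aln: Alignment, min_len: int) -> list[SVCall]:
    out = []
    rpos = aln.t_start
    for n, op in cigar_ops(aln.cigar):
        if op in "=XM":
            rpos += n
        elif op == "D":
            if n >= min_len:
                out.append(
                    SVCall(aln.target_id, rpos, rpos + n, "DEL", n, source="cigar")
                )
            rpos += n
        elif op == "I":
            if n >= min_len:
                out.append(SVCall(aln.target_id, rpos, rpos, "INS", n, source="cigar"))
    return out


def _split_read_events(alns: list[Alignment], min_len: int) -> list[SVCall]:
    """Split-segment evidence from one read: opposite-strand segment pairs
    with adjacent target intervals imply an inversion; same-strand pairs
    with a target gap and little query gap imply a deletion (and vice versa
    an insertion)."""
    out = []
    if len(alns) < 2:
        return out
    segs = sorted(alns, key=lambda a: (a.target_id, a.t_start))
    backbone = max(alns, key=lambda a: a.q_end - a.q_start)
    for a in segs:
        if a is backbone or a.target_id != backbone.target_id:
            continue
        if a.strand != backbone.strand:
            # inverted segment: its own target interval is the INV interval,
            # required to be adjacent/overlapping the backbone's
            gap = max(a.t_start, backbone.t_start) - min(a.t_end, backbone.t_end)
            L = a.t_end - a.t_start
            if gap <= 1000 and L >= min_len:
                out.append(SVCall(a.target_id, a.t_start, a.t_end, "INV", L, "split"))
    # same-strand ordered pairs -> DEL/INS between segment ends
    same = [a for a in segs if a.strand == backbone.strand]
    same.sort(key=lambda a: a.q_start if backbone.strand == "+" else -a.q_end)
    for a, b in zip(same, same[1:]):
        tgap = b.t_start - a.t_end
        qgap = (b.q_start - a.q_end) if backbone.strand == "+" else (a.q_start - b.q_end)
        if tgap >= min_len and qgap < min_len and qgap > -50:
            out.append(SVCall(a.target_id, a.t_end, a.t_end + tgap, "DEL", tgap, "split"))
        elif qgap >= min_len and tgap < min_len and tgap > -50:
            out.append(SVCall(a.target_id, a.t_end, a.t_end, "INS", qgap, "split"))
    return out


def extract_sv_candidates(
    per_read_alignments: list[list[Alignment]],
    min_len: int = 50,
    min_support: int = 3,
    cluster_dist: int = 500,
) -> list[SVCall]:
    """Per-read SV evidence from CIGAR runs (D/I >= min_len) and split
    segments, clustered across reads by type/locus; clusters supported by at
    least ``min_support`` reads become calls at the cluster's median
    coordinates and length."""
    raw: list[SVCall] = []
    for alns in per_read_alignments:
        for aln in alns:
            raw.extend(_cigar_events(aln, min_len))
        raw.extend(_split_read_events(alns, min_len))
    raw.sort(key=lambda c: (c.svtype, c.chrom, c.start))
    calls: list[SVCall] = []
    cluster: list[SVCall] = []

    def flush():
        if len(cluster) >= min_support:
            # partial evidence (clipped segments, split I/D runs) biases a
            # plain median; use the dominant length mode — the largest
            # subgroup of mutually similar lengths, longer on ties
            lens = sorted(c.length for c in cluster)
            best = (0, 0, 0)
            i = 0
            for j in range(len(lens)):
                while lens[i] < 0.7 * lens[j]:
                    i += 1
                if j - i + 1 >= best[0]:
                    best = (j - i + 1, lens[i], lens[j])
            group = [c for c in cluster if best[1] <= c.length <= best[2]]
            if len(group) >= min_support:
                starts = sorted(c.start for c in group)
                glens = sorted(c.length for c in group)
                start = starts[len(starts) // 2]
                length = glens[len(glens) // 2]
                c0 = group[0]
                end = start if c0.svtype == "INS" else start + length
                calls.append(
                    SVCall(c0.chrom, start, end, c0.svtype, length, c0.source,
                           len(group))
                )
        cluster.clear()

    cluster_end = 0
    for c in raw:
        near = (
            cluster
            and c.svtype == cluster[0].svtype
            and c.chrom == cluster[0].chrom
            and (
                c.start - cluster[0].start <= cluster_dist
                or (c.svtype != "INS" and c.start < cluster_end)
            )
        )
        if near:
            cluster.append(c)
            cluster_end = max(cluster_end, c.end)
        else:
            flush()
            cluster.append(c)
            cluster_end = c.end
    flush()
    return calls


# ---------------------------------------------------------------------------
# Truvari-style matching


def breakpoint_score(call: SVCall, truth: SVCall) -> float:
    """Mean absolute offset of the start and end breakpoints; lower is a
    more accurate breakpoint."""
    if call.chrom != truth.chrom:
        raise ValueError("breakpoint score is undefined across chromosomes")
    return (abs(call.start - truth.start) + abs(call.end - truth.end)) / 2.0


def length_similarity(call: SVCall, truth: SVCall) -> float:
    """min(L1, L2) / max(L1, L2), in (0, 1]; symmetric."""
    if call.length <= 0 or truth.length <= 0:
        raise ValueError("SV lengths must be positive")
    return min(call.length, truth.length) / max(call.length, truth.length)


def match_calls(
    calls: list[SVCall],
    truths: list[SVCall],
    refdist: int = 500,
    pctsize: float = 0.7,
) -> MatchResult:
    """Greedy one-to-one matching: candidate pairs need the same SV type,
    breakpoint score <= refdist and length similarity >= pctsize; pairs are
    assigned in ascending breakpoint score, each record used once."""
    cand: list[tuple[float, int, int]] = []
    for i, c in enumerate(calls):
        for j, t in enumerate(truths):
            if c.svtype != t.svtype or c.chrom != t.chrom:
                continue
            bs = breakpoint_score(c, t)
            if bs <= refdist and length_similarity(c, t) >= pctsize:
                cand.append((bs, i, j))
    cand.sort(key=lambda x: (x[0], x[1], x[2]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    res = MatchResult()
    for bs, i, j in cand:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        res.pairs.append((calls[i], truths[j]))
    res.fp = [c for i, c in enumerate(calls) if i not in used_c]
    res.fn = [t for j, t in enumerate(truths) if j not in used_t]
    return res


def prf(match: MatchResult) -> PRFScores:
    tp = len(match.pairs)
    fp = len(match.fp)
    fn = len(match.fn)
    if tp + fp == 0:
        warnings.warn("empty call set: precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = f1_score(precision, recall)
    return PRFScores(precision, recall, f1, tp, fp, fn)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def union_calls(
    set_a: list[SVCall],
    set_b: list[SVCall],
    refdist: int = 500,
    pctsize: float = 0.7,
) -> list[SVCall]:
    """Union model: all of set A, plus every member of set B that does not
    match any member of A; duplicates collapse to the A representative."""
    m = match_calls(set_b, set_a, refdist=refdist, pctsize=pctsize)
    return list(set_a) + list(m.fp)


def exclude_regions(calls: list[SVCall], bed_regions) -> list[SVCall]:
    """Drop calls overlapping any excluded region (any-overlap rule).

    ``bed_regions`` is an iterable of (chrom, start, end). INS calls are
    points; they are dropped when the insertion point falls inside a
    region."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in bed_regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = []
    for c in calls:
        tree = trees.get(c.chrom)
        end = c.end if c.end > c.start else c.start + 1
        if tree is None or not tree.overlap(c.start, end):
            kept.append(c)
    return kept
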