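"""The two-stage hybrid alignment strategy.

Stage 1 aligns the nucleotide read with the standard (canonical,
alphabet-4) engine to locate regions of interest (ROIs) on the genome.
Each ROI is widened by b = (1 - f + 0.25) * n, where f is the fraction of
the read covered by the stage-1 alignment and n the read length, so that a
read whose placement was truncated by errors or a structural variant still
fits inside the window.

Stage 2 quantizes the read (both orientations — the quantized reverse
complement must be computed from nucleotides) and the ROI windows, and
re-aligns in ternary symbol space with a longer minimizer (k = 18).
Quantized coordinates are mapped back to nucleotide coordinates, and the
emitted CIGAR is re-derived by banded global alignment of the implied
nucleotide substrings, so downstream SV extraction works on ordinary
nucleotide alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align as _bio_align

from .aligner import (
    Alignment,
    NUCLEOTIDE_PARAMS,
    QUANTIZED_PARAMS,
    AlignParams,
    TargetIndex,
    _extend_left,
    _extend_right,
    align,
    alignment_score,
    banded_global,
    cigar_ops,
    compute_mapq,
    merge_cigar,
    select_alignments,
)
from .pore_model import QmerModel, QuantizerConfig
from .quantize import (
    quantize_sequence,
    quantized_reverse_complement,
    reverse_complement,
)


@dataclass
class RegionOfInterest:
    """Stage-1 hit on the target, plus its extension for stage 2."""

    target_id: str
    s: int              # stage-1 alignment interval (0-based half-open)
    e: int
    f: float            # aligned fraction of the read, capped at 1
    b: int              # extension length
    s_q: int            # extended, clamped window
    e_q: int
    read_length: int
    strand_hint: str = "+"


def extend_roi(s: int, e: int, n: int, target_length: int) -> tuple[int, int]:
    """Widen a stage-1 interval by b = (1 - f + 0.25) * n, clamped to the
    target. f is capped at 1 first (a deletion-inflated genome span must not
    produce a negative extension), so b >= 0.25 * n always."""
    assert 0 <= s <= e <= target_length and n > 0
    f = min(1.0, (e - s) / n)
    b = round((1.0 - f + 0.25) * n)
    return max(0, s - b), min(target_length, e + b)


def find_rois(
    read: str,
    genome: dict[str, str] | TargetIndex,
    params: AlignParams | None = None,
) -> list[RegionOfInterest]:
    """Stage-1 alignment -> one ROI per alignment (primary and secondary,
    possibly on different chromosomes); overlapping extended windows on the
    same target are merged. Empty list = read unmapped in stage 1."""
    rois, _ = _find_rois_with_stage1(read, genome, params)
    return rois


def _find_rois_with_stage1(
    read: str,
    genome: dict[str, str] | TargetIndex,
    params: AlignParams | None = None,
):
    index = genome if isinstance(genome, TargetIndex) else TargetIndex(
        genome, params or NUCLEOTIDE_PARAMS
    )
    step1 = align(read, index)
    return rois_from_alignments(step1, index.lengths, len(read)), step1


def rois_from_alignments(
    alignments: list[Alignment], target_lengths: dict[str, int], n: int
) -> list[RegionOfInterest]:
    rois: list[RegionOfInterest] = []
    for aln in alignments:
        tl = target_lengths[aln.target_id]
        s_q, e_q = extend_roi(aln.t_start, aln.t_end, n, tl)
        f = min(1.0, (aln.t_end - aln.t_start) / n)
        rois.append(
            RegionOfInterest(
                target_id=aln.target_id,
                s=aln.t_start,
                e=aln.t_end,
                f=f,
                b=round((1.0 - f + 0.25) * n),
                s_q=s_q,
                e_q=e_q,
                read_length=n,
                strand_hint=aln.strand,
            )
        )
    # merge overlapping extended windows per target to avoid duplicate work
    merged: list[RegionOfInterest] = []
    for roi in sorted(rois, key=lambda r: (r.target_id, r.s_q)):
        if (
            merged
            and merged[-1].target_id == roi.target_id
            and roi.s_q <= merged[-1].e_q
        ):
            prev = merged[-1]
            prev.e_q = max(prev.e_q, roi.e_q)
            prev.e = max(prev.e, roi.e)
            prev.s = min(prev.s, roi.s)
        else:
            merged.append(roi)
    return merged


def map_quantized_interval(
    q_start: int,
    q_end: int,
    window_start: int,
    strand: str,
    Q: int,
    window_nt_length: int | None = None,
) -> tuple[int, int]:
    """Quantized-coordinate interval -> nucleotide interval (half-open).

    A quantized symbol at position i covers nucleotides [i, i + Q), so a
    quantized interval widens by Q - 1 on the nucleotide axis. The reverse
    branch maps an interval expressed on the reverse-complement-derived
    quantized sequence of a window back onto the forward window.
    """
    if q_start >= q_end:
        raise ValueError("empty quantized interval")
    if strand == "+":
        lo, hi = q_start, q_end + Q - 1
    else:
        if window_nt_length is None:
            raise ValueError("reverse mapping requires the window length")
        lo = window_nt_length - (q_end + Q - 1)
        hi = window_nt_length - q_start
    if lo < 0 or (window_nt_length is not None and hi > window_nt_length):
        raise ValueError("quantized interval outside window")
    return window_start + lo, window_start + hi


# ---------------------------------------------------------------------------
# nucleotide CIGAR stitching
#
# The emitted CIGAR is rebuilt in nucleotide space through the quantized
# chain's anchors. Gaps that are balanced on both axes are filled with
# unit-cost banded alignment; gaps dominated by one axis (structural indels)
# are filled with an AFFINE-gap alignment so a long deletion/insertion stays
# one contiguous D/I run instead of being shredded by spurious unit-cost
# matches — downstream SV extraction depends on contiguous runs.

_AFFINE = _bio_align.PairwiseAligner()
_AFFINE.mode = "global"
_AFFINE.match_score = 2
_AFFINE.mismatch_score = -4
_AFFINE.open_gap_score = -12
_AFFINE.extend_gap_score = -0.2

_INDEL_GAP = 40  # |dq - dt| beyond which a gap is treated as structural


def _small_edit_rate(cigar: str) -> float:
    """Error rate over the aligned columns, NOT counting indel runs of
    structural size (>= _INDEL_GAP): a clean alignment through a large
    deletion or insertion is high-quality evidence, not noise."""
    good = bad = 0
    for n, op in cigar_ops(cigar):
        if op == "=":
            good += n
        elif op == "X" or (op in "ID" and n < _INDEL_GAP):
            bad += n
    total = good + bad
    return bad / total if total else 1.0


def _match_cigar(a: str, b: str) -> tuple[str, int]:
    """Equal-length comparison -> =/X run-length CIGAR and mismatch count."""
    if not a:
        return "", 0
    x = np.frombuffer(a.encode(), dtype=np.uint8) != np.frombuffer(
        b.encode(), dtype=np.uint8
    )
    bounds = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [x.size]))
    cig = "".join(
        f"{e - s}{'X' if x[s] else '='}" for s, e in zip(starts, ends)
    )
    return cig, int(x.sum())


def _affine_fill(gq: str, gt: str) -> tuple[str, int]:
    aln = _AFFINE.align(gq, gt)[0]
    qb, tb = aln.aligned
    parts: list[str] = []
    edits = 0
    qp = tp = 0
    for (qs, qe), (ts, te) in zip(qb, tb):
        if qs > qp:
            parts.append(f"{qs - qp}I")
            edits += qs - qp
        if ts > tp:
            parts.append(f"{ts - tp}D")
            edits += ts - tp
        mc, md = _match_cigar(gq[qs:qe], gt[ts:te])
        parts.append(mc)
        edits += md
        qp, tp = qe, te
    if len(gq) > qp:
        parts.append(f"{len(gq) - qp}I")
        edits += len(gq) - qp
    if len(gt) > tp:
        parts.append(f"{len(gt) - tp}D")
        edits += len(gt) - tp
    return merge_cigar(parts), edits


def _fill_gap(gq: str, gt: str, band: int) -> tuple[str, int]:
    if not gq and not gt:
        return "", 0
    if not gq:
        return f"{len(gt)}D", len(gt)
    if not gt:
        return f"{len(gq)}I", len(gq)
    if abs(len(gq) - len(gt)) >= _INDEL_GAP:
        return _affine_fill(gq, gt)
    d, cig = banded_global(gq, gt, band)
    return cig, d


def _anchor_runs(
    anchors: list[tuple[int, int]],
    span: int,
    q_off: int,
    t_off: int,
    qlen: int,
    tlen: int,
) -> list[tuple[int, int, int]]:
    """Quantized anchors -> merged exact diagonal runs in the stitching
    frame; conflicting overlaps are dropped."""
    runs: list[tuple[int, int, int]] = []
    for aq, at in anchors:
        rq, rt = aq - q_off, at + t_off
        if rq < 0 or rt < 0:
            continue
        ln = min(span, qlen - rq, tlen - rt)
        if ln <= 0:
            continue
        if runs:
            pq, pt, pl = runs[-1]
            if rt - rq == pt - pq and rq <= pq + pl:
                runs[-1] = (pq, pt, max(pl, rq + ln - pq))
                continue
            if rq < pq + pl or rt < pt + pl:
                continue
        runs.append((rq, rt, ln))
    return runs


def _stitch(
    read_sub: str,
    target_sub: str,
    runs: list[tuple[int, int, int]],
    band: int,
) -> tuple[int, int, str, int]:
    """Anchored piecewise alignment of read_sub against target_sub.

    The query is consumed fully; the target interval floats at both ends
    (free-end alignment), which refines the back-mapped boundaries to their
    local optimum. Returns (t_start, t_end, cigar, edits) relative to
    target_sub.
    """
    parts: list[str] = []
    edits = 0
    q0, t0 = runs[0][0], runs[0][1]
    gq, avail = read_sub[:q0], target_sub[:t0]
    if gq:
        if avail:
            res = edlib.align(gq[::-1], avail[::-1], mode="SHW", task="path")
            parts.append(
                "".join(f"{n}{o}" for n, o in cigar_ops(res["cigar"])[::-1])
            )
            edits += res["editDistance"]
            t_start = t0 - (res["locations"][0][1] + 1)
        else:
            parts.append(f"{len(gq)}I")
            edits += len(gq)
            t_start = t0
    else:
        t_start = t0
    qpos, tpos = q0, t0
    for rq, rt, rl in runs:
        cig, d = _fill_gap(read_sub[qpos:rq], target_sub[tpos:rt], band)
        parts.append(cig)
        edits += d
        mc, md = _match_cigar(read_sub[rq : rq + rl], target_sub[rt : rt + rl])
        parts.append(mc)
        edits += md
        qpos, tpos = rq + rl, rt + rl
    gq, avail = read_sub[qpos:], target_sub[tpos:]
    if gq:
        if avail:
            res = edlib.align(gq, avail, mode="SHW", task="path")
            parts.append(res["cigar"])
            edits += res["editDistance"]
            t_end = tpos + res["locations"][0][1] + 1
        else:
            parts.append(f"{len(gq)}I")
            edits += len(gq)
            t_end = tpos
    else:
        t_end = tpos
    return t_start, t_end, merge_cigar(parts), edits


@dataclass
class HybridResult:
    """Everything the evaluator needs about one read: the stage-1
    (nucleotide) alignments, the ROIs, and the final hybrid alignments in
    nucleotide coordinates."""

    read_id: str
    read_length: int
    step1: list[Alignment] = field(default_factory=list)
    rois: list[RegionOfInterest] = field(default_factory=list)
    alignments: list[Alignment] = field(default_factory=list)

    @property
    def primary(self) -> Alignment | None:
        for a in self.alignments:
            if a.primary:
                return a
        return self.alignments[0] if self.alignments else None

    @property
    def step1_primary(self) -> Alignment | None:
        for a in self.step1:
            if a.primary:
                return a
        return self.step1[0] if self.step1 else None


class HybridAligner:
    """Reusable two-stage aligner: builds the nucleotide genome index once,
    then maps reads one at a time."""

    def __init__(
        self,
        genome: dict[str, str],
        model: QmerModel,
        cfg: QuantizerConfig,
        nt_params: AlignParams = NUCLEOTIDE_PARAMS,
        q_params: AlignParams = QUANTIZED_PARAMS,
    ):
        self.genome = genome
        self.model = model
        self.cfg = cfg
        self.q_params = q_params
        self.min_segment_span = 35  # quantized symbols; ~40 nt, below the
        # 50 bp floor of reportable SVs
        self.index = TargetIndex(genome, nt_params)
        self._win_cache: dict[tuple[str, int, int], str] = {}

    # -- helpers ----------------------------------------------------------

    def _quantized_window(self, tid: str, s_q: int, e_q: int) -> str:
        key = (tid, s_q, e_q)
        if key not in self._win_cache:
            if len(self._win_cache) > 256:
                self._win_cache.clear()
            seq = self.genome[tid][s_q:e_q]
            self._win_cache[key] = quantize_sequence(seq, self.model, self.cfg).to_text()
        return self._win_cache[key]

    # -- main entry -------------------------------------------------------

    def align_read(self, read: str, read_id: str = "") -> HybridResult:
        n = len(read)
        res = HybridResult(read_id=read_id, read_length=n)
        Q = self.model.Q
        if n < Q + self.q_params.k - 1:
            return res
        rois, step1 = _find_rois_with_stage1(read, self.index)
        res.step1 = step1
        res.rois = rois
        if not rois:
            return res

        q_fwd = quantize_sequence(read, self.model, self.cfg).to_text()
        q_rc = quantized_reverse_complement(read, self.model, self.cfg).to_text()
        rc_read = reverse_complement(read)

        candidates: list[Alignment] = []
        for roi in rois:
            win_text = self._quantized_window(roi.target_id, roi.s_q, roi.e_q)
            if len(win_text) < self.q_params.k:
                continue
            win_index = TargetIndex({roi.target_id: win_text}, self.q_params)
            for strand, qtext in (("+", q_fwd), ("-", q_rc)):
                for qaln in align(qtext, win_index, query_id=read_id):
                    # spurious mini-chains are common in the repetitive
                    # ternary space: require a minimal quantized span and a
                    # plausible nucleotide identity before trusting a segment
                    if qaln.q_end - qaln.q_start < self.min_segment_span:
                        continue
                    nt = self._to_nucleotide(qaln, roi, strand, read, rc_read, n, Q)
                    if nt is None:
                        continue
                    if _small_edit_rate(nt.cigar) > 0.35:
                        continue
                    candidates.append(nt)

        if not candidates:
            # stage 2 found nothing anywhere: fall back to stage 1 so a read
            # mapped by the nucleotide stage is never lost
            for a in step1:
                a.fallback = True
            res.alignments = step1
            return res

        # mapq of the primary from quantized-stage chain competition
        kept, second = select_alignments(candidates)
        primary = kept[0]
        primary.mapq = compute_mapq(primary.chain_score, second, primary.anchor_count)
        self._heal_clipped_ends(primary, kept, read, rc_read)
        res.alignments = kept
        return res

    def _heal_clipped_ends(
        self,
        aln: Alignment,
        kept: list[Alignment],
        read: str,
        rc_read: str,
    ) -> None:
        """Occasionally the quantized chain ends short of the read end and
        the symbol-space extension gives up; retry the unaligned tails in
        NUCLEOTIDE space (chunked, same acceptance rate). Only tails not
        claimed by another split segment are touched, so breakpoints of
        split (e.g. inverted) alignments stay where the quantized stage put
        them."""
        n = len(read)
        if aln.q_start == 0 and aln.q_end == n:
            return
        oriented = read if aln.strand == "+" else rc_read
        oq_s = aln.q_start if aln.strand == "+" else n - aln.q_end
        oq_e = aln.q_end if aln.strand == "+" else n - aln.q_start
        others = [o for o in kept if o is not aln]
        # a side is free when no other segment covers query there
        if aln.strand == "+":
            left_cov = any(o.q_start < aln.q_start for o in others)
            right_cov = any(o.q_end > aln.q_end for o in others)
        else:
            left_cov = any(o.q_end > aln.q_end for o in others)
            right_cov = any(o.q_start < aln.q_start for o in others)
        target = self.genome[aln.target_id]
        cig_l = cig_r = ""
        d_l = d_r = 0
        t_s, t_e = aln.t_start, aln.t_end
        if oq_s > 0 and not left_cov:
            oq_s, t_s, cig_l, d_l = _extend_left(
                oriented, target, oq_s, t_s, NUCLEOTIDE_PARAMS
            )
        if oq_e < n and not right_cov:
            oq_e, t_e, cig_r, d_r = _extend_right(
                oriented, target, oq_e, t_e, NUCLEOTIDE_PARAMS
            )
        if cig_l or cig_r:
            aln.cigar = merge_cigar([cig_l, aln.cigar, cig_r])
            aln.t_start, aln.t_end = t_s, t_e
            if aln.strand == "+":
                aln.q_start, aln.q_end = oq_s, oq_e
            else:
                aln.q_start, aln.q_end = n - oq_e, n - oq_s
            aln.edit_dist += d_l + d_r
            aln.score = alignment_score(aln.cigar)
            aln.check()
        self._polish_plain_primary(aln, oriented)

    def _polish_plain_primary(self, aln: Alignment, oriented: str) -> None:
        """Final boundary polish for alignments WITHOUT structural indel
        runs: re-place the aligned read portion by free-boundary (infix)
        alignment in a slightly padded window, which finds the globally
        optimal target interval where greedy chunked extension can be a few
        edits off. Alignments carrying runs >= the SV floor are left
        untouched so breakpoints are not re-shredded by unit-cost
        realignment."""
        if any(op in "ID" and x >= _INDEL_GAP for x, op in cigar_ops(aln.cigar)):
            return
        n = aln.query_length
        oq_s = aln.q_start if aln.strand == "+" else n - aln.q_end
        oq_e = aln.q_end if aln.strand == "+" else n - aln.q_start
        read_sub = oriented[oq_s:oq_e]
        if not read_sub:
            return
        target = self.genome[aln.target_id]
        pad = 16
        lo = max(0, aln.t_start - pad)
        hi = min(len(target), aln.t_end + pad)
        res = edlib.align(read_sub, target[lo:hi], mode="HW", task="path")
        if res["editDistance"] < 0 or res["editDistance"] > aln.edit_dist:
            return
        loc = res["locations"][0]
        aln.t_start, aln.t_end = lo + loc[0], lo + loc[1] + 1
        aln.cigar = res["cigar"]
        aln.edit_dist = res["editDistance"]
        aln.score = alignment_score(aln.cigar)
        aln.check()

    def _to_nucleotide(
        self,
        qaln: Alignment,
        roi: RegionOfInterest,
        strand: str,
        read: str,
        rc_read: str,
        n: int,
        Q: int,
    ) -> Alignment | None:
        """Back-map one quantized alignment into nucleotide coordinates and
        re-derive its CIGAR on the nucleotide substrings."""
        try:
            t_lo, t_hi = map_quantized_interval(
                qaln.t_start, qaln.t_end, roi.s_q, "+", Q
            )
        except ValueError:
            return None
        tlen = len(self.genome[roi.target_id])
        t_hi = min(t_hi, tlen)
        if strand == "+":
            q_lo, q_hi = qaln.q_start, min(qaln.q_end + Q - 1, n)
            read_sub = read[q_lo:q_hi]
        else:
            # interval on the RC read -> original read coordinates
            rc_lo, rc_hi = qaln.q_start, min(qaln.q_end + Q - 1, n)
            q_lo, q_hi = n - rc_hi, n - rc_lo
            read_sub = rc_read[rc_lo:rc_hi]
        if not read_sub:
            return None
        # Quantized coordinates resolve the target interval only to within
        # ~(Q - 1) bases; pad the window and let the stitched alignment's
        # free ends settle on the locally optimal nucleotide boundaries.
        pad = Q + 10
        t_lo_p = max(0, t_lo - pad)
        t_hi_p = min(tlen, t_hi + pad)
        target_sub = self.genome[roi.target_id][t_lo_p:t_hi_p]
        if not target_sub:
            return None
        runs = []
        if qaln.anchors_qt:
            runs = _anchor_runs(
                qaln.anchors_qt,
                span=self.q_params.k + Q - 1,
                q_off=qaln.q_start,
                t_off=roi.s_q - t_lo_p,
                qlen=len(read_sub),
                tlen=len(target_sub),
            )
        if runs:
            rel_lo, rel_hi, cigar, edits = _stitch(
                read_sub, target_sub, runs, self.q_params.band
            )
            t_lo, t_hi = t_lo_p + rel_lo, t_lo_p + rel_hi
        else:
            # no usable anchors: plain infix alignment
            res = edlib.align(read_sub, target_sub, mode="HW", task="path")
            loc = res["locations"][0]
            t_lo, t_hi = t_lo_p + loc[0], t_lo_p + loc[1] + 1
            edits, cigar = res["editDistance"], res["cigar"]
        aln = Alignment(
            query_id=qaln.query_id,
            target_id=roi.target_id,
            strand=strand,
            q_start=q_lo,
            q_end=q_hi,
            t_start=t_lo,
            t_end=t_hi,
            cigar=cigar,
            score=alignment_score(cigar),
            edit_dist=edits,
            mapq=0,
            domain="quantized",
            primary=False,
            query_length=n,
            chain_score=qaln.chain_score,
            anchor_count=qaln.anchor_count,
        )
        aln.check()
        return aln


def hybrid_align(
    read: str,
    genome: dict[str, str],
    model: QmerModel,
    cfg: QuantizerConfig,
    q_params: AlignParams = QUANTIZED_PARAMS,
    read_id: str = "",
) -> list[Alignment]:
    """One-shot convenience wrapper; for many reads against one genome use
    HybridAligner directly so the genome index is built once."""
    return HybridAligner(genome, model, cfg, q_params=q_params).align_read(
        read, read_id
    ).alignments


def align_batch(
    reads_path,
    genome_path,
    model: QmerModel,
    cfg: QuantizerConfig,
    out_sam=None,
    out_paf=None,
    q_params: AlignParams = QUANTIZED_PARAMS,
    log=None,
) -> list[HybridResult]:
    """Hybrid-align every read in a FASTQ/FASTA file, in input order, and
    write SAM and/or PAF. Unmapped reads become unmapped SAM records.
    Deterministic: same inputs give byte-identical outputs."""
    from . import io as qio

    genome = {r.name: r.sequence.upper() for r in qio.read_fasta(genome_path)}
    try:
        reads = qio.read_fastq(reads_path)
    except ValueError:
        reads = qio.read_fasta(reads_path)
    reads = [qio.SeqRecord(r.name, r.sequence.upper(), r.quality) for r in reads]
    aligner = HybridAligner(genome, model, cfg, q_params=q_params)
    results = []
    n_mapped = n_fallback = 0
    for rec in reads:
        res = aligner.align_read(rec.sequence, rec.name)
        results.append(res)
        if res.alignments:
            n_mapped += 1
            if res.alignments[0].fallback:
                n_fallback += 1
    if log is not None:
        log(
            f"reads={len(reads)} mapped={n_mapped} "
            f"unmapped={len(reads) - n_mapped} fallback={n_fallback}"
        )
    tlens = {n: len(s) for n, s in genome.items()}
    if out_sam:
        qio.write_sam(
            [(rec, res.alignments) for rec, res in zip(reads, results)], tlens, out_sam
        )
    if out_paf:
        qio.write_paf(
            [a for res in results for a in res.alignments], tlens, out_paf
        )
    return results
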