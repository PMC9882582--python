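"""Alphabet-generic minimizer seed-chain-extend alignment engine.

The same engine serves the nucleotide stage (alphabet size 4, canonical
minimizers over both strands) and the quantized stage (alphabet size 3,
forward-only minimizers: a symbol alphabet derived from currents has no
complement, so the caller must supply the reverse-complement-derived query
as a separate sequence).

Base-level gap filling and end extension are delegated to edlib's banded
bit-parallel alignment; seeding, chaining and mapping-quality logic live
here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .quantize import encode_bases, reverse_complement, rolling_kmer_codes

# ---------------------------------------------------------------------------
# parameters and records


@dataclass(frozen=True)
class AlignParams:
    k: int = 15                 # minimizer k-mer length
    w: int = 10                 # minimizer window
    alphabet_size: int = 4
    canonical: bool = True      # strand-canonical minimizers (nucleotide mode)
    max_gap: int = 5000         # max anchor-to-anchor gap for chaining
    band: int = 64              # initial extension band half-width
    min_chain_score: float = 40.0
    gap_gamma: float = 0.02     # chain gap cost per |dt - dq| unit
    gap_open: float = 25.0      # extra cost per link whose diagonal shift
    gap_open_thresh: int = 25   # exceeds this — one big structural jump must
    # beat a staircase of small spurious off-diagonal steps
    max_chains: int = 5
    lookback: int = 64          # chaining predecessor window
    split_min_gap: int = 40     # min gap (both sides) to test for a chain split
    split_max_rate: float = 0.35  # gap edit rate above which the chain splits
    tail_max_rate: float = 0.30   # end-extension acceptance edit rate

    def __post_init__(self):
        assert self.k >= 1 and self.w >= 1 and self.alphabet_size >= 2
        assert self.k * np.log2(self.alphabet_size) <= 62


NUCLEOTIDE_PARAMS = AlignParams()
QUANTIZED_PARAMS = AlignParams(
    k=18, w=10, alphabet_size=3, canonical=False, min_chain_score=36.0
)


@dataclass(frozen=True)
class Anchor:
    target_pos: int
    query_pos: int
    length: int
    strand: str = "+"


@dataclass
class Chain:
    anchors: list[Anchor]
    score: float
    strand: str
    target_id: str

    def __len__(self):
        return len(self.anchors)


@dataclass
class Alignment:
    query_id: str
    target_id: str
    strand: str                 # '+' or '-'
    q_start: int                # original-query coordinates, 0-based half-open
    q_end: int
    t_start: int
    t_end: int
    cigar: str                  # ops =/X/I/D in alignment orientation
    score: float
    edit_dist: int
    mapq: int
    domain: str = "nucleotide"  # or "quantized"
    primary: bool = True
    fallback: bool = False
    query_length: int = 0
    chain_score: float = 0.0
    anchor_count: int = 0
    anchors_qt: list[tuple[int, int]] | None = None  # (q, t) seed positions

    def check(self) -> None:
        qc, tc = cigar_consumed(self.cigar)
        assert qc == self.q_end - self.q_start, (qc, self.q_start, self.q_end)
        assert tc == self.t_end - self.t_start, (tc, self.t_start, self.t_end)
        assert 0 <= self.q_start < self.q_end
        assert 0 <= self.t_start < self.t_end


_CIG_RE = re.compile(r"(\d+)([=XIDMS])")


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def cigar_consumed(cigar: str) -> tuple[int, int]:
    """(query-consumed, target-consumed) lengths of a CIGAR (S excluded)."""
    q = t = 0
    for n, op in cigar_ops(cigar):
        if op in "=XMI":
            q += n
        if op in "=XMD":
            t += n
    return q, t


def merge_cigar(parts: list[str]) -> str:
    ops: list[tuple[int, str]] = []
    for part in parts:
        for n, op in cigar_ops(part):
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + n, op)
            else:
                ops.append((n, op))
    return "".join(f"{n}{op}" for n, op in ops)


def cigar_matches(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op == "=")


def alignment_score(cigar: str) -> float:
    """Gap-aware alignment score: +1 per match, -2 per mismatch, and an
    affine charge per indel run (open 4, 0.05 per column). A long
    structural indel inside an otherwise good alignment costs little — it
    must not make the alignment look worse than a short spurious one."""
    score = 0.0
    for n, op in cigar_ops(cigar):
        if op == "=":
            score += n
        elif op in "XM":
            score -= 2 * n
        elif op in "ID":
            score -= 4 + 0.05 * n
    return score


# ---------------------------------------------------------------------------
# edit distance and banded alignment kernels


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (exact, unbanded)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def banded_global(query: str, target: str, band: int, band_cap: int = 4096):
    """Banded global alignment with widen-and-retry.

    Starts at ``band`` (at least the length difference, which any global
    alignment must bridge), doubles on overflow up to ``band_cap``, then
    falls back to unbanded. Returns (edit_dist, cigar).
    """
    if not query and not target:
        return 0, ""
    if not query:
        return len(target), f"{len(target)}D"
    if not target:
        return len(query), f"{len(query)}I"
    k = max(band, abs(len(query) - len(target)) + 1)
    while True:
        res = edlib.align(query, target, mode="NW", task="path", k=k)
        if res["editDistance"] >= 0:
            return res["editDistance"], res["cigar"]
        if k > band_cap:
            res = edlib.align(query, target, mode="NW", task="path")
            return res["editDistance"], res["cigar"]
        k *= 2


# ---------------------------------------------------------------------------
# minimizers


def _mix64(x: np.ndarray) -> np.ndarray:
    """Invertible splitmix64-style integer mixer, vectorized on uint64."""
    with np.errstate(over="ignore"):
        x = x.astype(np.uint64)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return x


def _window_minima(hashes: np.ndarray, w: int) -> np.ndarray:
    """Indices of the (leftmost) minimum in every length-w window."""
    if hashes.size < w:
        return np.array([], dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(hashes, w)
    idx = win.argmin(axis=1) + np.arange(win.shape[0])
    return np.unique(idx)


def extract_minimizers(seq_codes: np.ndarray, params: AlignParams):
    """Window-minimum minimizers.

    Returns (positions, hashes, strands) arrays; strands is all 0 in
    non-canonical (quantized) mode, else 0 for forward-canonical and 1 where
    the reverse-complement k-mer was the canonical representative.
    """
    k, w = params.k, params.w
    n = seq_codes.size
    empty = (np.array([], int), np.array([], np.uint64), np.array([], int))
    if n < k:
        return empty
    fwd = rolling_kmer_codes(seq_codes, k, base=params.alphabet_size)
    if params.canonical:
        rc_codes = (params.alphabet_size - 1) - seq_codes[::-1]
        rev = rolling_kmer_codes(rc_codes, k, base=params.alphabet_size)[::-1]
        strands = (rev < fwd).astype(int)
        canon = np.where(strands == 1, rev, fwd)
    else:
        strands = np.zeros(fwd.size, dtype=int)
        canon = fwd
    hashes = _mix64(canon.astype(np.uint64))
    if hashes.size < w:
        pos = np.array([int(np.argmin(hashes))])
    else:
        pos = _window_minima(hashes, w)
    return pos, hashes[pos], strands[pos]


class TargetIndex:
    """Minimizer index over a set of named target sequences, built once."""

    def __init__(self, targets: dict[str, str], params: AlignParams):
        self.params = params
        self.seqs = dict(targets)
        self.lengths = {name: len(s) for name, s in targets.items()}
        self.index: dict[int, list[tuple[str, int, int]]] = {}
        for name, seq in targets.items():
            codes = encode_bases(seq) if params.alphabet_size == 4 else _sym_codes(seq)
            pos, hashes, strands = extract_minimizers(codes, params)
            for p, h, s in zip(pos.tolist(), hashes.tolist(), strands.tolist()):
                self.index.setdefault(h, []).append((name, p, s))


def _sym_codes(seq: str) -> np.ndarray:
    """Symbol-character string ('0','1','2',...) -> integer codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int8) - ord("0")


def seq_to_codes(seq: str, params: AlignParams) -> np.ndarray:
    return encode_bases(seq) if params.alphabet_size == 4 else _sym_codes(seq)


# ---------------------------------------------------------------------------
# chaining


def chain_anchors(anchors: list[Anchor], params: AlignParams) -> list[Chain]:
    """Co-linear chaining by dynamic programming.

    Score of a chain is the sum of anchor gains (min(k, dt, dq) for each
    link, k for the first anchor) minus gap_gamma * |dt - dq| per link;
    links with max(dt, dq) > max_gap are forbidden. Chains are returned by
    descending score (ties: leftmost target start); lower-scoring chains are
    re-derived after removing anchors already used.
    """
    if not anchors:
        return []
    k = params.k
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].target_pos, anchors[i].query_pos))
    t = np.array([anchors[i].target_pos for i in order], dtype=np.int64)
    q = np.array([anchors[i].query_pos for i in order], dtype=np.int64)
    n = t.size
    alive = np.ones(n, dtype=bool)
    chains: list[Chain] = []
    strand = anchors[0].strand
    for _ in range(params.max_chains):
        if not alive.any():
            break
        f = np.full(n, -np.inf)
        parent = np.full(n, -1, dtype=int)
        idx_alive = np.flatnonzero(alive)
        for ii, i in enumerate(idx_alive):
            f[i] = float(k)
            lo = max(0, ii - params.lookback)
            js = idx_alive[lo:ii]
            if js.size == 0:
                continue
            dt = t[i] - t[js]
            dq = q[i] - q[js]
            ok = (dt > 0) & (dq > 0) & (np.maximum(dt, dq) <= params.max_gap)
            if not ok.any():
                continue
            js, dt, dq = js[ok], dt[ok], dq[ok]
            gain = np.minimum(k, np.minimum(dt, dq)).astype(float)
            shift = np.abs(dt - dq)
            cand = (
                f[js]
                + gain
                - params.gap_gamma * shift
                - params.gap_open * (shift > params.gap_open_thresh)
            )
            best = int(np.argmax(cand))
            if cand[best] > f[i]:
                f[i] = float(cand[best])
                parent[i] = js[best]
        end = int(np.argmax(np.where(alive, f, -np.inf)))
        score = float(f[end])
        if score < params.min_chain_score:
            break
        members = []
        node = end
        while node != -1:
            members.append(node)
            node = parent[node]
        members.reverse()
        chains.append(
            Chain(
                anchors=[anchors[order[m]] for m in members],
                score=score,
                strand=strand,
                target_id="",
            )
        )
        alive[members] = False
    chains.sort(key=lambda c: (-c.score, c.anchors[0].target_pos))
    return chains


# ---------------------------------------------------------------------------
# extension


def _has_bad_block(
    cigar: str, win: int = 200, max_frac: float = 0.40, indel_run: int = 30
) -> bool:
    """True if some ~win-column stretch of the alignment is mostly non-match.

    A long gap whose average identity looks acceptable can still hide a
    foreign block (e.g. an inverted segment flanked by good sequence); the
    windowed scan catches it where the average would not. Long I/D runs
    (>= indel_run) are NOT counted as bad: a clean structural indel is a
    legitimate part of one alignment and must stay in the CIGAR.
    """
    ops = cigar_ops(cigar)
    pc, pb = [0], [0]
    for n, op in ops:
        pc.append(pc[-1] + n)
        bad = n if (op == "X" or (op in "ID" and n < indel_run)) else 0
        pb.append(pb[-1] + bad)
    total = pc[-1]
    if total == 0:
        return False
    if total < win:
        return pb[-1] > max_frac * total
    i = 0
    for j in range(1, len(ops) + 1):
        while pc[j] - pc[i + 1] >= win:
            i += 1
        dc = pc[j] - pc[i]
        if dc >= win and pb[j] - pb[i] > max_frac * dc:
            return True
    return False


_EXT_CHUNK = 256  # end extension advances chunk-wise so a locally foreign
# region (e.g. an inverted segment) stops the extension instead of being
# averaged away by good flanking sequence


def _extend_right(query: str, target: str, qe: int, te: int, params: AlignParams):
    """Greedy chunked extension toward the query end. Each chunk must align
    within tail_max_rate or the extension stops (the remainder soft-clips).
    Returns (new_q_end, new_t_end, cigar_suffix, extra_edits)."""
    parts: list[str] = []
    d_tot = 0
    while qe < len(query):
        chunk = query[qe : qe + _EXT_CHUNK]
        avail = target[te : te + len(chunk) + params.band]
        if not avail:
            break
        res = edlib.align(chunk, avail, mode="SHW", task="path")
        d = res["editDistance"]
        if d > params.tail_max_rate * len(chunk) + 2:
            break
        parts.append(res["cigar"])
        d_tot += d
        qe += len(chunk)
        te += res["locations"][0][1] + 1
    return qe, te, merge_cigar(parts), d_tot


def _extend_left(query: str, target: str, qs: int, ts: int, params: AlignParams):
    """Mirror of _extend_right toward the query start (on reversed strings).
    Returns (new_q_start, new_t_start, cigar_prefix, extra_edits)."""
    qe_r, te_r, cig_r, d = _extend_right(
        query[:qs][::-1], target[:ts][::-1], 0, 0, params
    )
    ops = cigar_ops(cig_r)[::-1]
    cig = "".join(f"{n}{op}" for n, op in ops)
    return qs - qe_r, ts - te_r, cig, d


def _trim_weak_blocks(
    anchors: list[Anchor], params: AlignParams, min_block: int = 3
) -> list[Anchor]:
    """Drop thinly-supported anchor blocks around structural jumps.

    Max-sum chaining happily carries its accumulated score across a large
    diagonal jump to pick up a few stray anchors; a structural event is only
    trusted when the block beyond it is both deep enough (>= min_block
    seeds) and dense enough (genuine blocks carry a seed every few tens of
    symbols, stray ones are scattered). The largest block is always kept."""
    if len(anchors) <= min_block:
        return anchors
    blocks: list[list[Anchor]] = [[anchors[0]]]
    for prev, cur in zip(anchors, anchors[1:]):
        shift = abs(
            (cur.target_pos - prev.target_pos) - (cur.query_pos - prev.query_pos)
        )
        if shift > params.gap_open_thresh:
            blocks.append([])
        blocks[-1].append(cur)
    biggest = max(len(b) for b in blocks)

    def solid(b: list[Anchor]) -> bool:
        span = b[-1].query_pos + params.k - b[0].query_pos
        return len(b) >= max(min_block, span / 100)

    kept = [b for b in blocks if solid(b) or len(b) == biggest]
    return [x for b in kept for x in b]


def extend_chain(
    query: str, target: str, chain: Chain, params: AlignParams
) -> list[Alignment]:
    """Base-level extension of a chain into one or more gapless-coordinate
    alignment segments.

    Inter-anchor gaps are bridged by banded global alignment. A gap that is
    long on BOTH query and target and aligns poorly (edit rate above
    split_max_rate) splits the chain there: such regions are typically
    rearranged (e.g. inverted) rather than merely divergent, and gluing
    them into one CIGAR would hide the breakpoint. Pure deletions and
    insertions (long on one side only) are always bridged, so they surface
    as D/I runs. Segment ends are extended toward the query ends while the
    tail still aligns within tail_max_rate.
    """
    k = params.k
    a = _trim_weak_blocks(chain.anchors, params)
    # split detection between consecutive anchors
    cut_after: set[int] = set()
    for j in range(len(a) - 1):
        dq = a[j + 1].query_pos - (a[j].query_pos + k)
        dt = a[j + 1].target_pos - (a[j].target_pos + k)
        if dq >= params.split_min_gap and dt >= params.split_min_gap:
            gq = query[a[j].query_pos + k : a[j + 1].query_pos]
            gt = target[a[j].target_pos + k : a[j + 1].target_pos]
            d, cig = banded_global(gq, gt, params.band)
            # a pure indel explains |dt - dq| edits; only the EXCESS beyond
            # that indicates genuinely foreign (e.g. inverted) sequence. The
            # windowed block test is applied only to roughly balanced gaps:
            # unit-cost alignment shreds a long indel into short runs that
            # would otherwise masquerade as a bad block.
            excess = d - abs(dt - dq)
            balanced = abs(dt - dq) <= 0.5 * max(dq, dt)
            if excess > params.split_max_rate * min(len(gq), len(gt)) or (
                balanced and _has_bad_block(cig)
            ):
                cut_after.add(j)
    segments: list[list[Anchor]] = [[]]
    for j, anc in enumerate(a):
        segments[-1].append(anc)
        if j in cut_after:
            segments.append([])
    out: list[Alignment] = []
    first_seg, last_seg = 0, len(segments) - 1
    for si, seg in enumerate(segments):
        qs, ts = seg[0].query_pos, seg[0].target_pos
        qe, te = seg[-1].query_pos + k, seg[-1].target_pos + k
        qe, te = min(qe, len(query)), min(te, len(target))
        d_mid, cig_mid = banded_global(query[qs:qe], target[ts:te], params.band)
        d_l = d_r = 0
        cig_l = cig_r = ""
        if si == first_seg:
            qs, ts, cig_l, d_l = _extend_left(query, target, qs, ts, params)
        if si == last_seg:
            qe, te, cig_r, d_r = _extend_right(query, target, qe, te, params)
        cigar = merge_cigar([cig_l, cig_mid, cig_r])
        edits = d_l + d_mid + d_r
        score = alignment_score(cigar)
        aln = Alignment(
            query_id="",
            target_id=chain.target_id,
            strand=chain.strand,
            q_start=qs,
            q_end=qe,
            t_start=ts,
            t_end=te,
            cigar=cigar,
            score=score,
            edit_dist=edits,
            mapq=0,
            query_length=len(query),
            chain_score=chain.score,
            anchor_count=len(chain),
            anchors_qt=[(x.query_pos, x.target_pos) for x in seg],
        )
        aln.check()
        out.append(aln)
    return out


def _q_overlap(a: Alignment, b: Alignment) -> int:
    return max(0, min(a.q_end, b.q_end) - max(a.q_start, b.q_start))


def _t_overlap(a: Alignment, b: Alignment) -> int:
    if a.target_id != b.target_id:
        return 0
    return max(0, min(a.t_end, b.t_end) - max(a.t_start, b.t_start))


def select_alignments(
    alns: list[Alignment], overlap_frac: float = 0.3
) -> tuple[list[Alignment], float | None]:
    """Pick the reported alignment set from raw candidates.

    Candidates that duplicate an already-kept PLACEMENT (substantial overlap
    on both the query and the target axis) are discarded — repetitive
    low-alphabet sequences produce many shifted near-diagonal chains of the
    same region. Candidates covering a new query segment are kept as
    supplementary; candidates re-placing an already-kept query segment
    elsewhere on the target are kept as secondary and drive the mapping
    quality down. Returns (kept, best competing chain score or None).
    """
    if not alns:
        return [], None
    ranked = sorted(
        alns, key=lambda a: (-max(a.chain_score, a.score), -a.score, a.t_start)
    )
    kept: list[Alignment] = []
    for a in ranked:
        dup = any(
            _q_overlap(a, k)
            > overlap_frac * min(a.q_end - a.q_start, k.q_end - k.q_start)
            and _t_overlap(a, k)
            > overlap_frac * min(a.t_end - a.t_start, k.t_end - k.t_start)
            for k in kept
        )
        if dup:
            continue
        a.primary = not kept
        kept.append(a)
    primary = kept[0]
    alts = [
        k
        for k in kept[1:]
        if _q_overlap(k, primary)
        > overlap_frac * min(k.q_end - k.q_start, primary.q_end - primary.q_start)
    ]
    second = max((k.chain_score for k in alts), default=None)
    return kept, second


def compute_mapq(best_score: float, second_score: float | None, anchor_count: int) -> int:
    """Placement confidence from chain-score competition: 60 when the best
    chain is unchallenged, 0 when the runner-up ties it, scaled down for
    thinly anchored chains."""
    if second_score is None:
        return 60
    assert best_score > 0
    raw = round(40.0 * (1.0 - second_score / best_score)) * min(1.0, anchor_count / 10.0)
    return int(np.clip(round(raw), 0, 60))


# ---------------------------------------------------------------------------
# full composition


def _collect_anchors(query_codes: np.ndarray, index: TargetIndex):
    """Anchors per (target, strand). Minus-strand anchors are expressed in
    reverse-complemented-query coordinates so chaining sees co-linear
    coordinates on both strands."""
    params = index.params
    pos, hashes, strands = extract_minimizers(query_codes, params)
    buckets: dict[tuple[str, str], list[Anchor]] = {}
    qlen = query_codes.size
    for p, h, s in zip(pos.tolist(), hashes.tolist(), strands.tolist()):
        hits = index.index.get(h)
        if not hits:
            continue
        if len(hits) > 200:  # highly repetitive seed: skip
            continue
        for name, tp, tstrand in hits:
            if s == tstrand:
                buckets.setdefault((name, "+"), []).append(
                    Anchor(target_pos=tp, query_pos=p, length=params.k, strand="+")
                )
            else:
                rp = qlen - params.k - p
                buckets.setdefault((name, "-"), []).append(
                    Anchor(target_pos=tp, query_pos=rp, length=params.k, strand="-")
                )
    return buckets


def align(
    query: str,
    targets: dict[str, str] | TargetIndex,
    params: AlignParams | None = None,
    query_id: str = "",
) -> list[Alignment]:
    """Map one query against the indexed targets.

    In canonical (nucleotide) mode both strands are searched inherently; in
    quantized mode only the given orientation is searched and the caller
    supplies the reverse-complement-derived query separately. Returns
    alignments sorted by score; best segment is primary. Empty list means
    unmapped.
    """
    if isinstance(targets, TargetIndex):
        index = targets
        params = index.params
    else:
        params = params or NUCLEOTIDE_PARAMS
        index = TargetIndex(targets, params)
    if len(query) < params.k:
        return []
    qcodes = seq_to_codes(query, params)
    buckets = _collect_anchors(qcodes, index)
    chains: list[Chain] = []
    for (name, strand), ancs in buckets.items():
        # dedupe
        ancs = list({(x.target_pos, x.query_pos): x for x in ancs}.values())
        for ch in chain_anchors(ancs, params):
            ch.target_id = name
            ch.strand = strand
            chains.append(ch)
    chains.sort(key=lambda c: (-c.score, c.anchors[0].target_pos))
    if not chains or chains[0].score < params.min_chain_score:
        return []
    chains = [c for c in chains if c.score >= params.min_chain_score]
    rc_query = reverse_complement(query) if params.alphabet_size == 4 else None
    alignments: list[Alignment] = []
    for ci, ch in enumerate(chains):
        if ch.strand == "-" and rc_query is None:
            # symbol space has no complement; minus-strand chains cannot
            # occur in non-canonical mode
            continue
        qseq = rc_query if ch.strand == "-" else query
        for aln in extend_chain(qseq, index.seqs[ch.target_id], ch, params):
            if ch.strand == "-":
                qs, qe = aln.q_start, aln.q_end
                aln.q_start, aln.q_end = len(query) - qe, len(query) - qs
            aln.query_id = query_id
            aln.primary = ci == 0
            alignments.append(aln)
    if not alignments:
        return []
    kept, second = select_alignments(alignments)
    primary = kept[0]
    primary.mapq = compute_mapq(primary.chain_score, second, primary.anchor_count)
    return kept
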