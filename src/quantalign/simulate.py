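"""Synthetic genomes, planted structural variants and nanopore-like reads.

The simulator emulates the study design used to validate the method:
a random genome, planted INS/DEL/INV of lengths uniform on a configurable
range, and long reads with roughly 10% errors whose substitutions are
biased by the pore model — with probability ``confusion_weight`` a
substituted base is the one whose resulting Q-mer current is NEAREST the
original Q-mer's current, which is exactly the error mode the quantized
alignment is designed to absorb. Indels are placed uniformly; no
homopolymer-specific inflation is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pore_model import QmerModel, QuantizerConfig
from .quantize import (
    quantize_codes,
    quantize_sequence,
    reverse_complement,
    rolling_kmer_codes,
)
from .sv import SVCall

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Desk-scale defaults; the SV length range follows the study design
    (uniform between 50 and 10000) and total error rate is ~10%."""

    genome_length: int = 200_000
    gc: float = 0.5
    seed: int = 0
    n_ins: int = 10
    n_del: int = 10
    n_inv: int = 5
    sv_length_range: tuple[int, int] = (50, 10_000)
    min_sv_separation: int = 1000
    coverage: float = 20.0
    read_length_median: int = 3000
    read_length_sigma: float = 0.5  # log-normal shape
    read_length_min: int = 1000
    sub_rate: float = 0.04
    ins_rate: float = 0.03
    del_rate: float = 0.03
    confusion_weight: float = 1.0
    # confusion bursts: occasional stretches where the basecaller emits a
    # current-equivalent but heavily substituted word — locally dense,
    # always current-biased substitutions (ignored entirely when all error
    # rates are zero)
    burst_rate: float = 1e-4      # per-base probability a burst starts
    burst_len_mean: int = 300     # geometric mean burst length
    burst_density: float = 0.5    # per-base substitution prob inside bursts

    def __post_init__(self):
        assert 0 < self.gc < 1
        assert self.sv_length_range[0] <= self.sv_length_range[1]
        for r in (self.sub_rate, self.ins_rate, self.del_rate, self.confusion_weight):
            assert 0.0 <= r <= 1.0
        assert min(self.n_ins, self.n_del, self.n_inv) >= 0


@dataclass
class ReadTruth:
    read_id: str
    chrom: str
    start: int      # on the (mutated) genome the read was sampled from
    end: int
    strand: str


def simulate_genome(cfg: SimConfig) -> dict[str, str]:
    """I.i.d. random genome at the requested GC content, one contig."""
    assert cfg.genome_length >= 1000
    rng = np.random.default_rng(cfg.seed)
    at, gc = (1 - cfg.gc) / 2, cfg.gc / 2
    codes = rng.choice(4, size=cfg.genome_length, p=[at, gc, gc, at])
    return {"chr1": BASES[codes].tobytes().decode("ascii")}


def _sample_sv_layout(rng, glen: int, cfg: SimConfig) -> list[SVCall]:
    """Rejection-sample non-overlapping SV placements (with a minimum
    separation so truth intervals stay unambiguous), on the ORIGINAL
    reference coordinates."""
    lo, hi = cfg.sv_length_range
    types = ["DEL"] * cfg.n_del + ["INS"] * cfg.n_ins + ["INV"] * cfg.n_inv
    placed: list[tuple[int, int, str, int]] = []  # (start, end, type, length)
    sep = cfg.min_sv_separation
    for svtype in types:
        for _ in range(10_000):
            length = int(rng.integers(lo, hi + 1))
            span = 0 if svtype == "INS" else length
            start = int(rng.integers(sep, glen - span - sep))
            end = start + span
            if all(start - sep >= e or end + sep <= s for s, e, _, _ in placed):
                placed.append((start, end, svtype, length))
                break
        else:
            raise ValueError(
                f"genome of length {glen} cannot host the requested SVs "
                f"with {sep} bp separation"
            )
    placed.sort()
    return [
        SVCall("chr1", s, e, t, L, source="truth") for s, e, t, L in placed
    ]


def plant_svs(
    genome: dict[str, str], cfg: SimConfig
) -> tuple[dict[str, str], list[SVCall]]:
    """Apply the sampled SVs to a copy of the genome.

    Truth coordinates are reported on the ORIGINAL reference so calls made
    from read-to-original-reference alignments are directly comparable.
    DEL removes the interval, INS inserts random sequence at the point,
    INV reverse-complements the interval in place.
    """
    (name, seq), = genome.items()
    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.n_del + cfg.n_ins + cfg.n_inv == 0:
        return {name: seq}, []
    truths = _sample_sv_layout(rng, len(seq), cfg)
    pieces: list[str] = []
    cursor = 0
    for sv in truths:
        pieces.append(seq[cursor : sv.start])
        if sv.svtype == "DEL":
            cursor = sv.end
        elif sv.svtype == "INS":
            ins = BASES[rng.choice(4, size=sv.length)].tobytes().decode("ascii")
            pieces.append(ins)
            cursor = sv.start
        else:  # INV
            pieces.append(reverse_complement(seq[sv.start : sv.end]))
            cursor = sv.end
    pieces.append(seq[cursor:])
    mutated = "".join(pieces)
    truths = [
        SVCall(name, t.start, t.end, t.svtype, t.length, t.source) for t in truths
    ]
    return {name: mutated}, truths


def _apply_errors(
    codes: np.ndarray, rng: np.random.Generator, cfg: SimConfig, model: QmerModel
) -> np.ndarray:
    """Vectorized error process on one read's base codes.

    Substitutions first (current-similarity-biased via the Q-mer map of the
    clean read), then indels via repeat counts (0 = deletion, 2 = insertion
    of a random base after the position).
    """
    n = codes.size
    q = model.Q
    out = codes.copy()
    # --- substitutions (uniform background + dense confusion bursts)
    sub_p = np.full(n, cfg.sub_rate)
    bias_p = np.full(n, cfg.confusion_weight)
    if cfg.burst_rate > 0:
        for s in np.flatnonzero(rng.random(n) < cfg.burst_rate):
            ln = int(rng.geometric(1.0 / cfg.burst_len_mean))
            sub_p[s : s + ln] = cfg.burst_density
            bias_p[s : s + ln] = 1.0
    sub_mask = rng.random(n) < sub_p
    sub_pos = np.flatnonzero(sub_mask)
    if sub_pos.size and n >= q:
        # alternatives for each substituted base
        alts = np.array([[b for b in range(4) if b != a] for a in range(4)])
        choices = alts[codes[sub_pos]]  # (m, 3)
        biased = rng.random(sub_pos.size) < bias_p[sub_pos]
        uniform_pick = choices[np.arange(sub_pos.size), rng.integers(0, 3, sub_pos.size)]
        picked = uniform_pick.copy()
        bi = np.flatnonzero(biased)
        if bi.size:
            # biased picks: minimize the TOTAL current disturbance over all
            # Q windows containing the base — a base substitution perturbs
            # every overlapping Q-mer, and the emulated error mode is one
            # whose whole current profile stays close to the original.
            # Choices are evaluated against the clean read (independent sites).
            pos = bi_pos = sub_pos[bi]
            kcodes = rolling_kmer_codes(codes, q)
            cost = np.zeros((bi.size, 3))
            for off in range(q):  # base is at digit `off` of window pos-off
                w = pos - off
                valid = (w >= 0) & (w <= n - q)
                if not valid.any():
                    continue
                wv = w[valid]
                orig_code = kcodes[wv]
                orig_cur = model.currents[orig_code]
                place = 4 ** (q - 1 - off)
                deltas = (choices[bi][valid] - codes[pos[valid]][:, None]) * place
                cand_cur = model.currents[orig_code[:, None] + deltas]
                cost[valid] += np.abs(cand_cur - orig_cur[:, None])
            best = np.argmin(cost, axis=1)
            picked[bi] = choices[bi, best]
        out[sub_pos] = picked
    # --- indels
    u = rng.random(n)
    counts = np.ones(n, dtype=np.int64)
    counts[u < cfg.del_rate] = 0
    counts[(u >= cfg.del_rate) & (u < cfg.del_rate + cfg.ins_rate)] = 2
    expanded = np.repeat(out, counts)
    # inserted positions: the second copy of each duplicated base becomes random
    ins_sites = np.cumsum(counts)[counts == 2] - 1
    if ins_sites.size:
        expanded[ins_sites] = rng.choice(4, size=ins_sites.size)
    return expanded


def simulate_reads(
    genome: dict[str, str],
    cfg: SimConfig,
    model: QmerModel | None = None,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Sample reads uniformly (random strand) to the target coverage and
    apply the error model. Returns ([(read_id, sequence)], truth placements).
    ``model`` is required whenever sub_rate * confusion_weight > 0."""
    assert cfg.coverage > 0
    if cfg.sub_rate * cfg.confusion_weight > 0 and model is None:
        raise ValueError("a QmerModel is required for current-biased substitutions")
    rng = np.random.default_rng(cfg.seed + 2)
    (name, seq), = genome.items()
    glen = len(seq)
    codes_all = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes_all = lut[codes_all]
    total_target = cfg.coverage * glen
    reads: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    total = 0
    i = 0
    mu = np.log(cfg.read_length_median)
    while total < total_target:
        length = int(np.exp(rng.normal(mu, cfg.read_length_sigma)))
        length = max(cfg.read_length_min, min(length, glen))
        start = int(rng.integers(0, glen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = codes_all[start : start + length]
        if strand == "-":
            frag = 3 - frag[::-1]
        if cfg.sub_rate + cfg.ins_rate + cfg.del_rate > 0:
            frag = _apply_errors(frag, rng, cfg, model)
        rid = f"read{i:05d}"
        reads.append((rid, BASES[frag].tobytes().decode("ascii")))
        truths.append(ReadTruth(rid, name, start, start + length, strand))
        total += length
        i += 1
    return reads, truths


def confusable_pair(
    model: QmerModel,
    cfg: QuantizerConfig,
    length: int = 20,
    seed: int = 0,
    budget: int = 5000,
) -> tuple[str, str]:
    """Find two DISTINCT nucleotide sequences with identical quantized
    sequences — the information loss at the heart of quantization.

    Randomized search: mutate a random sequence one base at a time toward
    current-similar alternatives and accept when the full quantization is
    unchanged. Raises if the budget is exhausted.
    """
    assert length >= model.Q
    rng = np.random.default_rng(seed)
    for _ in range(budget):
        codes = rng.choice(4, size=length)
        ref = quantize_codes(codes, model, cfg)
        pos = int(rng.integers(0, length))
        alt = codes.copy()
        others = [b for b in range(4) if b != codes[pos]]
        alt[pos] = others[int(rng.integers(0, 3))]
        if np.array_equal(quantize_codes(alt, model, cfg), ref):
            a = BASES[codes].tobytes().decode("ascii")
            b = BASES[alt].tobytes().decode("ascii")
            return a, b
    raise RuntimeError(
        f"no confusable pair of length {length} found within {budget} trials"
    )


def verify_confusable(
    a: str, b: str, model: QmerModel, cfg: QuantizerConfig
) -> bool:
    """True iff a != b but their quantized sequences are identical."""
    if a == b:
        return False
    qa = quantize_sequence(a, model, cfg).symbols
    qb = quantize_sequence(b, model, cfg).symbols
    return qa.size == qb.size and bool(np.array_equal(qa, qb))
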