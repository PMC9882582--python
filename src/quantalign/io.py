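"""Standard-format I/O: FASTA/FASTQ in, PAF/SAM/VCF/BED/TSV out.

All internal coordinates are 0-based half-open; conversion to the 1-based
conventions of SAM and VCF happens only here (for SAM, inside pysam).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam

from .aligner import Alignment, cigar_ops
from .quantize import reverse_complement
from .sv import SVCall


@dataclass
class SeqRecord:
    name: str
    sequence: str
    quality: str | None = None


def read_fasta(path) -> list[SeqRecord]:
    """Ordered FASTA records (plain or gzip), identifiers verbatim."""
    with pysam.FastxFile(str(path)) as fh:
        return [SeqRecord(e.name, e.sequence) for e in fh]


def read_fastq(path) -> list[SeqRecord]:
    """Ordered FASTQ records with qualities (plain or gzip)."""
    out = []
    with pysam.FastxFile(str(path)) as fh:
        for i, e in enumerate(fh):
            if e.quality is None:
                raise ValueError(f"record {i} ({e.name}): missing quality line")
            out.append(SeqRecord(e.name, e.sequence, e.quality))
    return out


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            name, seq = (rec.name, rec.sequence) if isinstance(rec, SeqRecord) else rec
            fh.write(f">{name}\n{seq}\n")


def write_fastq(records, path, default_quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, SeqRecord):
                name, seq, qual = rec.name, rec.sequence, rec.quality
            else:
                name, seq = rec
                qual = None
            qual = qual or default_quality * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# PAF


def paf_line(aln: Alignment, target_length: int) -> str:
    matches = sum(n for n, op in cigar_ops(aln.cigar) if op == "=")
    block = sum(n for n, op in cigar_ops(aln.cigar) if op in "=XMID")
    return "\t".join(
        str(x)
        for x in (
            aln.query_id,
            aln.query_length,
            aln.q_start,
            aln.q_end,
            aln.strand,
            aln.target_id,
            target_length,
            aln.t_start,
            aln.t_end,
            matches,
            block,
            aln.mapq,
        )
    )


def write_paf(alignments, target_lengths: dict[str, int], path) -> None:
    """Standard 12-column PAF."""
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(paf_line(aln, target_lengths[aln.target_id]) + "\n")


def read_paf(path) -> pd.DataFrame:
    cols = [
        "query", "qlen", "qstart", "qend", "strand",
        "target", "tlen", "tstart", "tend", "matches", "block", "mapq",
    ]
    return pd.read_csv(path, sep="\t", header=None, names=cols)


# ---------------------------------------------------------------------------
# SAM


def write_sam(
    read_alignments: list[tuple[SeqRecord, list[Alignment]]],
    target_lengths: dict[str, int],
    path,
) -> None:
    """One record group per read, in input order; unmapped reads are emitted
    as FLAG-4 records. Non-primary segments are flagged supplementary."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in target_lengths.items()],
    }
    refs = {n: i for i, n in enumerate(target_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec, alns in read_alignments:
            if not alns:
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.name
                a.flag = 4
                a.query_sequence = rec.sequence
                if rec.quality:
                    a.query_qualities = pysam.qualitystring_to_array(rec.quality)
                out.write(a)
                continue
            for aln in alns:
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.name
                flag = 0
                if aln.strand == "-":
                    flag |= 16
                if not aln.primary:
                    flag |= 2048
                a.flag = flag
                a.reference_id = refs[aln.target_id]
                a.reference_start = aln.t_start
                a.mapping_quality = aln.mapq
                seq = (
                    rec.sequence
                    if aln.strand == "+"
                    else reverse_complement(rec.sequence)
                )
                n = len(seq)
                if aln.strand == "+":
                    lclip, rclip = aln.q_start, n - aln.q_end
                else:
                    lclip, rclip = n - aln.q_end, aln.q_start
                cig = ""
                if lclip:
                    cig += f"{lclip}S"
                cig += aln.cigar
                if rclip:
                    cig += f"{rclip}S"
                a.cigarstring = cig
                a.query_sequence = seq
                a.set_tag("NM", aln.edit_dist)
                out.write(a)


# ---------------------------------------------------------------------------
# VCF


def write_vcf_sv(calls: list[SVCall], contig_lengths: dict[str, int], path) -> None:
    """SV call set as VCF 4.2 with SVTYPE/SVLEN/END INFO keys (SVLEN is
    negative for deletions, per convention)."""
    header = pysam.VariantHeader()
    for name, ln in contig_lengths.items():
        header.contigs.add(name, length=ln)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.info.add("SUPPORT", 1, "Integer", "Number of supporting reads")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.start)):
            rec = out.new_record(
                contig=c.chrom,
                start=c.start,
                alleles=("N", f"<{c.svtype}>"),
            )
            rec.info["SVTYPE"] = c.svtype
            rec.info["SVLEN"] = -c.length if c.svtype == "DEL" else c.length
            rec.info["SUPPORT"] = c.support
            rec.stop = max(c.end, c.start + 1)
            out.write(rec)


def read_vcf_sv(path, source: str = "") -> list[SVCall]:
    """SVCall list from a VCF with SVTYPE and SVLEN and/or END.

    VCF POS is 1-based with the convention that POS names the first affected
    base of the record; internally start = POS - 1. Records with neither
    SVLEN nor END are skipped with a warning.
    """
    import warnings

    def info_get(rec, key):
        try:
            val = rec.info.get(key)
        except (KeyError, ValueError):  # key absent from the header
            return None
        return val[0] if isinstance(val, tuple) else val

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = info_get(rec, "SVTYPE")
            if svtype not in ("INS", "DEL", "INV"):
                continue
            svlen = info_get(rec, "SVLEN")
            start = rec.start
            if svtype == "INS":
                if svlen is None:
                    warnings.warn(f"{rec.chrom}:{rec.pos}: INS without SVLEN, skipped")
                    continue
                calls.append(
                    SVCall(rec.chrom, start, start, "INS", abs(int(svlen)),
                           source=source,
                           support=int(info_get(rec, "SUPPORT") or 1))
                )
            else:
                # SVLEN is authoritative for the span when present (htslib
                # recomputes END from it on write); END alone also works
                if svlen is not None:
                    end = start + abs(int(svlen))
                else:
                    end = rec.stop
                    if end <= start:
                        warnings.warn(
                            f"{rec.chrom}:{rec.pos}: no END or SVLEN, skipped"
                        )
                        continue
                calls.append(
                    SVCall(rec.chrom, start, end, svtype, end - start,
                           source=source,
                           support=int(info_get(rec, "SUPPORT") or 1))
                )
    return calls


# ---------------------------------------------------------------------------
# BED and reports


def read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    return [(str(c), int(s), int(e)) for c, s, e in df.itertuples(index=False)]


def write_eval_report(match, scores, path) -> None:
    """Tab-separated evaluation report: one row per matched pair with
    breakpoint score and length similarity, then a summary block."""
    from .sv import breakpoint_score, length_similarity

    rows = [
        {
            "chrom": c.chrom,
            "call_start": c.start,
            "call_end": c.end,
            "truth_start": t.start,
            "truth_end": t.end,
            "svtype": c.svtype,
            "call_len": c.length,
            "truth_len": t.length,
            "breakpoint_score": breakpoint_score(c, t),
            "length_similarity": round(length_similarity(c, t), 4),
        }
        for c, t in match.pairs
    ]
    with open(path, "w") as fh:
        pd.DataFrame(
            rows,
            columns=[
                "chrom", "call_start", "call_end", "truth_start", "truth_end",
                "svtype", "call_len", "truth_len",
                "breakpoint_score", "length_similarity",
            ],
        ).to_csv(fh, sep="\t", index=False)
        fh.write(
            f"# precision={scores.precision:.4f} recall={scores.recall:.4f} "
            f"f1={scores.f1:.4f} tp={scores.tp} fp={scores.fp} fn={scores.fn}\n"
        )
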