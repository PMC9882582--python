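"""Nucleotide -> current-level -> quantized (ternary) sequence translation.

A nucleotide sequence of length n yields n - Q + 1 overlapping Q-mers; each
is looked up in the Q-mer map to give a current level, and currents are hard
thresholded into a small symbol alphabet. No raw-signal information is used:
the translation is a pure function of the basecalled sequence and the table.

The quantized reverse complement is NOT derivable from the forward quantized
sequence (complementation acts on nucleotides, not on currents), so callers
that need both orientations must quantize both explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .pore_model import QmerModel, QuantizerConfig

_NT_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _NT_CODE[ord(b)] = i
    _NT_CODE[ord(b.lower())] = i

_ACGT_RUN = re.compile("[ACGTacgt]+")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class AmbiguousBaseError(ValueError):
    """Sequence contains a non-ACGT character; split it first."""


class SequenceTooShortError(ValueError):
    """Sequence shorter than the Q-mer length."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """ACGT string -> int8 codes (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _NT_CODE[arr]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise AmbiguousBaseError(
            f"non-ACGT character {seq[pos]!r} at position {pos}; "
            "use split_on_ambiguous() first"
        )
    return codes


def rolling_kmer_codes(codes: np.ndarray, q: int, base: int = 4) -> np.ndarray:
    """Base-``base`` codes of every length-q window (MSB first), vectorized."""
    n = codes.size
    if n < q:
        raise SequenceTooShortError(f"sequence length {n} < Q={q}")
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), q)
    powers = base ** np.arange(q - 1, -1, -1, dtype=np.int64)
    return windows @ powers


@dataclass
class QuantizedSequence:
    """Ternary (or ``levels``-ary) symbol sequence derived from nucleotides.

    symbols[i] is the quantized current of the Q-mer starting at nucleotide
    i of the source (so len(symbols) == source_length - Q + 1).
    """

    symbols: np.ndarray
    source_length: int
    Q: int
    levels: int
    source_id: str = ""
    orientation: str = "forward"  # or "reverse-complement"

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.uint8)
        assert self.symbols.size == self.source_length - self.Q + 1
        assert self.symbols.size == 0 or int(self.symbols.max()) < self.levels

    def __len__(self) -> int:
        return self.symbols.size

    def to_text(self, alphabet: str = "012") -> str:
        """Render symbols as characters (default digits) for export."""
        lut = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
        return lut[self.symbols].tobytes().decode("ascii")


def current_sequence(nt_seq: str, model: QmerModel) -> np.ndarray:
    """Translate a nucleotide sequence into its per-window current levels."""
    codes = encode_bases(nt_seq)
    kcodes = rolling_kmer_codes(codes, model.Q)
    return model.currents[kcodes]


def quantize_codes(
    codes: np.ndarray, model: QmerModel, cfg: QuantizerConfig
) -> np.ndarray:
    """Core binning on pre-encoded base codes: symbol = number of thresholds
    strictly below the current (a value equal to a threshold falls in the
    lower bin)."""
    kcodes = rolling_kmer_codes(codes, model.Q)
    currents = model.currents[kcodes]
    thr = np.asarray(cfg.thresholds)
    return np.searchsorted(thr, currents, side="left").astype(np.uint8)


def quantize_sequence(
    nt_seq: str,
    model: QmerModel,
    cfg: QuantizerConfig,
    source_id: str = "",
) -> QuantizedSequence:
    symbols = quantize_codes(encode_bases(nt_seq), model, cfg)
    return QuantizedSequence(
        symbols=symbols,
        source_length=len(nt_seq),
        Q=model.Q,
        levels=cfg.levels,
        source_id=source_id,
        orientation="forward",
    )


def quantized_reverse_complement(
    nt_seq: str,
    model: QmerModel,
    cfg: QuantizerConfig,
    source_id: str = "",
) -> QuantizedSequence:
    """Quantization of the reverse complement of ``nt_seq``.

    Must be computed from the nucleotides: the forward quantized sequence
    alone does not determine it.
    """
    rc = reverse_complement(nt_seq)
    symbols = quantize_codes(encode_bases(rc), model, cfg)
    return QuantizedSequence(
        symbols=symbols,
        source_length=len(nt_seq),
        Q=model.Q,
        levels=cfg.levels,
        source_id=source_id,
        orientation="reverse-complement",
    )


def split_on_ambiguous(nt_seq: str, q: int) -> list[tuple[int, str]]:
    """Maximal ACGT-only runs with their 0-based offsets; runs shorter than
    q (which admit no Q-mer window) are dropped."""
    out = []
    for m in _ACGT_RUN.finditer(nt_seq):
        if m.end() - m.start() >= q:
            out.append((m.start(), m.group(0)))
    return out


def write_quantized_fasta(records, path, alphabet: str = "012") -> None:
    """FASTA-like export of quantized sequences for external tools.

    ``records`` is an iterable of QuantizedSequence; symbols are rendered via
    ``alphabet`` (e.g. "ACG" to feed a nucleotide-only aligner).
    """
    with open(path, "w") as fh:
        for rec in records:
            name = rec.source_id or "quantized"
            fh.write(f">{name} orientation={rec.orientation} Q={rec.Q}\n")
            fh.write(rec.to_text(alphabet) + "\n")
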