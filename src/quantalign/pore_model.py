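"""Q-mer pore models: the table mapping each Q-length DNA word to the median
ionic current (pA) it produces in the nanopore, plus the hard-threshold
configuration used to collapse currents into a small symbol alphabet.

The model is the package's stand-in for sequencing physics: two different
Q-mers with nearly equal median currents are easily confused by a basecaller,
and quantization deliberately maps them to the same symbol.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


class PoreModelError(ValueError):
    """Malformed, incomplete or degenerate pore-model input."""


def _kmer_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + _BASE_CODE[b]
    return code


def _code_kmer(code: int, q: int) -> str:
    out = []
    for _ in range(q):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class QmerModel:
    """Complete Q-mer -> median current table.

    Currents are stored densely, indexed by the base-4 encoding of the Q-mer
    (A=0, C=1, G=2, T=3, most significant base first), so lookup during
    quantization is a single vectorized fancy-index.
    """

    Q: int
    currents: np.ndarray  # shape (4**Q,), picoamperes
    stdevs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.shape != (4**self.Q,):
            raise PoreModelError(
                f"expected {4**self.Q} currents for Q={self.Q}, "
                f"got {self.currents.shape}"
            )
        if not np.all(np.isfinite(self.currents)) or np.any(self.currents <= 0):
            raise PoreModelError("current values must be finite and positive")

    def __getitem__(self, kmer: str) -> float:
        if len(kmer) != self.Q:
            raise PoreModelError(f"expected a {self.Q}-mer, got {kmer!r}")
        return float(self.currents[_kmer_code(kmer)])

    def __len__(self) -> int:
        return self.currents.size

    @property
    def kmers(self) -> list[str]:
        return ["".join(p) for p in itertools.product(BASES, repeat=self.Q)]


@dataclass
class QuantizerConfig:
    """Hard-threshold configuration: ``levels`` bins split by ``levels - 1``
    strictly increasing current thresholds (pA). The default setting in this
    package is three levels, the ternary code."""

    levels: int
    thresholds: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if self.levels < 1:
            raise PoreModelError("levels must be >= 1")
        if len(self.thresholds) != self.levels - 1:
            raise PoreModelError("levels must equal len(thresholds) + 1")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise PoreModelError("thresholds must be strictly increasing")


def load_qmer_model(path) -> QmerModel:
    """Read an ONT-style tab-separated pore model (columns ``kmer`` and
    ``level_mean``, optional ``level_stdv``; header line optional).

    Q is inferred from the k-mer strings; the table must contain every
    possible Q-mer exactly once.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    # Tolerate a header row naming the columns.
    if df.iloc[0, 0].lower() in {"kmer", "k-mer"}:
        df = df.iloc[1:]
    kmers = df.iloc[:, 0].astype(str)
    lengths = kmers.str.len().unique()
    if len(lengths) != 1:
        raise PoreModelError(f"inconsistent k-mer lengths in model: {sorted(lengths)}")
    q = int(lengths[0])
    if not kmers.str.fullmatch(f"[ACGT]{{{q}}}").all():
        bad = kmers[~kmers.str.fullmatch(f"[ACGT]{{{q}}}")].iloc[0]
        raise PoreModelError(f"invalid k-mer {bad!r} in model table")
    try:
        means = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as e:
        raise PoreModelError(f"non-numeric current value: {e}") from e
    currents = np.full(4**q, np.nan)
    codes = np.fromiter((_kmer_code(k) for k in kmers), dtype=int, count=len(kmers))
    currents[codes] = means
    missing = np.flatnonzero(np.isnan(currents))
    if missing.size:
        raise PoreModelError(
            f"model is incomplete: missing {_code_kmer(int(missing[0]), q)} "
            f"({missing.size} of {4**q} Q-mers absent)"
        )
    stdevs = None
    if df.shape[1] >= 3:
        try:
            sd = df.iloc[:, 2].astype(float).to_numpy()
        except ValueError:
            sd = None
        if sd is not None:
            stdevs = np.empty(4**q)
            stdevs[codes] = sd
    return QmerModel(Q=q, currents=currents, stdevs=stdevs)


def write_qmer_model(model: QmerModel, path) -> None:
    """Emit the same tab-separated dialect the loader reads (with header)."""
    with open(path, "w") as fh:
        cols = "kmer\tlevel_mean" + ("\tlevel_stdv" if model.stdevs is not None else "")
        fh.write(cols + "\n")
        for code, kmer in enumerate(model.kmers):
            row = f"{kmer}\t{model.currents[code]:.6f}"
            if model.stdevs is not None:
                row += f"\t{model.stdevs[code]:.6f}"
            fh.write(row + "\n")


def synthetic_qmer_model(
    Q: int = 6,
    seed: int = 0,
    mean: float = 90.0,
    sd: float = 12.0,
    noise_frac: float = 0.3,
) -> QmerModel:
    """Deterministic synthetic pore model: 4**Q positive currents around
    ``mean`` pA with overall spread ~``sd``, on the R9.4-class scale
    (roughly 50-130 pA).

    Real Q-mer maps are structured, not i.i.d.: the measured current is
    dominated by the bases nearest the pore constriction, and some base
    pairs disturb the current almost identically — which is why whole
    sequences can be confusable through the map. The synthetic table
    emulates this with a position-weighted sum of base contributions
    (weights peaked at the central positions; A/C and G/T nearly degenerate)
    plus an idiosyncratic per-Q-mer noise term (``noise_frac`` of the total
    spread). With noise_frac=1 the structure vanishes and the table is
    i.i.d.
    """
    if Q <= 0:
        raise PoreModelError("Q must be a positive integer")
    if sd <= 0:
        raise PoreModelError("sd must be positive")
    rng = np.random.default_rng(seed)
    # per-position weights, peaked OFF-center: real pores read the bases at
    # the constriction unevenly, and the asymmetry matters — it keeps the
    # map of a reverse complement statistically unrelated to the forward map
    x = np.arange(Q) - (Q - 1) / 3
    w = np.exp(-0.5 * (x / max(1.0, Q / 5)) ** 2)
    # base contributions: the pore separates two base CLASSES strongly but
    # barely resolves the two bases within a class (the same partition at
    # every position, as pore chemistry dictates). Within-class swaps are
    # the current-similar ("confusable") errors a basecaller makes —
    # distinct nucleotide words with near-identical current profiles, which
    # quantization deliberately maps together. Together with the asymmetric
    # weights, reversal decorrelates the profile, so the quantization of a
    # reverse complement carries no systematic relation to the forward one.
    v_levels = np.array([-1.0, -0.98, 0.9, 0.92])
    perm = rng.permutation(4)
    v_base = np.empty(4)
    v_base[perm] = v_levels
    codes = np.arange(4**Q)
    digits = (codes[:, None] // (4 ** np.arange(Q - 1, -1, -1))) % 4
    struct = (v_base[digits] * w).sum(axis=1)
    struct = struct / struct.std()
    # the idiosyncratic (non-additive) part of the current depends on the
    # CLASS-reduced word: swapping a base for its in-class partner leaves it
    # unchanged, as it must for confusability to be a property of the pore
    # rather than of this table's randomness
    high = (v_base[digits] > 0).astype(np.int64)
    reduced = high @ (2 ** np.arange(Q - 1, -1, -1, dtype=np.int64))
    sd_noise = sd * noise_frac
    sd_struct = max(1e-9, np.sqrt(max(0.0, sd**2 - sd_noise**2)))
    eps = rng.normal(0.0, sd_noise, size=2**Q)
    currents = mean + sd_struct * struct + eps[reduced]
    # Redraw the (rare) non-positive values so the invariant holds at any sd.
    bad = currents <= 0
    while bad.any():
        currents[bad] = mean + rng.normal(0.0, sd_noise, size=int(bad.sum()))
        bad = currents <= 0
    return QmerModel(Q=Q, currents=currents)


def compute_thresholds(model: QmerModel, levels: int = 3) -> QuantizerConfig:
    """Equal-mass quantile thresholds over the multiset of 4**Q currents.

    For three levels the thresholds sit at the 1/3 and 2/3 empirical
    quantiles (lower quantile convention: sorted value at index
    floor(m*p)), giving a maximum-entropy ternary code. The rule is a
    documented, configurable choice; any strictly increasing thresholds can
    be supplied directly via QuantizerConfig.
    """
    if levels < 1:
        raise PoreModelError("levels must be >= 1")
    srt = np.sort(model.currents)
    m = srt.size
    thresholds = [float(srt[int(np.floor(m * i / levels))]) for i in range(1, levels)]
    if len(set(thresholds)) != len(thresholds):
        raise PoreModelError(
            f"cannot place {levels - 1} distinct thresholds: too few distinct currents"
        )
    return QuantizerConfig(levels=levels, thresholds=tuple(thresholds))
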