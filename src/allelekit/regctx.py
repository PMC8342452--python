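"""Promoter PWM scanning, allelic TFBS sharing, and TE proximity.

Scanning uses log-odds scores in bits discretized on a 1e-3-bit integer
lattice.  Both the window scores and the null score distribution (a
dynamic-programming convolution of per-column score distributions under
the background model) live on the same lattice, so reported tail
p-values are *exact* for the discretized scoring system and match
exhaustive enumeration over all words.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import BedInterval, GeneRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_PSEUDOCOUNT = 1e-8
DEFAULT_P_THRESHOLD = 1e-5
SCORE_BINS_PER_BIT = 1000


@dataclass
class PWM:
    """Position frequency matrix (4 x length, columns summing to 1)."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x length with length >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """Per-base log2((f + pseudocount) / background) in bits."""
        return np.log2(
            (self.matrix + self.pseudocount) / self.background[:, None]
        )

    def information_content(self) -> float:
        """Total IC in bits relative to the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            term = self.matrix * np.log2(self.matrix / self.background[:, None])
        return float(np.nansum(term))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class TFBSHit:
    gene_id: str
    motif_id: str
    offset: int  # 0-based window start on the forward promoter
    strand: str  # "+" | "-"
    score: float  # log-odds, bits
    p: float


@dataclass(frozen=True)
class TFBSComparison:
    locus_id: str
    shared: int
    specific_a: int
    specific_b: int
    shared_types: int
    specific_types_a: int
    specific_types_b: int


@dataclass(frozen=True)
class ProximityResult:
    gene_id: str
    nearest_te_distance: int | None
    te_id: str | None


# ---------------------------------------------------------------------------
# exact score distribution on the integer lattice


class ScoreDistribution:
    """Null distribution of the integer-lattice window score under the
    background model, computed by exact DP convolution per column."""

    def __init__(self, int_scores: np.ndarray, background: np.ndarray) -> None:
        length = int_scores.shape[1]
        offset = int(int_scores.min(axis=0).sum())
        span = int((int_scores.max(axis=0) - int_scores.min(axis=0)).sum())
        probs = np.zeros(span + 1)
        probs[0] = 1.0
        shift = 0
        for col in range(length):
            col_scores = int_scores[:, col]
            col_min = int(col_scores.min())
            new = np.zeros_like(probs)
            for b in range(4):
                s = int(col_scores[b]) - col_min
                if s == 0:
                    new += background[b] * probs
                else:
                    new[s:] += background[b] * probs[:-s]
            probs = new
            shift += col_min
        support = np.nonzero(probs)[0]
        self.scores = support + offset  # == support + shift
        # survival: P(S >= s), exact tail on the lattice
        tail = np.cumsum(probs[support][::-1])[::-1]
        self.survival = np.minimum(tail, 1.0)

    def pvalue(self, int_score: int) -> float:
        idx = np.searchsorted(self.scores, int_score, side="left")
        if idx >= len(self.scores):
            return float(self.survival[-1]) if int_score <= self.scores[-1] else 0.0
        return float(self.survival[idx])

    def threshold_for(self, p_threshold: float) -> int:
        """Smallest lattice score with tail probability < p_threshold."""
        below = self.survival < p_threshold
        if not below.any():
            return int(self.scores[-1]) + 1
        return int(self.scores[np.argmax(below)])


def _lattice_scores(pwm: PWM) -> np.ndarray:
    """Integer-lattice log-odds; -inf (zero frequency with zero
    pseudocount) is clipped to a large finite penalty."""
    with np.errstate(divide="ignore"):
        bits = pwm.log_odds()
    floor = -100.0 * pwm.length  # far below any attainable threshold
    return np.rint(
        np.clip(bits, floor, None) * SCORE_BINS_PER_BIT
    ).astype(np.int64)


class PWMScanner:
    """Caches lattice scores and null distributions for one PWM."""

    def __init__(self, pwm: PWM) -> None:
        self.pwm = pwm
        self.int_scores = _lattice_scores(pwm)
        self.dist = ScoreDistribution(self.int_scores, pwm.background)
        self.rc_int_scores = _lattice_scores(pwm.reverse_complement())

    def scan(
        self,
        sequence: str,
        gene_id: str = "",
        p_threshold: float = DEFAULT_P_THRESHOLD,
    ) -> list[TFBSHit]:
        """All windows (both strands) with exact tail p < ``p_threshold``.

        Windows containing a non-ACGT character are skipped; a motif
        longer than the sequence yields an empty result.
        """
        length = self.pwm.length
        seq = sequence.upper()
        n = len(seq)
        if length > n:
            return []
        encoded = np.full(n, -1, dtype=np.int64)
        for base, idx in BASE_INDEX.items():
            encoded[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
        valid = encoded >= 0
        window_valid = (
            np.convolve(valid.astype(int), np.ones(length, dtype=int), "valid")
            == length
        )
        cutoff = self.dist.threshold_for(p_threshold)
        hits: list[TFBSHit] = []
        enc = np.where(valid, encoded, 0)
        for strand, table in (("+", self.int_scores), ("-", self.rc_int_scores)):
            window_scores = np.zeros(n - length + 1, dtype=np.int64)
            for col in range(length):
                window_scores += table[enc[col : col + n - length + 1], col]
            for pos in np.nonzero(window_valid & (window_scores >= cutoff))[0]:
                s = int(window_scores[pos])
                hits.append(
                    TFBSHit(
                        gene_id=gene_id,
                        motif_id=self.pwm.motif_id,
                        offset=int(pos),
                        strand=strand,
                        score=s / SCORE_BINS_PER_BIT,
                        p=self.dist.pvalue(s),
                    )
                )
        hits.sort(key=lambda h: (h.offset, h.strand))
        return hits


def scan_pwm(
    sequence: str,
    pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    gene_id: str = "",
) -> list[TFBSHit]:
    """One-shot scan (see :class:`PWMScanner` for scanning many promoters)."""
    return PWMScanner(pwm).scan(sequence, gene_id=gene_id, p_threshold=p_threshold)


# ---------------------------------------------------------------------------
# shared / specific TFBS accounting


def _motif_counts(hits: Iterable[TFBSHit]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.motif_id] = counts.get(h.motif_id, 0) + 1
    return counts


def compare_tfbs(
    hits_a: Iterable[TFBSHit], hits_b: Iterable[TFBSHit], locus_id: str = ""
) -> TFBSComparison:
    """Per-motif min/max accounting of hit instances, plus motif-type
    counts: for motif m with a hits in A and b in B, shared gains
    min(a, b), specific_A gains max(a - b, 0), and symmetrically."""
    counts_a = _motif_counts(hits_a)
    counts_b = _motif_counts(hits_b)
    shared = specific_a = specific_b = 0
    for motif in set(counts_a) | set(counts_b):
        a = counts_a.get(motif, 0)
        b = counts_b.get(motif, 0)
        shared += min(a, b)
        specific_a += max(a - b, 0)
        specific_b += max(b - a, 0)
    types_a, types_b = set(counts_a), set(counts_b)
    return TFBSComparison(
        locus_id=locus_id,
        shared=shared,
        specific_a=specific_a,
        specific_b=specific_b,
        shared_types=len(types_a & types_b),
        specific_types_a=len(types_a - types_b),
        specific_types_b=len(types_b - types_a),
    )


# ---------------------------------------------------------------------------
# TE proximity


def nearest_te_distance(
    gene: GeneRecord, tes: Sequence[BedInterval]
) -> ProximityResult:
    """Distance from the gene body to the nearest TE on its chromosome
    (0 if overlapping; ``None`` if the chromosome has no TE).  Intervals
    are compared 0-based half-open."""
    g_start, g_end = gene.interval0()
    best: tuple[int, str] | None = None
    for te in tes:
        if te.chrom != gene.chrom:
            continue
        if te.start < g_end and g_start < te.end:
            d = 0
        elif te.start >= g_end:
            d = te.start - g_end
        else:
            d = g_start - te.end
        if best is None or d < best[0] or (d == best[0] and te.name < best[1]):
            best = (d, te.name)
    if best is None:
        return ProximityResult(gene.gene_id, None, None)
    return ProximityResult(gene.gene_id, best[0], best[1])


# ---------------------------------------------------------------------------
# PWM text formats


def write_jaspar(pwms: Iterable[PWM], path: str | Path, scale: int = 100) -> None:
    """JASPAR-style count matrices (frequencies scaled to integer counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            counts = np.rint(pwm.matrix * scale).astype(int)
            for i, base in enumerate(BASES):
                row = " ".join(str(v) for v in counts[i])
                fh.write(f"{base} [ {row} ]\n")


def read_jaspar(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    pwms: list[PWM] = []
    motif_id = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        if motif_id is None:
            return
        matrix = np.array([rows[b] for b in BASES], dtype=float)
        matrix = matrix / matrix.sum(axis=0, keepdims=True)
        pwms.append(PWM(motif_id=motif_id, matrix=matrix, pseudocount=pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                m = re.match(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]+?)\s*\]?$", line)
                if m:
                    rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    flush()
    return pwms


def read_meme(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Minimal MEME-dialect reader (MOTIF blocks with letter-probability
    matrices; ACGT alphabet)."""
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freqs = lines[i + 1].split()
            background = np.array(
                [float(freqs[freqs.index(b) + 1]) for b in BASES]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and "letter-probability" not in lines[j]:
                j += 1
            width = int(re.search(r"w=\s*(\d+)", lines[j]).group(1))
            block = []
            for k in range(j + 1, j + 1 + width):
                block.append([float(x) for x in lines[k].split()])
            matrix = np.array(block).T  # rows become ACGT
            matrix = matrix / matrix.sum(axis=0, keepdims=True)
            pwms.append(
                PWM(
                    motif_id=motif_id,
                    matrix=matrix,
                    background=background.copy(),
                    pseudocount=pseudocount,
                )
            )
            i = j + 1 + width
            continue
        i += 1
    return pwms
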