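"""Codon-aware pairwise alignment and Ka/Ks estimation.

The primary estimator is NG86-style counting: fractional synonymous /
nonsynonymous site counting, pathway-averaged difference counting, and
Jukes–Cantor multiple-hit correction.  A kappa-weighted variant
(``method="YN-approx"``) is available behind a flag; it reuses the same
difference counting but weights site counting by an estimated
transition/transversion ratio.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
KS_EXCLUSION_CEILING = 5.0

_CODON_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_AA))

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon; ``*`` for a stop."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    try:
        return _CODON_AA[codon]
    except KeyError:
        raise ValueError(f"not a standard codon: {codon!r}") from None


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


@lru_cache(maxsize=None)
def ng86_sites(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each of the three positions contributes one site, split by the fraction
    of its single-nucleotide mutants that are synonymous.  Mutants that
    create stop codons are excluded from the denominator at that position.
    With ``kappa != 1`` mutants reached by transitions get weight ``kappa``
    (transversions weight 1), giving the kappa-corrected site counts used
    by the YN-approx method.
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon has no site decomposition: {codon}")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn_w = 0.0
        tot_w = 0.0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            w = kappa if (codon[pos], nuc) in TRANSITIONS else 1.0
            tot_w += w
            if translate_codon(mutant) == aa:
                syn_w += w
        if tot_w > 0:
            s += syn_w / tot_w
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    All orderings of the differing positions are walked; a step is
    synonymous when it does not change the encoded amino acid.  Orderings
    that pass through an intermediate stop codon are discarded.  If every
    ordering is blocked by stops, the raw number of differences is split
    equally between the two classes.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if is_stop(codon_a) or is_stop(codon_b):
        raise ValueError("difference counting is defined for sense codons only")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_valid = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt) and nxt != codon_b:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_valid += 1
    if n_valid == 0:
        half = len(diff_pos) / 2.0
        return half, half
    return syn_total / n_valid, nonsyn_total / n_valid


def jukes_cantor(p: float) -> float:
    """JC69 correction d = -(3/4) ln(1 - (4/3) p); raises on saturation."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise ValueError(f"saturated: p = {p:.4f} >= 3/4 is not JC-correctable")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


# ---------------------------------------------------------------------------
# codon alignment


@dataclass(frozen=True)
class CodonAlignment:
    """Two CDS rows aligned codon-by-codon (``---`` marks a codon gap)."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned rows must have equal codon length")

    def counted_columns(self) -> list[tuple[str, str]]:
        """Gap-free columns used for site/difference counting."""
        return [
            (a, b)
            for a, b in zip(self.codons_a, self.codons_b)
            if a != "---" and b != "---"
        ]


def _check_cds(cds: str, name: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if is_stop(codon) and i < n_codons - 1:
            raise ValueError(f"{name}: internal stop codon {codon} at codon {i}")
    return cds


def _strip_terminal_stop(cds: str) -> str:
    return cds[:-3] if len(cds) >= 3 and is_stop(cds[-3:]) else cds


@lru_cache(maxsize=1)
def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_codons(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided global alignment back-threaded to codons.

    Translations are aligned with BLOSUM62 and affine gaps; each protein
    gap becomes a ``---`` codon gap.  Terminal stop codons are trimmed;
    internal stops are rejected with their position.
    """
    cds_a = _strip_terminal_stop(_check_cds(cds_a, "cds_a"))
    cds_b = _strip_terminal_stop(_check_cds(cds_b, "cds_b"))
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    prot_a = "".join(translate_codon(c) for c in codons_a)
    prot_b = "".join(translate_codon(c) for c in codons_b)
    alignment = _protein_aligner().align(prot_a, prot_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(codons_a[ia])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(codons_b[ib])
            ib += 1
    return CodonAlignment(tuple(out_a), tuple(out_b))


# ---------------------------------------------------------------------------
# Ka/Ks estimation


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    method: str
    n_sites: float
    s_sites: float
    n_diffs: float = 0.0
    s_diffs: float = 0.0
    excluded: bool = False
    note: str = ""


def _estimate_kappa(columns: list[tuple[str, str]]) -> float:
    """Crude kappa from the K2P-style ts/tv ratio over all nt differences."""
    ts = tv = 0
    for a, b in columns:
        for x, y in zip(a, b):
            if x != y:
                if (x, y) in TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    if tv == 0:
        return 2.0 if ts else 1.0
    return max(2.0 * ts / tv, 0.1)


def kaks(alignment: CodonAlignment, method: str = "NG86") -> KaKsResult:
    """Ka/Ks for one codon alignment.

    Sites are averaged over both sequences; differences are pathway
    averaged; pN and pS are Jukes–Cantor corrected.  Saturation
    (p >= 3/4) yields ``None`` with a reason; Ks above the analysis
    ceiling (5.0) is flagged ``excluded`` but still reported.
    """
    if method not in ("NG86", "YN-approx"):
        raise ValueError(f"unknown method: {method}")
    columns = [
        (a, b)
        for a, b in alignment.counted_columns()
        if not is_stop(a) and not is_stop(b)
    ]
    kappa = _estimate_kappa(columns) if method == "YN-approx" else 1.0
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    for a, b in columns:
        sa, na = ng86_sites(a, kappa)
        sb, nb = ng86_sites(b, kappa)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = pathway_differences(a, b)
        s_diffs += sd
        n_diffs += nd
    base = dict(
        method=method,
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=n_diffs,
        s_diffs=s_diffs,
    )
    if s_sites == 0 or n_sites == 0:
        return KaKsResult(ka=None, ks=None, ratio=None, note="no counted sites", **base)
    p_n = n_diffs / n_sites
    p_s = s_diffs / s_sites
    try:
        ka = jukes_cantor(p_n)
    except ValueError:
        return KaKsResult(
            ka=None, ks=None, ratio=None, note=f"pN = {p_n:.4f} saturated", **base
        )
    try:
        ks = jukes_cantor(p_s)
    except ValueError:
        return KaKsResult(
            ka=ka, ks=None, ratio=None, note=f"pS = {p_s:.4f} saturated", **base
        )
    ratio = ka / ks if ks > 0 else None
    excluded = ks > KS_EXCLUSION_CEILING
    note = f"Ks > {KS_EXCLUSION_CEILING} excluded from analyses" if excluded else ""
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, excluded=excluded, note=note, **base)


def kaks_for_cds(cds_a: str, cds_b: str, method: str = "NG86") -> KaKsResult:
    """Convenience wrapper: align then estimate.

    The sequences are aligned in a canonical order so tied-score
    alignments cannot break the exact symmetry kaks(A,B) == kaks(B,A);
    all counted quantities are themselves order-independent.
    """
    if cds_b < cds_a:
        cds_a, cds_b = cds_b, cds_a
    return kaks(align_codons(cds_a, cds_b), method=method)
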