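"""Allele pairing via homology-match chaining into collinear blocks.

A match table (precomputed, or built here from translated k-mer Jaccard
similarity) is chained by dynamic programming over gene-rank space into
collinear blocks, blocks likely reflecting whole-genome duplication are
removed by a median-Ks rule, and one allele pair is emitted per retained
anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .io import GeneRecord
from .kaks import translate_codon

DEFAULT_MIN_BLOCK_SIZE = 5
DEFAULT_MAX_GAP = 25
DEFAULT_WGD_KS_CEILING = 0.15
PROTEIN_KMER = 5


@dataclass(frozen=True)
class Match:
    gene_a: str
    gene_b: str
    score: float
    chrom_a: str = ""
    chrom_b: str = ""
    rank_a: int = -1
    rank_b: int = -1


@dataclass
class MatchTable:
    rows: list[Match]

    def __post_init__(self) -> None:
        for m in self.rows:
            if m.score < 0:
                raise ValueError(f"negative similarity score: {m}")

    def with_ranks(
        self, genes_a: Sequence[GeneRecord], genes_b: Sequence[GeneRecord]
    ) -> "MatchTable":
        """Attach chromosome and dense per-chromosome gene-order ranks."""
        rank_of_a = _dense_ranks(genes_a)
        rank_of_b = _dense_ranks(genes_b)
        rows = []
        for m in self.rows:
            if m.gene_a not in rank_of_a or m.gene_b not in rank_of_b:
                continue
            ca, ra = rank_of_a[m.gene_a]
            cb, rb = rank_of_b[m.gene_b]
            rows.append(
                replace(m, chrom_a=ca, chrom_b=cb, rank_a=ra, rank_b=rb)
            )
        return MatchTable(rows)


def _dense_ranks(genes: Sequence[GeneRecord]) -> dict[str, tuple[str, int]]:
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, tuple[str, int]] = {}
    for chrom, members in by_chrom.items():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(members):
            out[g.gene_id] = (chrom, rank)
    return out


@dataclass
class CollinearBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # "forward" | "reverse"
    anchors: list[Match]
    score: float
    median_ks: float | None = None


@dataclass(frozen=True)
class AllelePair:
    locus_id: str
    gene_a: str
    gene_b: str
    block_id: int


# ---------------------------------------------------------------------------
# match table construction


def _protein_kmers(cds: str, k: int = PROTEIN_KMER) -> frozenset[str]:
    protein = "".join(
        translate_codon(cds[i : i + 3]) for i in range(0, len(cds) - len(cds) % 3, 3)
    ).rstrip("*")
    if "*" in protein:  # internal stop: use the prefix before it
        protein = protein.split("*")[0]
    return frozenset(protein[i : i + k] for i in range(len(protein) - k + 1))


def build_match_table(
    cds_a: Mapping[str, str],
    cds_b: Mapping[str, str],
    top_k: int = 5,
    genes_a: Sequence[GeneRecord] | None = None,
    genes_b: Sequence[GeneRecord] | None = None,
) -> MatchTable:
    """Best-scoring candidate counterparts by translated k-mer Jaccard.

    For each gene in A the ``top_k`` highest-Jaccard genes in B are kept
    (and symmetrically for B against A).  Sequences whose length is not a
    multiple of 3 are skipped with a warning.  If gene annotations are
    supplied, ranks are attached.
    """
    if not cds_a or not cds_b:
        raise ValueError("both CDS sets must be non-empty")
    skipped = 0

    def kmer_sets(cds: Mapping[str, str]) -> dict[str, frozenset[str]]:
        nonlocal skipped
        out = {}
        for gene, seq in cds.items():
            if len(seq) % 3 != 0:
                skipped += 1
                continue
            out[gene] = _protein_kmers(seq)
        return out

    sets_a = kmer_sets(cds_a)
    sets_b = kmer_sets(cds_b)
    if skipped:
        warnings.warn(f"skipped {skipped} untranslatable sequences", stacklevel=2)

    index_b: dict[str, list[str]] = {}
    for gene_b, kmers in sets_b.items():
        for kmer in kmers:
            index_b.setdefault(kmer, []).append(gene_b)

    best: dict[tuple[str, str], float] = {}
    per_a: dict[str, list[tuple[float, str]]] = {}
    for gene_a, kmers_a in sets_a.items():
        shared: dict[str, int] = {}
        for kmer in kmers_a:
            for gene_b in index_b.get(kmer, ()):
                shared[gene_b] = shared.get(gene_b, 0) + 1
        scored = []
        for gene_b, inter in shared.items():
            union = len(kmers_a) + len(sets_b[gene_b]) - inter
            if union:
                scored.append((inter / union, gene_b))
        scored.sort(key=lambda t: (-t[0], t[1]))
        per_a[gene_a] = scored[:top_k]

    for gene_a, candidates in per_a.items():
        for score, gene_b in candidates:
            best[(gene_a, gene_b)] = score
    # symmetrize: keep the pair if gene_a ranks within top_k for gene_b too
    per_b: dict[str, list[tuple[float, str]]] = {}
    for (gene_a, gene_b), score in best.items():
        per_b.setdefault(gene_b, []).append((score, gene_a))
    for gene_b, candidates in per_b.items():
        candidates.sort(key=lambda t: (-t[0], t[1]))

    rows = [
        Match(gene_a=a, gene_b=b, score=s)
        for (a, b), s in sorted(best.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    ]
    table = MatchTable(rows)
    if genes_a is not None and genes_b is not None:
        table = table.with_ranks(genes_a, genes_b)
    return table


# ---------------------------------------------------------------------------
# collinear chaining


def _chain_once(
    matches: list[Match], orientation: str, max_gap: int
) -> tuple[list[int], float]:
    """Best-scoring monotone chain (indices into ``matches``) by DP.

    Anchors must be strictly increasing in rank_a and strictly monotone
    in rank_b (increasing for forward, decreasing for reverse); the number
    of skipped ranks between consecutive anchors (|delta| - 1) must not
    exceed ``max_gap`` on either side.
    """
    n = len(matches)
    sign = 1 if orientation == "forward" else -1
    best_score = [m.score for m in matches]
    prev = [-1] * n
    for i in range(n):
        mi = matches[i]
        for j in range(n):
            if j == i:
                continue
            mj = matches[j]
            da = mi.rank_a - mj.rank_a
            db = sign * (mi.rank_b - mj.rank_b)
            if da <= 0 or db <= 0:
                continue
            if da - 1 > max_gap or db - 1 > max_gap:
                continue
            cand = best_score[j] + mi.score
            if cand > best_score[i] + 1e-12:
                best_score[i] = cand
                prev[i] = j
    if not matches:
        return [], 0.0
    end = max(range(n), key=lambda i: (best_score[i], -matches[i].rank_a))
    chain = []
    i = end
    while i != -1:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    return chain, best_score[end]


def chain_collinear_blocks(
    table: MatchTable,
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE,
    max_gap: int = DEFAULT_MAX_GAP,
    min_score: float = 0.0,
) -> list[CollinearBlock]:
    """Greedy extraction of maximal-score collinear chains per chromosome
    pair and orientation; chains shorter than ``min_block_size`` are
    discarded.  ``min_score`` drops weak homology matches before
    chaining (true counterparts score orders of magnitude above k-mer
    noise, so a small floor like 0.05 removes spurious chains)."""
    by_pair: dict[tuple[str, str], list[Match]] = {}
    for m in table.rows:
        if m.score < min_score:
            continue
        if m.rank_a < 0 or m.rank_b < 0:
            raise ValueError("ranks must be populated before chaining")
        by_pair.setdefault((m.chrom_a, m.chrom_b), []).append(m)

    blocks: list[CollinearBlock] = []
    block_id = 0
    for (chrom_a, chrom_b) in sorted(by_pair):
        pool = sorted(
            by_pair[(chrom_a, chrom_b)],
            key=lambda m: (m.rank_a, m.rank_b, m.gene_a, m.gene_b),
        )
        while pool:
            candidates = []
            for orientation in ("forward", "reverse"):
                idx, score = _chain_once(pool, orientation, max_gap)
                candidates.append((score, len(idx), orientation, idx))
            candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
            score, length, orientation, idx = candidates[0]
            if length < min_block_size:
                break
            anchors = [pool[i] for i in idx]
            blocks.append(
                CollinearBlock(
                    block_id=block_id,
                    chrom_a=chrom_a,
                    chrom_b=chrom_b,
                    orientation=orientation,
                    anchors=anchors,
                    score=score,
                )
            )
            block_id += 1
            used = set(idx)
            pool = [m for i, m in enumerate(pool) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# WGD-block removal and pair extraction


def _median(values: list[float]) -> float:
    values = sorted(values)
    n = len(values)
    mid = n // 2
    return values[mid] if n % 2 else 0.5 * (values[mid - 1] + values[mid])


def _overlaps(b1: CollinearBlock, b2: CollinearBlock) -> bool:
    """Blocks claim overlapping gene ranges when they share anchor genes
    on either chromosome — the signature of an allelic block and a WGD
    duplicate both claiming one region.  (Rank-interval overlap alone
    would also flag legitimate inversion blocks nested inside a larger
    collinear run, which share no genes.)"""
    genes_a1 = {m.gene_a for m in b1.anchors}
    genes_a2 = {m.gene_a for m in b2.anchors}
    if b1.chrom_a == b2.chrom_a and genes_a1 & genes_a2:
        return True
    genes_b1 = {m.gene_b for m in b1.anchors}
    genes_b2 = {m.gene_b for m in b2.anchors}
    return b1.chrom_b == b2.chrom_b and bool(genes_b1 & genes_b2)


def filter_wgd_blocks(
    blocks: list[CollinearBlock],
    ks_per_pair: Mapping[tuple[str, str], float],
    ks_ceiling: float = DEFAULT_WGD_KS_CEILING,
) -> list[CollinearBlock]:
    """Drop likely WGD blocks: median anchor Ks above ``ks_ceiling``, and
    among blocks claiming overlapping gene ranges on one chromosome only
    the lowest-median-Ks block is retained as allelic."""
    annotated = []
    for block in blocks:
        ks_values = [
            ks_per_pair[(m.gene_a, m.gene_b)]
            for m in block.anchors
            if (m.gene_a, m.gene_b) in ks_per_pair
        ]
        block.median_ks = _median(ks_values) if ks_values else None
        annotated.append(block)

    survivors = [
        b for b in annotated if b.median_ks is None or b.median_ks <= ks_ceiling
    ]
    survivors.sort(
        key=lambda b: (b.median_ks if b.median_ks is not None else float("inf"), b.block_id)
    )
    kept: list[CollinearBlock] = []
    for block in survivors:
        if any(_overlaps(block, other) for other in kept):
            continue
        kept.append(block)
    kept.sort(key=lambda b: b.block_id)
    return kept


def extract_allele_pairs(blocks: list[CollinearBlock]) -> list[AllelePair]:
    """One pair per anchor; a gene claimed by several blocks goes to the
    highest-scoring block.  Locus ids are sequential in (chromosome,
    rank) order and deterministic."""
    ordered = sorted(blocks, key=lambda b: (-b.score, b.block_id))
    used_a: set[str] = set()
    used_b: set[str] = set()
    raw: list[tuple[str, int, str, str, int]] = []
    for block in ordered:
        for m in sorted(
            block.anchors, key=lambda m: (-m.score, m.gene_a, m.gene_b)
        ):
            if m.gene_a in used_a or m.gene_b in used_b:
                continue
            used_a.add(m.gene_a)
            used_b.add(m.gene_b)
            raw.append((m.chrom_a, m.rank_a, m.gene_a, m.gene_b, block.block_id))
    raw.sort()
    return [
        AllelePair(
            locus_id=f"locus_{i + 1:06d}", gene_a=a, gene_b=b, block_id=bid
        )
        for i, (_, _, a, b, bid) in enumerate(raw)
    ]


def write_match_table(table: MatchTable, path) -> None:
    """TSV: gene_a, gene_b, score (ranks are reattached from annotation)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for m in table.rows:
            fh.write(f"{m.gene_a}\t{m.gene_b}\t{m.score:.6g}\n")


def read_match_table(path) -> MatchTable:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_a", "gene_b", "score"]:
            raise ValueError("match table must have columns gene_a, gene_b, score")
        for line in fh:
            if not line.strip():
                continue
            gene_a, gene_b, score = line.rstrip("\n").split("\t")[:3]
            rows.append(Match(gene_a=gene_a, gene_b=gene_b, score=float(score)))
    return MatchTable(rows)


def pair_table_rows(pairs: Iterable[AllelePair]) -> list[dict]:
    return [
        dict(locus_id=p.locus_id, gene_a=p.gene_a, gene_b=p.gene_b, block_id=p.block_id)
        for p in pairs
    ]
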