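"""Synthetic diploid inputs with planted ground truth.

Every downstream stage consumes files this module can emit: a diploid
annotation with collinear allele pairs plus unpaired noise genes,
negative-binomial counts over tissues with planted bias categories, CDS
pairs evolved to target (Ka, Ks), promoters with planted motif
occurrences, TEs at controlled distances, Ks mixtures, LTR records in
controlled lifecycle proportions, and a k-mer histogram with a known
genome size.  The :class:`TruthTable` records what was planted so
recovery can be tested without external data.

Planted effects are coupled to the locus bias category the way the
analyses expect to find them: pairs in the ``largest`` category carry
nearer TEs, fewer shared promoter motifs, and higher planted Ka/Ks than
pairs in the ``smaller`` category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BedInterval, GeneRecord
from .kaks import NUCS, SENSE_CODONS, is_stop, ng86_sites, translate_codon
from .ltr import FlankEvidence, LibraryHit, LTRRecord
from .regctx import PWM

CATEGORIES = ("none", "smaller", "larger", "largest")
# band-midpoint fold changes per category (none: 1; smaller <= 2; 2 < larger < 8;
# largest >= 8)
CATEGORY_FC = {"none": 1.0, "smaller": 1.5, "larger": 4.0, "largest": 12.0}
DEFAULT_TISSUES = (
    "leaf",
    "bud",
    "rhizome",
    "rhizome_heart",
    "rhizome_skin",
    "lateral_tip",
    "upward_tip",
)
TE_LENGTH = 300
INTERGENIC_PAD = 2000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosome_pairs: int = 11
    genes_per_chromosome: int = 60
    fraction_unpaired: float = 0.1
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 4
    extra_replicates_first_tissue: int = 1  # 7 * 4 + 1 = 29 samples
    nb_dispersion: float = 0.05
    bias_category_mix: tuple[float, float, float, float] = (0.60, 0.15, 0.15, 0.10)
    promoter_length: int = 2000
    te_distance_grid: tuple[int, ...] = (0, 200, 600, 1500)
    kaks_grid: tuple[tuple[float, float], ...] = (
        (0.005, 0.05),
        (0.01, 0.10),
        (0.03, 0.20),
        (0.06, 0.30),
    )
    ks_mixture: tuple[tuple[float, float, float], ...] = (
        (0.3, 0.05, 0.6),
        (0.7, 0.10, 0.4),
    )
    ltr_mix: tuple[float, float, float] = (0.25, 0.50, 0.25)  # intact, solo, trunc
    mutation_rate: float = 1.3e-8
    cds_length_codons: int = 200
    n_expression_profiles: int = 4
    base_mean_log: float = 5.5
    base_mean_sd: float = 0.6
    n_ks_values: int = 2000
    n_ltr_records: int = 120
    n_ltr_families: int = 6
    ltr_length: int = 400
    n_motifs: int = 5
    motif_length: int = 10
    kmer_genome_size: float = 1.0e8
    kmer_peak_depth: int = 30
    invert_segment: bool = True  # plant one reverse-orientation block per pair

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")
        for name, mix in (
            ("bias_category_mix", self.bias_category_mix),
            ("ltr_mix", self.ltr_mix),
        ):
            if any(not 0 <= p <= 1 for p in mix):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
        if not 0 <= self.fraction_unpaired <= 1:
            raise ValueError("fraction_unpaired must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        weights = [w for _, _, w in self.ks_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("ks_mixture weights must sum to 1 within 1e-9")
        n_paired = round(self.genes_per_chromosome * (1 - self.fraction_unpaired))
        if n_paired < 5:
            raise ValueError(
                "genes_per_chromosome too small: "
                f"{self.genes_per_chromosome} genes at fraction_unpaired "
                f"{self.fraction_unpaired} leaves {n_paired} paired genes per "
                "chromosome, below the minimum collinear block size of 5"
            )
        if max(self.te_distance_grid) > self.promoter_length + INTERGENIC_PAD - TE_LENGTH:
            raise ValueError(
                "te_distance_grid exceeds the intergenic spacing; planted TEs "
                "would no longer be each gene's nearest TE"
            )
        for ka, ks in self.kaks_grid:
            _target_p(ks)  # raises if beyond the JC-correctable range
            _target_p(ka)

    @property
    def n_samples(self) -> int:
        return (
            len(self.tissues) * self.replicates_per_tissue
            + self.extra_replicates_first_tissue
        )

    def rng(self, stage: str) -> np.random.Generator:
        digest = sum(ord(c) * 31**i for i, c in enumerate(stage)) % (2**31)
        return np.random.default_rng([self.seed, digest])


def _target_p(d: float) -> float:
    """Expected observed proportion for a JC distance d; rejects targets
    too close to the saturation bound p = 3/4."""
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    if p >= 0.70:
        raise ValueError(
            f"requested divergence {d} implies p = {p:.3f}, beyond the "
            "JC-correctable range that sampling can recover (p >= 3/4 saturates)"
        )
    return p


@dataclass
class TruthTable:
    allele_pairs: list[tuple[str, str]] = field(default_factory=list)
    locus_category: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_category_per_tissue: dict[tuple[str, str], dict[str, str]] = field(
        default_factory=dict
    )
    planted_fc: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_kaks: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    planted_motif_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_te_distance: dict[str, int] = field(default_factory=dict)
    planted_ks_peaks: list[float] = field(default_factory=list)
    planted_ltr_class: dict[str, str] = field(default_factory=dict)
    planted_ltr_family: dict[str, int] = field(default_factory=dict)
    locus_profile: dict[tuple[str, str], int] = field(default_factory=dict)
    kmer_truth: dict[str, float] = field(default_factory=dict)

    def validate_against(self, genes: Sequence[GeneRecord]) -> None:
        known = {g.gene_id for g in genes}
        for a, b in self.allele_pairs:
            if a not in known or b not in known:
                raise ValueError(f"planted pair ({a}, {b}) missing from annotation")
        for cats in self.planted_category_per_tissue.values():
            for cat in cats.values():
                if cat not in CATEGORIES:
                    raise ValueError(f"unknown planted category {cat!r}")

    def to_json(self, path: str | Path) -> None:
        def pair_key(pair: tuple[str, str]) -> str:
            return f"{pair[0]}|{pair[1]}"

        payload = {
            "allele_pairs": [list(p) for p in self.allele_pairs],
            "locus_category": {pair_key(k): v for k, v in self.locus_category.items()},
            "planted_category_per_tissue": {
                pair_key(k): v for k, v in self.planted_category_per_tissue.items()
            },
            "planted_fc": {pair_key(k): v for k, v in self.planted_fc.items()},
            "planted_kaks": {
                pair_key(k): list(v) for k, v in self.planted_kaks.items()
            },
            "planted_motif_counts": self.planted_motif_counts,
            "planted_te_distance": self.planted_te_distance,
            "planted_ks_peaks": self.planted_ks_peaks,
            "planted_ltr_class": self.planted_ltr_class,
            "planted_ltr_family": self.planted_ltr_family,
            "locus_profile": {pair_key(k): v for k, v in self.locus_profile.items()},
            "kmer_truth": self.kmer_truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)

        def unkey(s: str) -> tuple[str, str]:
            a, b = s.split("|")
            return a, b

        return cls(
            allele_pairs=[tuple(p) for p in payload["allele_pairs"]],
            locus_category={unkey(k): v for k, v in payload["locus_category"].items()},
            planted_category_per_tissue={
                unkey(k): v
                for k, v in payload["planted_category_per_tissue"].items()
            },
            planted_fc={unkey(k): v for k, v in payload["planted_fc"].items()},
            planted_kaks={
                unkey(k): tuple(v) for k, v in payload["planted_kaks"].items()
            },
            planted_motif_counts={
                g: dict(v) for g, v in payload["planted_motif_counts"].items()
            },
            planted_te_distance=dict(payload["planted_te_distance"]),
            planted_ks_peaks=list(payload["planted_ks_peaks"]),
            planted_ltr_class=dict(payload["planted_ltr_class"]),
            planted_ltr_family={
                k: int(v) for k, v in payload["planted_ltr_family"].items()
            },
            locus_profile={unkey(k): v for k, v in payload["locus_profile"].items()},
            kmer_truth=dict(payload["kmer_truth"]),
        )


# ---------------------------------------------------------------------------
# annotation + genome


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NUCS))[rng.integers(0, 4, size=length)])


def generate_diploid_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], dict[str, str], TruthTable]:
    """Two haplotype gene sets with conserved order inside planted
    collinear runs; ``fraction_unpaired`` noise genes per haplotype have
    no counterpart.  Coordinates leave ``promoter_length`` clear upstream
    of every gene and never overlap on a strand."""
    rng = config.rng("annotation")
    truth = TruthTable()
    genes: list[GeneRecord] = []
    genome: dict[str, str] = {}
    gene_len = 3 * config.cds_length_codons
    step = gene_len + config.promoter_length + INTERGENIC_PAD

    n_total = config.genes_per_chromosome
    n_paired = round(n_total * (1 - config.fraction_unpaired))
    n_noise = n_total - n_paired

    for c in range(1, config.n_chromosome_pairs + 1):
        chrom_a, chrom_b = f"chrA{c:02d}", f"chrB{c:02d}"
        pair_ids = [
            (f"gA{c:02d}g{i:04d}", f"gB{c:02d}g{i:04d}") for i in range(n_paired)
        ]
        truth.allele_pairs.extend(pair_ids)

        order_a: list[str] = [a for a, _ in pair_ids]
        order_b: list[str] = [b for _, b in pair_ids]
        if config.invert_segment and n_paired >= 12:
            # reverse one interior run on haplotype B -> reverse-orientation block
            lo = n_paired // 3
            hi = lo + max(6, n_paired // 6)
            order_b[lo:hi] = order_b[lo:hi][::-1]
        noise_a = [f"nA{c:02d}g{i:04d}" for i in range(n_noise)]
        noise_b = [f"nB{c:02d}g{i:04d}" for i in range(n_noise)]
        for gene_id, order in zip(noise_a, _noise_slots(rng, n_paired, n_noise)):
            order_a.insert(order, gene_id)
        for gene_id, order in zip(noise_b, _noise_slots(rng, n_paired, n_noise)):
            order_b.insert(order, gene_id)

        for chrom, order in ((chrom_a, order_a), (chrom_b, order_b)):
            pos = config.promoter_length + 1  # 1-based gene start
            for gene_id in order:
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        chrom=chrom,
                        start=pos,
                        end=pos + gene_len - 1,
                        strand="+",
                    )
                )
                pos += step
            genome[chrom] = _random_dna(rng, pos - step + gene_len + 100)
    truth.validate_against(genes)
    return genes, genome, truth


def _noise_slots(rng: np.random.Generator, n_paired: int, n_noise: int) -> list[int]:
    slots = sorted(rng.integers(0, n_paired + 1, size=n_noise).tolist(), reverse=True)
    return slots


# ---------------------------------------------------------------------------
# counts


def _plant_locus_structure(
    truth: TruthTable, config: SimulationConfig
) -> None:
    """Assign each locus a bias category, a fold change, and a latent
    tissue profile (shared by both alleles -> coexpression structure)."""
    rng = config.rng("locus-structure")
    n = len(truth.allele_pairs)
    cats = rng.choice(len(CATEGORIES), size=n, p=list(config.bias_category_mix))
    profiles = rng.integers(0, config.n_expression_profiles, size=n)
    for pair, cat_idx, prof in zip(truth.allele_pairs, cats, profiles):
        category = CATEGORIES[cat_idx]
        truth.locus_category[pair] = category
        truth.planted_category_per_tissue[pair] = {
            t: category for t in config.tissues
        }
        truth.planted_fc[pair] = CATEGORY_FC[category]
        truth.locus_profile[pair] = int(prof)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    n_param = 1.0 / dispersion
    p_param = n_param / (n_param + mean)
    return rng.negative_binomial(n_param, p_param)


def simulate_counts(
    truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Integer NB counts (genes x samples) and the sample->tissue map.

    For a pair planted as category c, the ratio of generating means
    between alleles in every tissue equals the category's fold change
    (direction fixed per locus); both alleles share a latent tissue
    profile so allele pairs are coexpressed.
    """
    if not truth.locus_category:
        _plant_locus_structure(truth, config)
    rng = config.rng("counts")

    samples: list[str] = []
    sample_tissue: dict[str, str] = {}
    for t_idx, tissue in enumerate(config.tissues):
        reps = config.replicates_per_tissue + (
            config.extra_replicates_first_tissue if t_idx == 0 else 0
        )
        for r in range(1, reps + 1):
            name = f"{tissue}_r{r}"
            samples.append(name)
            sample_tissue[name] = tissue

    profile_matrix = np.exp(
        rng.normal(0.0, 0.8, size=(config.n_expression_profiles, len(config.tissues)))
    )

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []

    def tissue_means(base: float, profile: int) -> dict[str, float]:
        return {
            t: base * profile_matrix[profile, i]
            for i, t in enumerate(config.tissues)
        }

    for pair in truth.allele_pairs:
        gene_a, gene_b = pair
        base = float(
            np.exp(rng.normal(config.base_mean_log, config.base_mean_sd))
        )
        fc = truth.planted_fc[pair]
        direction = 1 if rng.random() < 0.5 else -1
        ratio = math.sqrt(fc)
        means = tissue_means(base, truth.locus_profile[pair])
        mean_a = np.array(
            [means[sample_tissue[s]] * (ratio if direction > 0 else 1 / ratio) for s in samples]
        )
        mean_b = np.array(
            [means[sample_tissue[s]] * (1 / ratio if direction > 0 else ratio) for s in samples]
        )
        gene_ids.append(gene_a)
        rows.append(_nb_draw(rng, mean_a, config.nb_dispersion))
        gene_ids.append(gene_b)
        rows.append(_nb_draw(rng, mean_b, config.nb_dispersion))

    n_noise = config.genes_per_chromosome - round(
        config.genes_per_chromosome * (1 - config.fraction_unpaired)
    )
    for c in range(1, config.n_chromosome_pairs + 1):
        for hap in "AB":
            for i in range(n_noise):
                gene_id = f"n{hap}{c:02d}g{i:04d}"
                base = float(
                    np.exp(rng.normal(config.base_mean_log, config.base_mean_sd))
                )
                profile = int(rng.integers(0, config.n_expression_profiles))
                means = tissue_means(base, profile)
                mean_vec = np.array([means[sample_tissue[s]] for s in samples])
                gene_ids.append(gene_id)
                rows.append(_nb_draw(rng, mean_vec, config.nb_dispersion))

    counts = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=int),
        index=gene_ids,
        columns=samples,
        dtype=int,
    )
    return counts, sample_tissue


# ---------------------------------------------------------------------------
# CDS pairs


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in codons)


def _plant_mutations(
    rng: np.random.Generator,
    cds: str,
    n_syn: int,
    n_nonsyn: int,
    used_positions: set[int],
) -> str:
    """Introduce exactly the requested numbers of synonymous and
    nonsynonymous single-nucleotide changes, never creating stops.

    Positions already carrying a mutation (on either lineage, via the
    shared ``used_positions`` set) are skipped so planted mutation counts
    equal observed differences and NG86 recovery is unbiased.
    """
    seq = list(cds)
    want = {"syn": n_syn, "nonsyn": n_nonsyn}
    attempts = 0
    max_attempts = 500 * (n_syn + n_nonsyn + 1)
    while (want["syn"] > 0 or want["nonsyn"] > 0) and attempts < max_attempts:
        attempts += 1
        pos = int(rng.integers(0, len(seq)))
        if pos in used_positions:
            continue
        codon_start = 3 * (pos // 3)
        codon = "".join(seq[codon_start : codon_start + 3])
        new_nuc = NUCS[int(rng.integers(0, 4))]
        if new_nuc == seq[pos]:
            continue
        offset = pos - codon_start
        mutant = codon[:offset] + new_nuc + codon[offset + 1 :]
        if is_stop(mutant):
            continue
        kind = "syn" if translate_codon(mutant) == translate_codon(codon) else "nonsyn"
        if want[kind] <= 0:
            continue
        want[kind] -= 1
        used_positions.add(pos)
        seq[pos] = new_nuc
    return "".join(seq)


def simulate_cds_pairs(
    truth: TruthTable, config: SimulationConfig
) -> dict[str, str]:
    """CDS for every gene: paired genes descend from a common ancestor
    mutated along both lineages so NG86 recovers the planted (Ka, Ks);
    noise genes get independent random CDS.  All sequences keep frame
    and contain no internal stops."""
    if not config.kaks_grid:
        raise ValueError("kaks_grid must be non-empty")
    if not truth.locus_category:
        _plant_locus_structure(truth, config)
    rng = config.rng("cds")
    grid_by_category = dict(zip(CATEGORIES, config.kaks_grid))
    cds: dict[str, str] = {}
    for pair in truth.allele_pairs:
        category = truth.locus_category[pair]
        ka, ks = grid_by_category.get(category, config.kaks_grid[-1])
        truth.planted_kaks[pair] = (ka, ks)
        ancestor = _random_cds(rng, config.cds_length_codons)
        s_sites = n_sites = 0.0
        for i in range(0, len(ancestor), 3):
            s, n = ng86_sites(ancestor[i : i + 3])
            s_sites += s
            n_sites += n
        n_syn_total = round(_target_p(ks) * s_sites)
        n_nonsyn_total = round(_target_p(ka) * n_sites)
        half_s, half_n = n_syn_total // 2, n_nonsyn_total // 2
        used: set[int] = set()
        seq_a = _plant_mutations(rng, ancestor, half_s, half_n, used)
        seq_b = _plant_mutations(
            rng, ancestor, n_syn_total - half_s, n_nonsyn_total - half_n, used
        )
        cds[pair[0]] = seq_a
        cds[pair[1]] = seq_b
    # noise genes: unrelated CDS
    n_total = config.genes_per_chromosome
    n_paired = round(n_total * (1 - config.fraction_unpaired))
    n_noise = n_total - n_paired
    for c in range(1, config.n_chromosome_pairs + 1):
        for hap in "AB":
            for i in range(n_noise):
                cds[f"n{hap}{c:02d}g{i:04d}"] = _random_cds(
                    rng, config.cds_length_codons
                )
    return cds


# ---------------------------------------------------------------------------
# regulatory context


def _default_motifs(config: SimulationConfig) -> list[PWM]:
    """Near-consensus PWMs (deterministic given the seed); information
    content well above the 8-bit recovery bar."""
    rng = config.rng("motifs")
    pwms = []
    for m in range(config.n_motifs):
        consensus = rng.integers(0, 4, size=config.motif_length)
        matrix = np.full((4, config.motif_length), 0.01)
        matrix[consensus, np.arange(config.motif_length)] = 0.97
        pwms.append(PWM(motif_id=f"motif{m:02d}", matrix=matrix))
    return pwms


# motifs shared/diverged per category: (n shared motifs, n allele-specific motifs)
CATEGORY_MOTIF_PLAN = {
    "none": (3, 0),
    "smaller": (3, 0),
    "larger": (2, 1),
    "largest": (1, 2),
}
CATEGORY_TE_RANK = {"largest": 0, "larger": 1, "smaller": 2, "none": 3}


def plant_regulatory_context(
    truth: TruthTable,
    config: SimulationConfig,
    genes: Sequence[GeneRecord],
    motifs: Sequence[PWM] | None = None,
) -> tuple[dict[str, str], list[BedInterval], list[PWM]]:
    """Promoter FASTA with planted exact-consensus motif insertions and a
    TE BED with one TE at the planted distance from each paired gene.

    Pairs in low-bias categories share motif plans between alleles; pairs
    in the ``largest`` category receive mostly allele-specific motifs and
    the nearest TEs.
    """
    if not truth.locus_category:
        _plant_locus_structure(truth, config)
    motifs = list(motifs) if motifs is not None else _default_motifs(config)
    for pwm in motifs:
        if pwm.length > config.promoter_length:
            raise ValueError(
                f"motif {pwm.motif_id} ({pwm.length} bp) longer than the "
                f"{config.promoter_length} bp promoter"
            )
    rng = config.rng("regulatory")
    gene_by_id = {g.gene_id: g for g in genes}
    promoters: dict[str, str] = {}
    tes: list[BedInterval] = []

    def build_promoter(gene_id: str, plan: dict[str, int]) -> None:
        seq = list(_random_dna(rng, config.promoter_length))
        placements: list[tuple[int, int]] = []
        counts: dict[str, int] = {}
        for motif_id, count in sorted(plan.items()):
            pwm = next(p for p in motifs if p.motif_id == motif_id)
            consensus = pwm.consensus()
            for _ in range(count):
                for _attempt in range(200):
                    offset = int(
                        rng.integers(0, config.promoter_length - pwm.length + 1)
                    )
                    span = (offset, offset + pwm.length)
                    if all(
                        span[1] <= s or span[0] >= e for s, e in placements
                    ):
                        placements.append(span)
                        seq[span[0] : span[1]] = list(consensus)
                        counts[motif_id] = counts.get(motif_id, 0) + 1
                        break
        promoters[gene_id] = "".join(seq)
        truth.planted_motif_counts[gene_id] = counts

    motif_ids = [p.motif_id for p in motifs]
    for pair in truth.allele_pairs:
        category = truth.locus_category[pair]
        n_shared, n_specific = CATEGORY_MOTIF_PLAN[category]
        chosen = list(
            rng.choice(motif_ids, size=min(len(motif_ids), n_shared + 2 * n_specific), replace=False)
        )
        shared = chosen[:n_shared]
        spec_a = chosen[n_shared : n_shared + n_specific]
        spec_b = chosen[n_shared + n_specific : n_shared + 2 * n_specific]
        plan_a = {m: 1 for m in shared}
        plan_a.update({m: 1 for m in spec_a})
        plan_b = {m: 1 for m in shared}
        plan_b.update({m: 1 for m in spec_b})
        build_promoter(pair[0], plan_a)
        build_promoter(pair[1], plan_b)

        distance = config.te_distance_grid[
            min(CATEGORY_TE_RANK[category], len(config.te_distance_grid) - 1)
        ]
        for gene_id in pair:
            gene = gene_by_id[gene_id]
            g_start, g_end = gene.interval0()
            if distance == 0:
                start = max(g_start, g_end - TE_LENGTH // 2)
            else:
                start = g_end + distance
            tes.append(
                BedInterval(gene.chrom, start, start + TE_LENGTH, f"TE_{gene_id}")
            )
            truth.planted_te_distance[gene_id] = distance

    # noise genes: plain background promoters, no planted TE
    for gene in genes:
        if gene.gene_id not in promoters:
            promoters[gene.gene_id] = _random_dna(rng, config.promoter_length)
            truth.planted_motif_counts[gene.gene_id] = {}
    tes.sort(key=lambda te: (te.chrom, te.start, te.name))
    return promoters, tes, motifs


# ---------------------------------------------------------------------------
# Ks, LTR, k-mer histogram


def simulate_ks_and_ltr(
    config: SimulationConfig, with_ltr_sequences: bool = True
) -> tuple[np.ndarray, list[LTRRecord], dict[int, float], TruthTable]:
    """Ks mixture samples (truncated to [0, 5]), LTR records in the
    configured lifecycle mix with class-consistent evidence, and a k-mer
    histogram whose total mass equals genome_size x peak_depth exactly.

    Returns a fresh :class:`TruthTable` carrying only the planted fields
    of this stage (callers merge as needed).
    """
    rng = config.rng("ks-ltr")
    truth = TruthTable()
    truth.planted_ks_peaks = [mean for mean, _, _ in config.ks_mixture]

    # --- Ks mixture
    weights = np.array([w for _, _, w in config.ks_mixture])
    means = np.array([m for m, _, _ in config.ks_mixture])
    sds = np.array([s for _, s, _ in config.ks_mixture])
    ks_values = np.empty(config.n_ks_values)
    filled = 0
    while filled < config.n_ks_values:
        comp = rng.choice(len(weights), size=config.n_ks_values - filled, p=weights)
        draw = rng.normal(means[comp], sds[comp])
        ok = draw[(draw >= 0) & (draw <= 5.0)]
        ks_values[filled : filled + ok.size] = ok
        filled += ok.size
    ks_values.sort()

    # --- LTR records
    classes = rng.choice(3, size=config.n_ltr_records, p=list(config.ltr_mix))
    families = rng.integers(0, config.n_ltr_families, size=config.n_ltr_records)
    family_consensus = [
        _random_dna(rng, config.ltr_length) for _ in range(config.n_ltr_families)
    ]
    records: list[LTRRecord] = []
    class_names = ("intact", "solo", "truncated")
    for i in range(config.n_ltr_records):
        cls = class_names[classes[i]]
        record_id = f"LTR{i:05d}"
        age_years = float(rng.uniform(1e5, 4e6))
        divergence = 2.0 * config.mutation_rate * age_years
        if with_ltr_sequences:
            ltr5 = _mutate_dna(rng, family_consensus[families[i]], 0.05)
            ltr3 = _mutate_dna(rng, ltr5, min(_target_p(divergence), 0.6))
        else:
            ltr5 = ltr3 = ""
        if cls == "intact":
            record = LTRRecord(
                record_id=record_id,
                gagpol_complete=True,
                ltr5_seq=ltr5,
                ltr3_seq=ltr3,
                divergence=divergence,
            )
        elif cls == "solo":
            record = LTRRecord(
                record_id=record_id,
                gagpol_complete=False,
                ltr5_seq=ltr5,
                library_hit=LibraryHit(
                    evalue=float(rng.uniform(1e-14, 1e-11)),
                    overlap_fraction=float(rng.uniform(0.92, 1.0)),
                    identity=float(rng.uniform(0.92, 1.0)),
                ),
                flank_evidence=(None, None),
            )
        else:
            record = LTRRecord(
                record_id=record_id,
                gagpol_complete=False,
                ltr5_seq=ltr5,
                library_hit=LibraryHit(
                    evalue=float(rng.uniform(1e-14, 1e-11)),
                    overlap_fraction=float(rng.uniform(0.92, 1.0)),
                    identity=float(rng.uniform(0.92, 1.0)),
                ),
                flank_evidence=(
                    FlankEvidence(
                        coverage_fraction=float(rng.uniform(0.55, 0.9)),
                        identity=float(rng.uniform(0.35, 0.7)),
                        evalue=float(rng.uniform(1e-12, 1e-9)),
                    ),
                    None,
                ),
            )
        truth.planted_ltr_class[record_id] = cls
        truth.planted_ltr_family[record_id] = int(families[i])
        records.append(record)

    # --- k-mer histogram (exact total mass = genome size x peak depth)
    histogram = _build_kmer_histogram(
        rng, config.kmer_genome_size, config.kmer_peak_depth
    )
    truth.kmer_truth = {
        "genome_size": config.kmer_genome_size,
        "peak_depth": float(config.kmer_peak_depth),
    }
    return ks_values, records, histogram, truth


def _mutate_dna(rng: np.random.Generator, seq: str, p: float) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for pos in hits:
        choices = [n for n in NUCS if n != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _build_kmer_histogram(
    rng: np.random.Generator, genome_size: float, peak_depth: int
) -> dict[int, float]:
    target_total = genome_size * peak_depth
    depths = np.arange(3, 3 * peak_depth)
    hom = np.exp(-0.5 * ((depths - peak_depth) / (peak_depth / 6)) ** 2)
    het = 0.5 * np.exp(-0.5 * ((depths - peak_depth / 2) / (peak_depth / 8)) ** 2)
    shape = hom + het
    shape /= shape.sum()
    provisional = np.floor(shape * target_total / np.maximum(depths, 1) / 2)
    histogram = {int(d): float(c) for d, c in zip(depths, provisional) if c > 0}
    rest = sum(d * c for d, c in histogram.items() if d != peak_depth)
    histogram[peak_depth] = (target_total - rest) / peak_depth
    # error tail at depths 1-2 (excluded by the estimator)
    histogram[1] = float(10 * genome_size // peak_depth)
    histogram[2] = float(2 * genome_size // peak_depth)
    return dict(sorted(histogram.items()))
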