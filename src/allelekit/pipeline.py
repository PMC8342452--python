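"""End-to-end orchestration over a working directory of plain-text files.

``run_pipeline`` executes the stages in dependency order on a (by
default simulated) dataset, persists every intermediate as TSV/JSON, and
returns a run report whose numbers are all recomputable from the
persisted files.  Identical config + seed gives an identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, ase, coexpr, dating, io, ltr as ltr_mod, regctx
from .kaks import kaks_for_cds
from .pairing import (
    AllelePair,
    build_match_table,
    chain_collinear_blocks,
    extract_allele_pairs,
    filter_wgd_blocks,
)
from .simulate import (
    SimulationConfig,
    generate_diploid_annotation,
    plant_regulatory_context,
    simulate_cds_pairs,
    simulate_counts,
    simulate_ks_and_ltr,
)
from .stats import mann_whitney_u

ALL_STAGES = (
    "simulate",
    "pair",
    "kaks",
    "ase",
    "tfbs",
    "tedist",
    "coexpr",
    "date",
    "ltr",
    "report",
)


@dataclass
class PipelineConfig:
    workdir: str = "pipeline_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # thresholds, defaulting to the published values
    tpm_expressed: float = 0.5
    fc_small: float = 2.0
    fc_large: float = 8.0
    alpha: float = 0.05
    top_fraction: float = 0.10
    pwm_p_threshold: float = 1e-5
    pwm_pseudocount: float = 1e-8
    scale_free_target: float = 0.9
    min_module_size: int = 60
    merge_cut_height: float = 0.15
    divergence_fraction: float = 0.5
    ks_ceiling: float = 5.0
    wgd_ks_ceiling: float = 0.15
    mutation_rate: float = 1.3e-8
    min_block_size: int = 5
    max_gap: int = 25
    min_match_score: float = 0.05
    ks_anchor: float = 0.7
    t_anchor_years: float = 63.57e6
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        # workdir excluded: the same analysis in two directories is the
        # same run
        payload = {k: v for k, v in asdict(self).items() if k != "workdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _split_haplotypes(
    genes: list[io.GeneRecord],
) -> tuple[list[io.GeneRecord], list[io.GeneRecord]]:
    hap_a = [g for g in genes if g.chrom.startswith("chrA")]
    hap_b = [g for g in genes if g.chrom.startswith("chrB")]
    return hap_a, hap_b


def _write_ltr_records(records: list[ltr_mod.LTRRecord], path: Path) -> None:
    rows = []
    for r in records:
        hit = r.library_hit
        f1, f2 = r.flank_evidence
        rows.append(
            dict(
                record_id=r.record_id,
                gagpol_complete=int(r.gagpol_complete),
                lib_evalue=hit.evalue if hit else "",
                lib_overlap=hit.overlap_fraction if hit else "",
                lib_identity=hit.identity if hit else "",
                flank1_coverage=f1.coverage_fraction if f1 else "",
                flank1_identity=f1.identity if f1 else "",
                flank1_evalue=f1.evalue if f1 else "",
                flank2_coverage=f2.coverage_fraction if f2 else "",
                flank2_identity=f2.identity if f2 else "",
                flank2_evalue=f2.evalue if f2 else "",
                divergence=r.divergence if r.divergence is not None else "",
                ltr5_seq=r.ltr5_seq,
                ltr3_seq=r.ltr3_seq,
                cls=r.cls,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ltr_records(path: str | Path) -> list[ltr_mod.LTRRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        hit = None
        if row.lib_evalue != "":
            hit = ltr_mod.LibraryHit(
                float(row.lib_evalue), float(row.lib_overlap), float(row.lib_identity)
            )
        flanks = []
        for cov, ident, ev in (
            (row.flank1_coverage, row.flank1_identity, row.flank1_evalue),
            (row.flank2_coverage, row.flank2_identity, row.flank2_evalue),
        ):
            flanks.append(
                ltr_mod.FlankEvidence(float(cov), float(ident), float(ev))
                if cov != ""
                else None
            )
        records.append(
            ltr_mod.LTRRecord(
                record_id=str(row.record_id),
                gagpol_complete=bool(int(row.gagpol_complete)),
                library_hit=hit,
                flank_evidence=(flanks[0], flanks[1]),
                divergence=float(row.divergence) if row.divergence != "" else None,
                ltr5_seq=str(row.ltr5_seq),
                ltr3_seq=str(row.ltr3_seq),
            )
        )
    return records


def contrast_by_category(
    values_by_category: Mapping[str, Mapping[str, np.ndarray]],
    min_group: int = 3,
) -> dict:
    """Per-category summaries and pairwise Mann–Whitney–Wilcoxon tests.

    ``values_by_category`` maps metric -> category -> values.  Categories
    with fewer than ``min_group`` members are skipped (noted).
    """
    out: dict = {}
    for metric, groups in values_by_category.items():
        summary = {}
        skipped = []
        usable = {}
        for cat, values in groups.items():
            values = np.asarray(
                [v for v in np.asarray(values, dtype=float) if np.isfinite(v)]
            )
            if values.size < min_group:
                skipped.append(cat)
                continue
            usable[cat] = values
            summary[cat] = dict(
                n=int(values.size),
                median=float(np.median(values)),
                mean=float(values.mean()),
            )
        tests = {}
        cats = sorted(usable)
        for i, c1 in enumerate(cats):
            for c2 in cats[i + 1 :]:
                _, p = mann_whitney_u(usable[c1], usable[c2])
                tests[f"{c1}|{c2}"] = p
        out[metric] = dict(summary=summary, pairwise_p=tests, skipped=sorted(skipped))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the report dict (also persisted)."""
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": sorted(stages, key=ALL_STAGES.index),
        "thresholds": {
            "tpm_expressed": config.tpm_expressed,
            "fc_cutoffs": [config.fc_small, config.fc_large],
            "alpha": config.alpha,
            "top_fraction": config.top_fraction,
            "pwm_p_threshold": config.pwm_p_threshold,
            "scale_free_target": config.scale_free_target,
            "min_module_size": config.min_module_size,
            "merge_cut_height": config.merge_cut_height,
            "ks_ceiling": config.ks_ceiling,
            "mutation_rate": config.mutation_rate,
        },
    }

    sim = SimulationConfig(**{**asdict(config.sim), "seed": config.seed})

    # ------------------------------------------------------------ simulate
    if "simulate" in stages:
        genes, genome, truth = generate_diploid_annotation(sim)
        counts, sample_tissue = simulate_counts(truth, sim)
        cds = simulate_cds_pairs(truth, sim)
        promoters, tes, motifs = plant_regulatory_context(truth, sim, genes)
        ks_values, ltr_records, kmer_hist, ks_truth = simulate_ks_and_ltr(sim)
        truth.planted_ks_peaks = ks_truth.planted_ks_peaks
        truth.planted_ltr_class = ks_truth.planted_ltr_class
        truth.planted_ltr_family = ks_truth.planted_ltr_family
        truth.kmer_truth = ks_truth.kmer_truth

        io.write_gff3(genes, work / "genes.gff3")
        io.write_fasta(genome, work / "genome.fa")
        io.write_fasta(cds, work / "cds.fa")
        io.write_fasta(promoters, work / "promoters.fa")
        regctx.write_jaspar(motifs, work / "motifs.jaspar")
        io.write_bed(tes, work / "tes.bed")
        io.write_counts(counts, work / "counts.tsv")
        io.write_sample_sheet(sample_tissue, work / "samples.tsv")
        truth.to_json(work / "truth.json")
        pd.DataFrame({"ks": ks_values}).to_csv(work / "ks_values.tsv", sep="\t", index=False)
        _write_ltr_records(ltr_records, work / "ltr_records.tsv")
        io.write_kmer_histogram(kmer_hist, work / "kmer_histogram.tsv")
        report["simulate"] = {
            "n_genes": len(genes),
            "n_pairs_planted": len(truth.allele_pairs),
            "n_samples": counts.shape[1],
        }

    genes: list[io.GeneRecord] = []
    cds: dict[str, str] = {}
    if stages & {"pair", "kaks", "ase", "tfbs", "tedist", "coexpr", "report"}:
        genes = io.read_gff3(work / "genes.gff3")
        gene_lengths = pd.Series({g.gene_id: g.end - g.start + 1 for g in genes})
    if stages & {"pair", "kaks"}:
        cds = io.read_fasta(work / "cds.fa")

    # ---------------------------------------------------------------- pair
    kaks_cache: dict[tuple[str, str], object] = {}

    def ks_of(pair: tuple[str, str]) -> float | None:
        if pair not in kaks_cache:
            kaks_cache[pair] = kaks_for_cds(cds[pair[0]], cds[pair[1]])
        return kaks_cache[pair].ks

    if "pair" in stages:
        hap_a, hap_b = _split_haplotypes(genes)
        precomputed = work / "match_table.tsv"
        if precomputed.exists():
            from .pairing import read_match_table

            table = read_match_table(precomputed).with_ranks(hap_a, hap_b)
        else:
            cds_a = {g.gene_id: cds[g.gene_id] for g in hap_a if g.gene_id in cds}
            cds_b = {g.gene_id: cds[g.gene_id] for g in hap_b if g.gene_id in cds}
            table = build_match_table(
                cds_a, cds_b, top_k=3, genes_a=hap_a, genes_b=hap_b
            )
        blocks = chain_collinear_blocks(
            table,
            min_block_size=config.min_block_size,
            max_gap=config.max_gap,
            min_score=config.min_match_score,
        )
        ks_per_pair = {}
        for block in blocks:
            for m in block.anchors:
                value = ks_of((m.gene_a, m.gene_b))
                if value is not None:
                    ks_per_pair[(m.gene_a, m.gene_b)] = value
        blocks = filter_wgd_blocks(blocks, ks_per_pair, ks_ceiling=config.wgd_ks_ceiling)
        pairs = extract_allele_pairs(blocks)
        pd.DataFrame(
            [
                dict(locus_id=p.locus_id, gene_a=p.gene_a, gene_b=p.gene_b, block_id=p.block_id)
                for p in pairs
            ]
        ).to_csv(work / "pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                dict(
                    block_id=b.block_id,
                    chrom_a=b.chrom_a,
                    chrom_b=b.chrom_b,
                    orientation=b.orientation,
                    n_anchors=len(b.anchors),
                    score=b.score,
                    median_ks=b.median_ks,
                )
                for b in blocks
            ]
        ).to_csv(work / "blocks.tsv", sep="\t", index=False)
        report["pair"] = {"n_blocks": len(blocks), "n_pairs": len(pairs)}

    pairs: list[AllelePair] = []
    if stages & {"kaks", "ase", "tfbs", "coexpr", "report"}:
        pairs_df = pd.read_csv(work / "pairs.tsv", sep="\t")
        pairs = [
            AllelePair(r.locus_id, r.gene_a, r.gene_b, int(r.block_id))
            for r in pairs_df.itertuples(index=False)
        ]

    # ---------------------------------------------------------------- kaks
    if "kaks" in stages:
        rows = []
        for p in pairs:
            result = kaks_cache.get((p.gene_a, p.gene_b))
            if result is None:
                result = kaks_for_cds(cds[p.gene_a], cds[p.gene_b])
            rows.append(
                dict(
                    locus_id=p.locus_id,
                    ka=result.ka,
                    ks=result.ks,
                    ratio=result.ratio,
                    n_sites=result.n_sites,
                    s_sites=result.s_sites,
                    method=result.method,
                    excluded=int(result.excluded),
                )
            )
        pd.DataFrame(rows).to_csv(work / "kaks.tsv", sep="\t", index=False)
        report["kaks"] = {"n_pairs": len(rows)}

    # ----------------------------------------------------------------- ase
    if stages & {"ase", "coexpr"}:
        counts = io.read_counts(work / "counts.tsv")
        sample_tissue = io.read_sample_sheet(work / "samples.tsv")
        tissues = list(dict.fromkeys(sample_tissue.values()))
        tpm = ase.compute_tpm(counts, gene_lengths)
    if "ase" in stages:
        expressed = set(ase.filter_expressed(tpm, config.tpm_expressed))
        testable = [
            p for p in pairs if p.gene_a in expressed or p.gene_b in expressed
        ]
        calls = ase.test_allelic_bias(counts, testable, sample_tissue)
        ase.calls_to_frame(calls).to_csv(work / "bias_calls.tsv", sep="\t", index=False)
        profiles = ase.build_profiles(calls, tissues)
        profiles = ase.rank_dynamic_stable(profiles, config.top_fraction)
        pd.DataFrame(
            [
                dict(locus_id=p.locus_id, fc_range=p.fc_range, label=p.label)
                for p in profiles
            ]
        ).to_csv(work / "profiles.tsv", sep="\t", index=False)
        transitions = ase.transition_summary(calls, tissues)
        with open(work / "transitions.json", "w") as fh:
            json.dump(transitions, fh, indent=1, sort_keys=True)
        per_tissue = {}
        frame = ase.calls_to_frame(calls)
        for tissue, sub in frame.groupby("tissue"):
            fractions = sub["category"].value_counts(normalize=True).to_dict()
            per_tissue[tissue] = {c: fractions.get(c, 0.0) for c in
                                  ("none", "smaller", "larger", "largest")}
        report["ase"] = {
            "n_expressed_genes": len(expressed),
            "n_tested_pairs": len(testable),
            "category_fractions": per_tissue,
            "transitions_overall": transitions["overall"],
        }

    # ---------------------------------------------------------------- tfbs
    if "tfbs" in stages:
        promoters = io.read_fasta(work / "promoters.fa")
        motifs = regctx.read_jaspar(work / "motifs.jaspar", config.pwm_pseudocount)
        scanners = [regctx.PWMScanner(p) for p in motifs]
        hit_rows = []
        compare_rows = []
        for p in pairs:
            hits_a = []
            hits_b = []
            for scanner in scanners:
                hits_a.extend(
                    scanner.scan(promoters[p.gene_a], p.gene_a, config.pwm_p_threshold)
                )
                hits_b.extend(
                    scanner.scan(promoters[p.gene_b], p.gene_b, config.pwm_p_threshold)
                )
            comparison = regctx.compare_tfbs(hits_a, hits_b, p.locus_id)
            compare_rows.append(asdict_comparison(comparison))
            for h in hits_a + hits_b:
                hit_rows.append(
                    dict(
                        gene_id=h.gene_id,
                        motif_id=h.motif_id,
                        offset=h.offset,
                        strand=h.strand,
                        score=h.score,
                        p=h.p,
                    )
                )
        pd.DataFrame(hit_rows).to_csv(work / "tfbs_hits.tsv", sep="\t", index=False)
        pd.DataFrame(compare_rows).to_csv(work / "tfbs_compare.tsv", sep="\t", index=False)
        report["tfbs"] = {"n_hits": len(hit_rows), "n_pairs": len(compare_rows)}

    # -------------------------------------------------------------- te-dist
    if "tedist" in stages:
        tes = io.read_bed(work / "tes.bed")
        rows = []
        for g in genes:
            prox = regctx.nearest_te_distance(g, tes)
            rows.append(
                dict(
                    gene_id=g.gene_id,
                    nearest_te_distance=(
                        prox.nearest_te_distance
                        if prox.nearest_te_distance is not None
                        else ""
                    ),
                    te_id=prox.te_id or "",
                )
            )
        pd.DataFrame(rows).to_csv(work / "te_distance.tsv", sep="\t", index=False)
        report["tedist"] = {"n_genes": len(rows)}

    # --------------------------------------------------------------- coexpr
    if "coexpr" in stages:
        expressed = set(ase.filter_expressed(tpm, config.tpm_expressed))
        allele_genes = sorted(
            {g for p in pairs for g in (p.gene_a, p.gene_b) if g in expressed}
        )
        net_config = coexpr.NetworkConfig(
            scale_free_target=config.scale_free_target,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height,
        )
        assignment = coexpr.detect_modules(tpm.loc[allele_genes], net_config)
        calls, withheld = coexpr.classify_allele_divergence(pairs, assignment)
        pd.DataFrame(
            sorted(assignment.gene_module.items()),
            columns=["gene_id", "module"],
        ).to_csv(work / "modules.tsv", sep="\t", index=False)
        pd.DataFrame(
            {f"M{m}": v for m, v in sorted(assignment.eigengenes.items())}
        ).to_csv(work / "eigengenes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                dict(locus_id=c.locus_id, cls=c.cls, distance=c.distance, threshold=c.threshold)
                for c in calls
            ]
        ).to_csv(work / "divergence.tsv", sep="\t", index=False)
        n = len(calls) + withheld
        fractions = {
            cls: sum(1 for c in calls if c.cls == cls) / n if n else 0.0
            for cls in ("coordinated", "similar", "divergent")
        }
        fractions["withheld"] = withheld / n if n else 0.0
        report["coexpr"] = {
            "soft_power": assignment.soft_power,
            "n_modules": len(assignment.eigengenes),
            "fractions": fractions,
        }

    # ----------------------------------------------------------------- date
    if "date" in stages:
        ks_values = pd.read_csv(work / "ks_values.tsv", sep="\t")["ks"].to_numpy()
        dist = dating.KsDistribution(ks_values)
        peaks = dating.detect_ks_peaks(dist)
        cal = dating.calibrate_rate(config.ks_anchor, config.t_anchor_years)
        dated = [
            dating.date_event(peak, cal, label=f"peak{i}")
            for i, peak in enumerate(peaks)
        ]
        ltr_records = read_ltr_records(work / "ltr_records.tsv")
        ages = {
            r.record_id: dating.ltr_insertion_time(r.divergence, config.mutation_rate)
            for r in ltr_records
            if r.divergence is not None
        }
        histogram = io.read_kmer_histogram(work / "kmer_histogram.tsv")
        genome_size, peak_depth = dating.kmer_genome_size(histogram)
        payload = {
            "ks_peaks": peaks,
            "rate": cal.r,
            "dated_events_mya": {d.label: d.age_mya for d in dated},
            "ltr_ages_years": ages,
            "genome_size": genome_size,
            "kmer_peak_depth": peak_depth,
        }
        with open(work / "dating.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        report["date"] = {
            "ks_peaks": peaks,
            "dated_events_mya": payload["dated_events_mya"],
            "genome_size": genome_size,
        }

    # ------------------------------------------------------------------ ltr
    if "ltr" in stages:
        ltr_records = read_ltr_records(work / "ltr_records.tsv")
        for r in ltr_records:
            ltr_mod.classify_ltr(r)
        if all(r.ltr5_seq for r in ltr_records):
            ltr_mod.cluster_ltrs(ltr_records)
        stats = ltr_mod.lifecycle_ratios(ltr_records)
        _write_ltr_records(ltr_records, work / "ltr_classified.tsv")
        payload = {
            "intact": stats.n_intact,
            "solo": stats.n_solo,
            "truncated": stats.n_truncated,
            "unclassified": stats.n_unclassified,
            "si_ratio": stats.si_ratio,
            "ti_ratio": stats.ti_ratio,
            "sti_ratio": stats.sti_ratio,
            "fraction_clusters_si_gt3": stats.fraction_clusters_si_gt3,
            "n_clusters": len(stats.per_cluster),
        }
        with open(work / "ltr_stats.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        report["ltr"] = payload

    # --------------------------------------------------------------- report
    if "report" in stages:
        report["contrasts"] = build_contrasts(work)
    with open(work / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def asdict_comparison(c: regctx.TFBSComparison) -> dict:
    return dict(
        locus_id=c.locus_id,
        shared=c.shared,
        specific_a=c.specific_a,
        specific_b=c.specific_b,
        shared_types=c.shared_types,
        specific_types_a=c.specific_types_a,
        specific_types_b=c.specific_types_b,
    )


def build_contrasts(workdir: str | Path) -> dict:
    """Category-grouped metric distributions with pairwise MWW tests,
    recomputed from the persisted intermediates."""
    work = Path(workdir)
    pairs = pd.read_csv(work / "pairs.tsv", sep="\t")
    calls = pd.read_csv(work / "bias_calls.tsv", sep="\t")
    global_calls = calls[calls["tissue"] == "global"].set_index("locus_id")
    category = global_calls["category"]

    metrics: dict[str, dict[str, np.ndarray]] = {}

    def add_metric(name: str, per_locus: pd.Series) -> None:
        groups: dict[str, list[float]] = {}
        for locus, value in per_locus.items():
            if locus not in category.index or pd.isna(value):
                continue
            groups.setdefault(category[locus], []).append(float(value))
        metrics[name] = {k: np.array(v) for k, v in groups.items()}

    kaks_df = pd.read_csv(work / "kaks.tsv", sep="\t").set_index("locus_id")
    add_metric("ka", kaks_df["ka"])
    add_metric("ks", kaks_df["ks"])
    add_metric("kaks_ratio", kaks_df["ratio"])

    tfbs = pd.read_csv(work / "tfbs_compare.tsv", sep="\t").set_index("locus_id")
    add_metric("shared_tfbs", tfbs["shared"])
    add_metric("specific_tfbs", tfbs["specific_a"] + tfbs["specific_b"])

    te = pd.read_csv(work / "te_distance.tsv", sep="\t").set_index("gene_id")
    te_dist = pd.to_numeric(te["nearest_te_distance"], errors="coerce")
    pair_te = pairs.set_index("locus_id").apply(
        lambda r: np.nanmin(
            [te_dist.get(r["gene_a"], np.nan), te_dist.get(r["gene_b"], np.nan)]
        )
        if not (
            pd.isna(te_dist.get(r["gene_a"], np.nan))
            and pd.isna(te_dist.get(r["gene_b"], np.nan))
        )
        else np.nan,
        axis=1,
    )
    add_metric("te_distance", pair_te)

    counts = io.read_counts(work / "counts.tsv")
    genes = io.read_gff3(work / "genes.gff3")
    lengths = pd.Series({g.gene_id: g.end - g.start + 1 for g in genes})
    tpm = ase.compute_tpm(counts, lengths)
    mean_tpm = tpm.mean(axis=1)
    pair_tpm = pairs.set_index("locus_id").apply(
        lambda r: 0.5 * (mean_tpm.get(r["gene_a"], np.nan) + mean_tpm.get(r["gene_b"], np.nan)),
        axis=1,
    )
    add_metric("mean_tpm", pair_tpm)

    return contrast_by_category(metrics)
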