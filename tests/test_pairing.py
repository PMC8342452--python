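"""Match-table construction, collinear chaining, WGD filtering, pair extraction."""

from __future__ import annotations

import numpy as np
import pytest

from allelekit.io import GeneRecord
from allelekit.pairing import (
    CollinearBlock,
    Match,
    MatchTable,
    build_match_table,
    chain_collinear_blocks,
    extract_allele_pairs,
    filter_wgd_blocks,
)


def make_match(ra, rb, score=1.0, chrom_a="A1", chrom_b="B1"):
    return Match(
        gene_a=f"a{ra}",
        gene_b=f"b{rb}",
        score=score,
        chrom_a=chrom_a,
        chrom_b=chrom_b,
        rank_a=ra,
        rank_b=rb,
    )


def brute_force_best_chain(matches, max_gap):
    """Enumerate every monotone gap-constrained chain (both orientations);
    return the best total score.  Exponential; instances must stay tiny."""
    best = 0.0
    n = len(matches)
    for orientation in (1, -1):
        order = sorted(range(n), key=lambda i: matches[i].rank_a)

        def dfs(prev, score, start):
            nonlocal best
            best = max(best, score)
            for nxt in range(start, n):
                i = order[nxt]
                if prev is not None:
                    da = matches[i].rank_a - matches[prev].rank_a
                    db = orientation * (matches[i].rank_b - matches[prev].rank_b)
                    if da <= 0 or db <= 0 or da - 1 > max_gap or db - 1 > max_gap:
                        continue
                dfs(i, score + matches[i].score, nxt + 1)

        dfs(None, 0.0, 0)
    return best


class TestBuildMatchTable:
    def test_identical_sets_self_similarity_one(self):
        cds = {f"g{i}": "ATGGCTAAACCCGGGTTTCTGCAT" * 4 for i in range(3)}
        # make them distinct so best match is the counterpart
        cds = {
            "g0": "ATGGCTAAACCCGGGTTTCTGCATGAAGAT" * 3,
            "g1": "ATGTGGCATCATGGGAAACCCTTTGATGAA" * 3,
            "g2": "ATGAAAGGGCCCTTTGCTGCTCATTGGCTG" * 3,
        }
        other = {f"h{i}": seq for i, seq in zip(range(3), cds.values())}
        table = build_match_table(cds, other, top_k=1)
        best = {m.gene_a: (m.gene_b, m.score) for m in table.rows}
        for i in range(3):
            assert best[f"g{i}"] == (f"h{i}", pytest.approx(1.0))

    def test_disjoint_random_sequences_near_zero(self, rng):
        from allelekit.simulate import _random_cds

        cds_a = {f"a{i}": _random_cds(rng, 100) for i in range(5)}
        cds_b = {f"b{i}": _random_cds(rng, 100) for i in range(5)}
        table = build_match_table(cds_a, cds_b, top_k=1)
        assert all(m.score < 0.05 for m in table.rows)

    def test_untranslatable_skipped_with_warning(self):
        cds_a = {"good": "ATGGCTAAACCCGGGTTTCTGCAT" * 3, "bad": "ATGGC"}
        cds_b = {"other": "ATGGCTAAACCCGGGTTTCTGCAT" * 3}
        with pytest.warns(UserWarning, match="skipped 1"):
            build_match_table(cds_a, cds_b)

    def test_mutated_counterparts_rank_first(self, small_dataset):
        """True counterpart is the top match for >= 99% of paired genes."""
        truth = small_dataset["truth"]
        cds = small_dataset["cds"]
        genes = small_dataset["genes"]
        hap_a = [g for g in genes if g.chrom.startswith("chrA")]
        hap_b = [g for g in genes if g.chrom.startswith("chrB")]
        table = build_match_table(
            {g.gene_id: cds[g.gene_id] for g in hap_a},
            {g.gene_id: cds[g.gene_id] for g in hap_b},
            top_k=1,
        )
        best = {m.gene_a: m.gene_b for m in table.rows}
        hits = sum(1 for a, b in truth.allele_pairs if best.get(a) == b)
        assert hits >= 0.99 * len(truth.allele_pairs)


class TestChaining:
    def test_empty_input(self):
        assert chain_collinear_blocks(MatchTable([])) == []

    def test_planted_forward_run(self):
        matches = [make_match(i, i) for i in range(5)]
        blocks = chain_collinear_blocks(MatchTable(matches), min_block_size=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward"
        assert len(blocks[0].anchors) == 5

    def test_planted_reverse_run(self):
        matches = [make_match(i, 4 - i) for i in range(5)]
        blocks = chain_collinear_blocks(MatchTable(matches), min_block_size=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "reverse"

    def test_short_runs_discarded(self):
        matches = [make_match(i, i) for i in range(4)]
        assert chain_collinear_blocks(MatchTable(matches), min_block_size=5) == []

    def test_gap_constraint_respected(self):
        matches = [make_match(i, i) for i in range(5)] + [
            make_match(50, 50), make_match(51, 51), make_match(52, 52),
            make_match(53, 53), make_match(54, 54),
        ]
        blocks = chain_collinear_blocks(
            MatchTable(matches), min_block_size=5, max_gap=10
        )
        assert len(blocks) == 2

    def test_row_order_invariance(self, rng):
        matches = [
            make_match(int(ra), int(rb), float(s))
            for ra, rb, s in zip(
                rng.permutation(20), rng.permutation(20), rng.uniform(0.5, 1, 20)
            )
        ]
        blocks1 = chain_collinear_blocks(MatchTable(matches), min_block_size=2)
        shuffled = list(matches)
        rng.shuffle(shuffled)
        blocks2 = chain_collinear_blocks(MatchTable(shuffled), min_block_size=2)
        sig1 = [(b.orientation, [(m.rank_a, m.rank_b) for m in b.anchors]) for b in blocks1]
        sig2 = [(b.orientation, [(m.rank_a, m.rank_b) for m in b.anchors]) for b in blocks2]
        assert sig1 == sig2

    def test_matches_brute_force_oracle_small_instances(self, rng):
        """Best extracted chain score equals exhaustive enumeration for
        instances of <= 12 matches."""
        for trial in range(40):
            n = int(rng.integers(2, 13))
            ranks_a = rng.choice(30, size=n, replace=False)
            ranks_b = rng.choice(30, size=n, replace=False)
            scores = rng.uniform(0.1, 1.0, size=n)
            matches = [
                make_match(int(a), int(b), float(s))
                for a, b, s in zip(ranks_a, ranks_b, scores)
            ]
            blocks = chain_collinear_blocks(
                MatchTable(matches), min_block_size=1, max_gap=29
            )
            best_block = max((b.score for b in blocks), default=0.0)
            oracle = brute_force_best_chain(matches, max_gap=29)
            assert best_block == pytest.approx(oracle), trial


class TestWgdFilter:
    def _block(self, block_id, anchors, chrom_a="A1", chrom_b="B1"):
        return CollinearBlock(
            block_id=block_id,
            chrom_a=chrom_a,
            chrom_b=chrom_b,
            orientation="forward",
            anchors=anchors,
            score=sum(m.score for m in anchors),
        )

    def test_overlapping_blocks_lower_ks_retained(self):
        shared = [make_match(i, i) for i in range(3)]
        rival = [
            Match(f"a{i}", f"c{i}", 1.0, "A1", "B1", i, 10 + i) for i in range(3)
        ]
        b1 = self._block(0, shared)
        b2 = self._block(1, rival)
        ks = {(m.gene_a, m.gene_b): 0.02 for m in shared}
        ks.update({(m.gene_a, m.gene_b): 0.12 for m in rival})
        kept = filter_wgd_blocks([b1, b2], ks, ks_ceiling=0.15)
        assert [b.block_id for b in kept] == [0]

    def test_block_above_ceiling_dropped(self):
        anchors = [make_match(i, i) for i in range(3)]
        block = self._block(0, anchors)
        ks = {(m.gene_a, m.gene_b): 0.3 for m in anchors}
        assert filter_wgd_blocks([block], ks, ks_ceiling=0.15) == []

    def test_no_overlap_all_below_ceiling_unchanged(self):
        b1 = self._block(0, [make_match(i, i) for i in range(3)])
        b2 = self._block(
            1, [Match(f"x{i}", f"y{i}", 1.0, "A2", "B2", i, i) for i in range(3)]
        )
        ks = {(m.gene_a, m.gene_b): 0.05 for m in b1.anchors + b2.anchors}
        kept = filter_wgd_blocks([b1, b2], ks)
        assert [b.block_id for b in kept] == [0, 1]

    def test_median_ks_annotated(self):
        anchors = [make_match(i, i) for i in range(3)]
        block = self._block(0, anchors)
        ks = {("a0", "b0"): 0.01, ("a1", "b1"): 0.02, ("a2", "b2"): 0.05}
        kept = filter_wgd_blocks([block], ks)
        assert kept[0].median_ks == pytest.approx(0.02)


class TestExtractPairs:
    def _block(self, block_id, anchors, score=None):
        return CollinearBlock(
            block_id=block_id,
            chrom_a="A1",
            chrom_b="B1",
            orientation="forward",
            anchors=anchors,
            score=score if score is not None else sum(m.score for m in anchors),
        )

    def test_disjoint_blocks_counting(self):
        b1 = self._block(0, [make_match(i, i) for i in range(5)])
        b2 = self._block(
            1, [Match(f"x{i}", f"y{i}", 1.0, "A1", "B1", 10 + i, 10 + i) for i in range(5)]
        )
        pairs = extract_allele_pairs([b1, b2])
        assert len(pairs) == 10

    def test_shared_gene_appears_once(self):
        m_shared = make_match(0, 0)
        b1 = self._block(0, [m_shared, make_match(1, 1)], score=10.0)
        b2 = self._block(
            1, [Match("a0", "z0", 1.0, "A1", "B1", 0, 20), make_match(2, 2)], score=1.0
        )
        pairs = extract_allele_pairs([b1, b2])
        genes_a = [p.gene_a for p in pairs]
        assert genes_a.count("a0") == 1
        # the higher-scoring block wins the shared gene
        winner = next(p for p in pairs if p.gene_a == "a0")
        assert winner.gene_b == "b0"

    def test_locus_ids_sequential_deterministic(self):
        b = self._block(0, [make_match(i, i) for i in range(3)])
        pairs = extract_allele_pairs([b])
        assert [p.locus_id for p in pairs] == [
            "locus_000001", "locus_000002", "locus_000003",
        ]

    def test_pair_count_bounded_and_unique(self, rng):
        anchors = [make_match(i, i, float(s)) for i, s in enumerate(rng.uniform(size=8))]
        pairs = extract_allele_pairs([self._block(0, anchors)])
        genes = [p.gene_a for p in pairs] + [p.gene_b for p in pairs]
        assert len(set(genes)) == len(genes)
        assert len(pairs) <= 8


class TestMatchTableIO:
    def test_round_trip(self, tmp_path):
        from allelekit.pairing import read_match_table, write_match_table

        table = MatchTable(
            [Match("gA1", "gB1", 0.75), Match("gA2", "gB2", 0.5)]
        )
        path = tmp_path / "matches.tsv"
        write_match_table(table, path)
        back = read_match_table(path)
        assert [(m.gene_a, m.gene_b, m.score) for m in back.rows] == [
            ("gA1", "gB1", 0.75),
            ("gA2", "gB2", 0.5),
        ]

    def test_bad_header_rejected(self, tmp_path):
        from allelekit.pairing import read_match_table

        path = tmp_path / "bad.tsv"
        path.write_text("x\ty\tz\n")
        with pytest.raises(ValueError, match="columns"):
            read_match_table(path)

    def test_ranks_reattach_from_annotation(self, tmp_path):
        from allelekit.pairing import read_match_table, write_match_table

        genes_a = [GeneRecord("gA1", "chrA01", 100, 200)]
        genes_b = [GeneRecord("gB1", "chrB01", 100, 200)]
        path = tmp_path / "m.tsv"
        write_match_table(MatchTable([Match("gA1", "gB1", 1.0)]), path)
        table = read_match_table(path).with_ranks(genes_a, genes_b)
        assert table.rows[0].rank_a == 0
        assert table.rows[0].chrom_b == "chrB01"


class TestEndToEndRecovery:
    def test_recovery_against_truth(self, small_dataset):
        """>= 95% recall and >= 99% precision vs the planted truth."""
        from allelekit.kaks import kaks_for_cds

        truth = small_dataset["truth"]
        cds = small_dataset["cds"]
        genes = small_dataset["genes"]
        hap_a = [g for g in genes if g.chrom.startswith("chrA")]
        hap_b = [g for g in genes if g.chrom.startswith("chrB")]
        table = build_match_table(
            {g.gene_id: cds[g.gene_id] for g in hap_a},
            {g.gene_id: cds[g.gene_id] for g in hap_b},
            top_k=3,
            genes_a=hap_a,
            genes_b=hap_b,
        )
        blocks = chain_collinear_blocks(table, min_score=0.05)
        ks = {}
        for block in blocks:
            for m in block.anchors:
                result = kaks_for_cds(cds[m.gene_a], cds[m.gene_b])
                if result.ks is not None:
                    ks[(m.gene_a, m.gene_b)] = result.ks
        blocks = filter_wgd_blocks(blocks, ks)
        pairs = extract_allele_pairs(blocks)
        called = {(p.gene_a, p.gene_b) for p in pairs}
        planted = set(truth.allele_pairs)
        tp = len(called & planted)
        assert tp / len(planted) >= 0.95
        assert tp / len(called) >= 0.99
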