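"""Readers/writers for the plain-text formats the pipeline exchanges.

Conventions: GFF3 coordinates are 1-based inclusive, BED is 0-based
half-open, counts tables are TSV with ``gene_id`` plus one column per
sample.  All writers emit deterministically ordered output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class GeneRecord:
    """One gene: GFF3-style 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval for BED-style arithmetic."""
        return self.start - 1, self.end


@dataclass(frozen=True)
class BedInterval:
    """0-based half-open interval (BED)."""

    chrom: str
    start: int
    end: int
    name: str = "."


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


# ---------------------------------------------------------------------------
# GFF3 genes


def write_gff3(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tallelekit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path: str | Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                GeneRecord(
                    gene_id=attrs["ID"],
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else "."
            out.append(BedInterval(f[0], int(f[1]), int(f[2]), name))
    return out


# ---------------------------------------------------------------------------
# tabular


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_sheet(sample_tissue: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\n")
        for sample, tissue in sample_tissue.items():
            fh.write(f"{sample}\t{tissue}\n")


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["tissue"]))


def write_kmer_histogram(histogram: Mapping[int, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for depth in sorted(histogram):
            count = histogram[depth]
            text = f"{count:.6f}".rstrip("0").rstrip(".")
            fh.write(f"{depth}\t{text}\n")


def read_kmer_histogram(path: str | Path) -> dict[int, float]:
    out: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            depth, count = line.split("\t")
            out[int(depth)] = float(count)
    return out
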