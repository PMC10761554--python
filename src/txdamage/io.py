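"""Plain-text readers and writers: FASTA, BED6, BED12, gene/count tables."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import FormatError, GeneModel, StrandedInterval

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "exon_starts", "exon_ends"]


def read_fasta(path) -> dict:
    """Chrom -> uppercase sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str], width: int = 60):
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_table(path, genes: Sequence[GeneModel]):
    """TSV gene table; coordinates 0-based half-open, exons comma-separated."""
    rows = []
    for g in genes:
        exons = sorted(g.exons)
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "exon_starts": ",".join(str(s) for s, _ in exons),
                "exon_ends": ",".join(str(e) for _, e in exons),
            }
        )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene table missing columns {missing}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            starts = [int(s) for s in str(row.exon_starts).split(",") if s not in ("", "nan")]
            ends = [int(e) for e in str(row.exon_ends).split(",") if e not in ("", "nan")]
            if len(starts) != len(ends):
                raise FormatError("exon_starts/exon_ends length mismatch")
            genes.append(
                GeneModel(
                    gene_id=row.gene_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    exons=tuple(zip(starts, ends)),
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return genes


def read_bed12(path) -> list:
    """BED12 records as GeneModel (blocks -> exons); validates block fields."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: line {i}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
                block_count = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path}: line {i} ({name}): blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            try:
                genes.append(GeneModel(name, chrom, start, end, strand, exons))
            except FormatError as exc:
                raise FormatError(f"{path}: line {i} ({name}): {exc}") from exc
    return genes


def read_bed6(path) -> list:
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}: line {i}: BED6 needs 6 fields, got {len(f)}")
            try:
                intervals.append(
                    StrandedInterval(f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5])
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {i}: {exc}") from exc
    return intervals


def write_bed6(path, intervals: Sequence[StrandedInterval]):
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def write_counts(path, gene_ids: Sequence[str], matrix: np.ndarray, sample_names: Sequence[str]):
    df = pd.DataFrame(np.asarray(matrix), index=list(gene_ids), columns=list(sample_names))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty count table")
    return df


def write_de_table(path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "padj"):
        if col not in df.columns:
            raise FormatError(f"{path}: DE table missing column {col!r}")
    return df
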