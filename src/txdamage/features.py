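"""Gene-architecture features: length, GC fraction, exon fraction, promoters.

Gene length is the genomic span (end - start), not the summed exon length,
and GC is computed over the full unspliced gene-body sequence: damage is a
property of the genome, not of the mature transcript.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import ArchFeatures, GeneModel, StrandedInterval

logger = logging.getLogger(__name__)


class UndefinedFeatureError(ValueError):
    """A feature has no defined value for the given input (e.g. all-N sequence)."""


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T), case-insensitive; N bases are excluded
    from both numerator and denominator.

    Raises
    ------
    UndefinedFeatureError
        If the sequence contains no A/C/G/T bases.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedFeatureError("gc_fraction undefined: no A/C/G/T bases")
    return gc / (gc + at)


def at_fraction(sequence: str) -> float:
    """Complement of :func:`gc_fraction` over counted bases."""
    return 1.0 - gc_fraction(sequence)


def merge_intervals(intervals: Iterable[tuple]) -> list:
    """Union of half-open intervals, returned sorted and non-overlapping.

    Adjacent (touching) intervals are coalesced.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def exon_fraction(gene: GeneModel) -> float:
    """Merged exon length divided by genomic span. No exons -> 0.0."""
    if not gene.exons:
        return 0.0
    covered = sum(e - s for s, e in merge_intervals(gene.exons))
    return covered / gene.length_bp


def compute_features(
    genes: Sequence[GeneModel], sequences: Mapping[str, str]
) -> list:
    """ArchFeatures for each gene, reading gene-body sequence from `sequences`."""
    out = []
    for g in genes:
        seq = sequences[g.chrom][g.start : g.end]
        out.append(
            ArchFeatures(
                gene_id=g.gene_id,
                length_bp=g.length_bp,
                gc_fraction=gc_fraction(seq),
                exon_fraction=exon_fraction(g),
            )
        )
    return out


def tertile_assign(values, boundaries: tuple | None = None):
    """Split values into low/mid/high bins at the 33.3/66.7 percentiles.

    Parameters
    ----------
    values : array-like of finite numbers, length >= 3.
    boundaries : optional (b1, b2) pair to impose externally derived cutoffs
        (e.g. cutoffs computed on a different gene universe) instead of the
        percentiles of `values`.

    Returns
    -------
    (labels, (b1, b2)) where labels[i] is "low" if v < b1, "mid" if
    b1 <= v <= b2, "high" if v > b2.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("tertile_assign requires finite values")
    if boundaries is None:
        if arr.size < 3:
            raise ValueError("tertile_assign requires at least 3 values")
        b1, b2 = np.percentile(arr, [100.0 / 3.0, 200.0 / 3.0])
    else:
        b1, b2 = boundaries
        if b1 > b2:
            raise ValueError("boundaries must satisfy b1 <= b2")
    labels = np.where(arr < b1, "low", np.where(arr > b2, "high", "mid"))
    return labels.tolist(), (float(b1), float(b2))


def extract_promoters(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    flank_bp: int = 3000,
) -> list:
    """Strand-aware upstream flanks of length `flank_bp` (gene body excluded).

    "+" gene -> [max(0, start - flank), start); "-" gene -> [end,
    min(chrom_len, end + flank)). Genes whose flank is clipped to zero length
    are skipped with a warning.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    promoters = []
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise KeyError(f"chrom_sizes missing {g.chrom!r}")
        clen = chrom_sizes[g.chrom]
        if g.strand == "+":
            s, e = max(0, g.start - flank_bp), g.start
        else:
            s, e = g.end, min(clen, g.end + flank_bp)
        if s >= e:
            logger.warning(
                "gene %s: promoter clipped to zero length at chromosome edge; skipped",
                g.gene_id,
            )
            continue
        promoters.append(
            StrandedInterval(g.chrom, s, e, name=g.gene_id, score=0, strand=g.strand)
        )
    return promoters
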