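"""Strand-specific aggregation of damage/repair reads over gene bodies.

A read overlapping a gene by >= 1 bp on the strand opposite the gene's
annotation increments the transcribed-strand (template) tally; same-strand
overlap increments the non-transcribed tally. The convention is flippable
via ``ts_is_antisense`` for assays that report the opposite orientation.
"""
from __future__ import annotations

import bisect
import logging
from typing import Mapping, Sequence

import numpy as np

from .models import CoverageProfile, GeneModel, StrandedInterval

logger = logging.getLogger(__name__)


def transcribed_strand_coverage(
    reads: Sequence[StrandedInterval],
    genes: Sequence[GeneModel],
    ts_is_antisense: bool = True,
):
    """Count reads per gene, split by transcribed vs non-transcribed strand.

    A read overlapping two genes increments both (no disambiguation). Reads
    on chromosomes absent from the gene set are skipped and tallied in the
    returned report.

    Returns
    -------
    (profiles, report) where profiles maps gene_id -> CoverageProfile and
    report records skipped read counts and the unknown chromosome names.
    """
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.start, g.end, g.gene_id))
        starts = [g.start for g in glist]
        ends = [g.end for g in glist]
        cummax_ends = list(np.maximum.accumulate(ends)) if ends else []
        index[chrom] = (glist, starts, ends, cummax_ends)

    profiles = {g.gene_id: CoverageProfile(gene_id=g.gene_id) for g in genes}
    skipped = 0
    unknown_chroms: set = set()
    for r in reads:
        idx = index.get(r.chrom)
        if idx is None:
            skipped += 1
            unknown_chroms.add(r.chrom)
            continue
        glist, starts, _ends, cummax_ends = idx
        hi = bisect.bisect_left(starts, r.end)  # genes with start < read.end
        lo = bisect.bisect_right(cummax_ends, r.start)  # first with end > read.start
        for k in range(lo, hi):
            g = glist[k]
            if g.end > r.start:  # half-open overlap >= 1 bp
                p = profiles[g.gene_id]
                antisense = r.strand != g.strand
                if antisense == ts_is_antisense:
                    p.ts_count += 1
                else:
                    p.nts_count += 1
    if skipped:
        logger.warning(
            "skipped %d reads on unknown chromosomes: %s",
            skipped,
            ", ".join(sorted(unknown_chroms)),
        )
    report = {"skipped_reads": skipped, "unknown_chroms": sorted(unknown_chroms)}
    return profiles, report


def normalize_coverage(count: float, library_size: float, gene_length_bp: float) -> float:
    """Reads per kilobase of gene per million reads of library."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    return count / ((gene_length_bp / 1000.0) * (library_size / 1e6))


def add_normalization(
    profiles: Mapping[str, CoverageProfile],
    genes: Sequence[GeneModel],
    library_size: float,
) -> Mapping[str, CoverageProfile]:
    """Fill ts_norm/nts_norm in-place for every profiled gene."""
    lengths = {g.gene_id: g.length_bp for g in genes}
    for gid, p in profiles.items():
        p.ts_norm = normalize_coverage(p.ts_count, library_size, lengths[gid])
        p.nts_norm = normalize_coverage(p.nts_count, library_size, lengths[gid])
    return profiles
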