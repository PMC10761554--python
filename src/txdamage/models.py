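"""Core domain records shared across the pipeline.

Coordinates are 0-based, half-open everywhere (BED semantics). Strand is
"+" or "-"; the transcribed (template) strand of a gene is the strand
opposite its annotation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-")


class FormatError(ValueError):
    """A record or file violates its declared format."""


@dataclass(frozen=True)
class GeneModel:
    """One gene's genomic span, strand, and exon intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        for es, ee in self.exons:
            if es >= ee:
                raise FormatError(f"gene {self.gene_id}: empty exon ({es},{ee})")
            if es < self.start or ee > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon ({es},{ee}) outside span "
                    f"[{self.start},{self.end})"
                )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def template_strand(self) -> str:
        """Strand read by the polymerase (opposite the annotated strand)."""
        return "-" if self.strand == "+" else "+"


@dataclass(frozen=True)
class StrandedInterval:
    """A stranded genomic interval (BED6 semantics)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(f"interval {self.chrom}:{self.start}-{self.end} is empty")
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ArchFeatures:
    """Gene-architecture determinants used for stratification."""

    gene_id: str
    length_bp: int
    gc_fraction: float
    exon_fraction: float


@dataclass
class CoverageProfile:
    """Per-gene stranded read tallies with optional RPKM-style normalization."""

    gene_id: str
    ts_count: int = 0
    nts_count: int = 0
    ts_norm: float = math.nan
    nts_norm: float = math.nan


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression result under one condition."""

    gene_id: str
    log2fc: float
    padj: float | None = None
    condition: tuple | None = None
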