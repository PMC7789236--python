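"""Typed records for every table the analysis touches.

Loops come from HICCUPS-style BEDPE tables (two anchors per row), domains from
HiTAD-style level-annotated tables, genes from GFF3, peaks and repeats from
BED, expression from a per-replicate TPM table, and eQTLs from a three-part
record (eQTL region, lead SNP, associated gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import GenomicInterval, StrandedInterval

GENE_FEATURE_TYPES = frozenset(
    {"gene", "lincRNA_gene", "miRNA_gene", "tRNA_gene"}
)

MAX_DOMAIN_LEVEL = 6


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop: two ordered anchors on one chromosome.

    ``anchor1`` is the left anchor after normalization
    (``anchor1.start <= anchor2.start``). The interior is the gap between the
    anchors and is only defined when they do not overlap.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    loop_id: str

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(
                f"loop {self.loop_id}: inter-chromosomal anchors "
                f"{self.anchor1.chrom} vs {self.anchor2.chrom}"
            )
        if self.anchor1.start > self.anchor2.start:
            raise ValueError(
                f"loop {self.loop_id}: anchors not ordered; normalize first"
            )

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def interior(self) -> Optional[GenomicInterval]:
        """Interval between the two anchors, or None when they touch/overlap."""
        if self.anchor1.end >= self.anchor2.start:
            return None
        return GenomicInterval(self.chrom, self.anchor1.end, self.anchor2.start)

    @property
    def span(self) -> GenomicInterval:
        """Full extent from the left edge of anchor1 to the right edge of anchor2."""
        return GenomicInterval(
            self.chrom, self.anchor1.start, max(self.anchor1.end, self.anchor2.end)
        )

    @property
    def length(self) -> int:
        """Anchor-to-anchor distance (loop length, as in length distributions)."""
        return self.anchor2.start - self.anchor1.start

    @staticmethod
    def make(
        chrom: str, x1: int, x2: int, y1: int, y2: int, loop_id: str
    ) -> "LoopRecord":
        """Build a loop from raw coordinates, ordering the anchors."""
        a = GenomicInterval(chrom, x1, x2)
        b = GenomicInterval(chrom, y1, y2)
        if b.start < a.start or (b.start == a.start and b.end < a.end):
            a, b = b, a
        return LoopRecord(a, b, loop_id)


@dataclass(frozen=True)
class DomainRecord:
    """A TAD-like domain or nested sub-domain with its hierarchy level.

    Level 0 domains are roots; levels 1..6 are successively nested
    sub-domains.
    """

    span: GenomicInterval
    level: int

    def __post_init__(self) -> None:
        if not (0 <= self.level <= MAX_DOMAIN_LEVEL):
            raise ValueError(
                f"domain level must be in 0..{MAX_DOMAIN_LEVEL}, got {self.level}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene model (gene / lincRNA_gene / miRNA_gene / tRNA_gene) with strand."""

    span: StrandedInterval
    gene_id: str
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_type not in GENE_FEATURE_TYPES:
            raise ValueError(
                f"gene {self.gene_id}: feature_type {self.feature_type!r} "
                f"not in {sorted(GENE_FEATURE_TYPES)}"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene replicate TPMs, their mean, and the expressed call (mean >= 1)."""

    gene_id: str
    tpm_by_replicate: tuple
    mean_tpm: float
    expressed: bool


@dataclass(frozen=True)
class PeakRecord:
    """An open-chromatin (ATAC-seq NF) peak, optionally tagged with a replicate."""

    span: GenomicInterval
    peak_id: str
    replicate: Optional[str] = None


@dataclass(frozen=True)
class ConsensusPeak:
    """Union interval of cross-replicate overlapping peaks with its support."""

    span: GenomicInterval
    support: int
    peak_id: str = ""


@dataclass(frozen=True)
class EqtlRecord:
    """An eQTL: its genomic region, 1-bp lead SNP, and associated gene id.

    ``snp_in_region`` flags whether the lead SNP falls inside the stated
    region (records with the SNP outside are accepted but flagged).
    """

    region: GenomicInterval
    lead_snp: GenomicInterval
    gene_id: str
    eqtl_id: str = ""

    def __post_init__(self) -> None:
        if self.lead_snp.length != 1:
            raise ValueError(
                f"eQTL {self.eqtl_id or self.gene_id}: lead SNP must be 1 bp"
            )

    @property
    def snp_in_region(self) -> bool:
        return self.region.contains(self.lead_snp)


@dataclass(frozen=True)
class RepeatRecord:
    """A repeat-element annotation (strand ignored throughout)."""

    span: GenomicInterval
    repeat_id: str = ""
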