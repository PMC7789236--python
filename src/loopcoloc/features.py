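"""Expression thresholding, consensus-peak construction and peak–gene proximity.

A gene is "expressed" when its replicate-mean TPM is at or above a threshold
(default 1). Consensus open-chromatin peaks are connected components of
cross-replicate overlapping peaks, kept when they touch at least
``min_support`` distinct replicates. Peak–gene proximity follows the
bedtools-closest convention: a signed distance (0 on overlap) combined with
the gene's strand yields one of four classes — overlapping, <2 kb upstream,
<2 kb downstream, or >2 kb away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

from .intervals import (
    GenomicInterval,
    NoNeighborError,
    SignedDistance,
    closest_feature,
    overlap_length,
)
from .records import ConsensusPeak, ExpressionRecord, GeneRecord, PeakRecord

PROXIMITY_CATEGORIES = ("overlap", "upstream_lt2kb", "downstream_lt2kb", "farther_2kb")


@dataclass(frozen=True)
class ProximityClass:
    """A peak-to-gene (or gene-to-peak) proximity call with its distance."""

    category: str
    distance: SignedDistance

    def __post_init__(self) -> None:
        if self.category not in PROXIMITY_CATEGORIES:
            raise ValueError(f"unknown proximity category {self.category!r}")


def compute_expression(
    table: pd.DataFrame, threshold: float = 1.0
) -> list[ExpressionRecord]:
    """Average per-replicate TPMs and call each gene expressed at mean >= threshold.

    ``table`` must hold a ``gene_id`` column plus one column per replicate
    (any column whose name starts with ``tpm``). The threshold boundary is
    inclusive: a gene with mean TPM exactly 1.0 is expressed.
    """
    tpm_cols = [c for c in table.columns if str(c).lower().startswith("tpm")]
    if not tpm_cols:
        raise ValueError("expression table has no tpm_* replicate columns")
    if (table[tpm_cols] < 0).any().any():
        raise ValueError("negative TPM value in expression table")
    records = []
    for row in table.itertuples(index=False):
        tpms = tuple(float(getattr(row, c)) for c in tpm_cols)
        mean = sum(tpms) / len(tpms)
        records.append(
            ExpressionRecord(
                gene_id=str(row.gene_id),
                tpm_by_replicate=tpms,
                mean_tpm=mean,
                expressed=mean >= threshold,
            )
        )
    return records


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_consensus_peaks(
    replicate_sets: Sequence[Sequence[PeakRecord]],
    min_support: int = 2,
    min_overlap_bp: int = 1,
) -> list[ConsensusPeak]:
    """Merge per-replicate peak calls into replicate-supported consensus peaks.

    Peaks across all replicates are grouped into connected components under
    pairwise overlap >= ``min_overlap_bp``; each component touching at least
    ``min_support`` distinct replicates is emitted as the union interval of
    its members, with support = number of distinct contributing replicates.
    """
    if not replicate_sets or min_support < 1:
        raise ValueError("need >= 1 replicate peak set and min_support >= 1")
    # fewer replicates than min_support cannot produce a consensus; the
    # result is the empty set rather than an error
    tagged: list[Tuple[GenomicInterval, int]] = []  # (interval, replicate index)
    for r, peaks in enumerate(replicate_sets):
        for p in peaks:
            tagged.append((p.span, r))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
    uf = _UnionFind(len(tagged))
    # sweep: only peaks in the active window (same chrom, start < running max end)
    # can satisfy a >= min_overlap_bp pairwise overlap
    active: list[int] = []
    for i, (iv, _r) in enumerate(tagged):
        active = [
            j
            for j in active
            if tagged[j][0].chrom == iv.chrom and tagged[j][0].end > iv.start
        ]
        for j in active:
            if overlap_length(tagged[j][0], iv) >= min_overlap_bp:
                uf.union(i, j)
        active.append(i)
    components: dict[int, list[int]] = {}
    for i in range(len(tagged)):
        components.setdefault(uf.find(i), []).append(i)
    consensus = []
    for members in components.values():
        reps = {tagged[i][1] for i in members}
        if len(reps) < min_support:
            continue
        ivs = [tagged[i][0] for i in members]
        consensus.append(
            (
                GenomicInterval(
                    ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs)
                ),
                len(reps),
            )
        )
    consensus.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    return [
        ConsensusPeak(span, support, f"C{i + 1}")
        for i, (span, support) in enumerate(consensus)
    ]


def orient_category(
    distance: SignedDistance, strand: str, proximity_bp: int = 2000
) -> str:
    """Proximity category from a signed distance and the gene's strand.

    Right of a ``+`` gene is 3' (downstream); right of a ``-`` gene is 5'
    (upstream). The |distance| == proximity_bp boundary counts as the
    near (<2 kb) class.
    """
    if distance.side == "overlap":
        return "overlap"
    if abs(distance.value) > proximity_bp:
        return "farther_2kb"
    right_of_gene = distance.side == "right"
    downstream = right_of_gene if strand == "+" else not right_of_gene
    return "downstream_lt2kb" if downstream else "upstream_lt2kb"


def classify_peak_gene_proximity(
    peak: PeakRecord,
    genes: Sequence[GeneRecord],
    proximity_bp: int = 2000,
) -> Tuple[Optional[GeneRecord], ProximityClass]:
    """Nearest gene to a peak and the peak's proximity class relative to it.

    The signed distance is taken from the gene's frame (negative = peak left
    of the gene), so upstream/downstream reflect the gene's strand. With no
    gene on the peak's chromosome, returns (None, farther_2kb) — the peak is
    distal by definition.
    """
    by_span = {g.span: g for g in genes}
    try:
        span, _ = closest_feature(
            peak.span, list(by_span), key=lambda iv: by_span[iv].gene_id
        )
    except NoNeighborError:
        return None, ProximityClass(
            "farther_2kb", SignedDistance(proximity_bp + 1, "right")
        )
    gene = by_span[span]
    # re-sign from the gene's frame: peak left of gene => negative
    from .intervals import signed_distance

    dist = signed_distance(gene.span, peak.span)
    return gene, ProximityClass(orient_category(dist, gene.span.strand, proximity_bp), dist)


def classify_gene_nearest_peak(
    gene: GeneRecord,
    peaks: Sequence[GenomicInterval],
    proximity_bp: int = 2000,
) -> ProximityClass:
    """Proximity class of a gene's nearest peak (the anchor-annotation direction).

    With no peak on the gene's chromosome the gene is in the "nearest peak
    >2 kb away" class.
    """
    try:
        _, dist = closest_feature(gene.span, peaks)
    except NoNeighborError:
        return ProximityClass("farther_2kb", SignedDistance(proximity_bp + 1, "right"))
    return ProximityClass(orient_category(dist, gene.span.strand, proximity_bp), dist)
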