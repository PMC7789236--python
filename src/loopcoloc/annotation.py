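"""Distinct-anchor annotation and loop-level gene/peak content summaries.

Each distinct anchor is annotated with counts of overlapping genes, bucketed
by expression status crossed with the proximity class of the gene's nearest
open-chromatin peak:

=====  ==========================================================
ef/uf  expressed/unexpressed gene, nearest peak > 2 kb from gene
en3/un3  nearest peak < 2 kb downstream (3') of gene
en5/un5  nearest peak < 2 kb upstream (5') of gene
eo/uo  nearest peak overlapping the gene
mp     peaks overlapping the anchor
mpfe   anchor peaks whose nearest expressed gene is > 2 kb away
bare   no gene and no peak on the anchor
=====  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from .colocation import distinct_anchors
from .features import classify_gene_nearest_peak
from .intervals import (
    GenomicInterval,
    IntervalIndex,
    NoNeighborError,
    closest_feature,
)
from .records import ExpressionRecord, GeneRecord, LoopRecord, PeakRecord

GENE_CATEGORIES = ("ef", "uf", "en3", "un3", "en5", "un5", "eo", "uo")
ANNOTATION_COLUMNS = (*GENE_CATEGORIES, "mp", "mpfe")

_CATEGORY_BY_PROXIMITY = {
    "farther_2kb": ("ef", "uf"),
    "downstream_lt2kb": ("en3", "un3"),
    "upstream_lt2kb": ("en5", "un5"),
    "overlap": ("eo", "uo"),
}


@dataclass(frozen=True)
class AnchorAnnotation:
    """Category counts for one distinct anchor."""

    anchor: GenomicInterval
    loop_ids: Tuple[str, ...]
    counts: Mapping[str, int]

    @property
    def bare(self) -> bool:
        return all(self.counts[c] == 0 for c in ANNOTATION_COLUMNS)

    @property
    def n_expressed_genes(self) -> int:
        return sum(self.counts[c] for c in ("ef", "en3", "en5", "eo"))

    @property
    def n_genes(self) -> int:
        return sum(self.counts[c] for c in GENE_CATEGORIES)


@dataclass(frozen=True)
class LoopContentSummary:
    loops_both_anchors_expressed: int
    loops_both_anchors_expressed_and_peaked: int
    anchors_peak_no_gene: int
    anchors_peak_no_gene_opposite_gene_and_peak: int
    bare_bare_loop_count: int


def classify_genes(
    genes: Sequence[GeneRecord],
    expression: Mapping[str, ExpressionRecord],
    peaks: Sequence[PeakRecord],
    proximity_bp: int = 2000,
) -> Dict[str, str]:
    """Per-gene annotation category from expression x nearest-peak proximity.

    Genes without an expression record are unexpressed. The nearest peak is
    searched genome-wide (not restricted to any anchor).
    """
    peak_spans = [p.span for p in peaks]
    out = {}
    for g in genes:
        expressed = g.gene_id in expression and expression[g.gene_id].expressed
        prox = classify_gene_nearest_peak(g, peak_spans, proximity_bp)
        e_cat, u_cat = _CATEGORY_BY_PROXIMITY[prox.category]
        out[g.gene_id] = e_cat if expressed else u_cat
    return out


def annotate_anchors(
    loops: Sequence[LoopRecord],
    genes: Sequence[GeneRecord],
    expression: Mapping[str, ExpressionRecord] | Iterable[ExpressionRecord],
    peaks: Sequence[PeakRecord],
    proximity_bp: int = 2000,
    min_overlap_bp: int = 1,
) -> list[AnchorAnnotation]:
    """Annotate every distinct anchor of *loops*.

    Genes overlapping an anchor by >= 1 bp contribute to exactly one of the
    eight gene categories; a gene spanning two anchors contributes to each.
    Peaks overlapping the anchor count as ``mp``, and additionally as
    ``mpfe`` when the peak's nearest expressed gene is more than 2 kb away
    (or no expressed gene exists on the chromosome).
    """
    if not isinstance(expression, Mapping):
        expression = {r.gene_id: r for r in expression}
    gene_cat = classify_genes(genes, expression, peaks, proximity_bp)
    gene_idx = IntervalIndex((g.span, g) for g in genes)
    peak_idx = IntervalIndex((p.span, p) for p in peaks)
    expressed_spans = [
        g.span
        for g in genes
        if g.gene_id in expression and expression[g.gene_id].expressed
    ]

    def peak_is_distal_from_expressed(peak: PeakRecord) -> bool:
        try:
            _, dist = closest_feature(peak.span, expressed_spans)
        except NoNeighborError:
            return True
        return abs(dist.value) > proximity_bp

    annotations = []
    for anchor, loop_ids in distinct_anchors(loops).items():
        counts = {c: 0 for c in ANNOTATION_COLUMNS}
        seen_genes = set()
        for _iv, g in gene_idx.overlapping(anchor, min_overlap_bp):
            if g.gene_id in seen_genes:  # de-dup within a single anchor
                continue
            seen_genes.add(g.gene_id)
            counts[gene_cat[g.gene_id]] += 1
        for _iv, p in peak_idx.overlapping(anchor, min_overlap_bp):
            counts["mp"] += 1
            if peak_is_distal_from_expressed(p):
                counts["mpfe"] += 1
        annotations.append(AnchorAnnotation(anchor, tuple(loop_ids), counts))
    return annotations


def annotation_summary(annotations: Sequence[AnchorAnnotation]) -> dict:
    """Anchor-level headline counts used throughout the analysis."""
    n_expr = sum(1 for a in annotations if a.n_expressed_genes >= 1)
    return {
        "distinct_anchors": len(annotations),
        "bare_anchors": sum(1 for a in annotations if a.bare),
        "anchors_with_expressed_gene": n_expr,
        "anchors_with_one_expressed_gene": sum(
            1 for a in annotations if a.n_expressed_genes == 1
        ),
        "anchors_with_peak": sum(1 for a in annotations if a.counts["mp"] >= 1),
        "anchors_peak_no_expressed_gene": sum(
            1
            for a in annotations
            if a.counts["mp"] >= 1 and a.n_expressed_genes == 0
        ),
    }


def summarize_loop_content(
    loops: Sequence[LoopRecord], annotations: Sequence[AnchorAnnotation]
) -> LoopContentSummary:
    """Loop-level content counts from the per-anchor annotations.

    Raises if a loop's anchor is missing from the annotation set (annotation
    must run on the same loop set first).
    """
    by_anchor = {a.anchor: a for a in annotations}
    both_expr = 0
    both_expr_peak = 0
    bare_bare = 0
    peak_no_gene_anchor_hit: set = set()
    for lp in loops:
        try:
            a1, a2 = by_anchor[lp.anchor1], by_anchor[lp.anchor2]
        except KeyError as exc:
            raise ValueError(
                f"loop {lp.loop_id}: anchor {exc.args[0]} missing from annotations"
            ) from None
        if a1.n_expressed_genes >= 1 and a2.n_expressed_genes >= 1:
            both_expr += 1
            if a1.counts["mp"] >= 1 and a2.counts["mp"] >= 1:
                both_expr_peak += 1
        if a1.bare and a2.bare:
            bare_bare += 1
        for this, other in ((a1, a2), (a2, a1)):
            if (
                this.counts["mp"] >= 1
                and this.n_expressed_genes == 0
                and other.n_expressed_genes >= 1
                and other.counts["mp"] >= 1
            ):
                peak_no_gene_anchor_hit.add(this.anchor)
    anchors_peak_no_gene = sum(
        1 for a in annotations if a.counts["mp"] >= 1 and a.n_expressed_genes == 0
    )
    return LoopContentSummary(
        loops_both_anchors_expressed=both_expr,
        loops_both_anchors_expressed_and_peaked=both_expr_peak,
        anchors_peak_no_gene=anchors_peak_no_gene,
        anchors_peak_no_gene_opposite_gene_and_peak=len(peak_no_gene_anchor_hit),
        bare_bare_loop_count=bare_bare,
    )


def write_annotations(annotations: Sequence[AnchorAnnotation], path) -> None:
    """Write the anchor-annotation table (seqid, start, end, locus, bare, categories)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["seqid", "start", "end", "locus", "bare", *ANNOTATION_COLUMNS])
        for a in annotations:
            locus = ";".join(a.loop_ids)
            w.writerow(
                [
                    a.anchor.chrom,
                    a.anchor.start,
                    a.anchor.end,
                    locus,
                    int(a.bare),
                    *[a.counts[c] for c in ANNOTATION_COLUMNS],
                ]
            )
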