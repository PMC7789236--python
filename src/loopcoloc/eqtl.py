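"""eQTL lead-SNP / expression-trait co-location with loop anchors.

An eQTL links a lead SNP to an associated gene (the "expression trait",
located here by the gene's full span). Against a loop set, each eQTL is
classified, in priority order, as: same-anchor (SNP and gene share at least
one distinct anchor), cross-anchor (SNP in one anchor and gene in the other
anchor of a single loop), or other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

from .intervals import GenomicInterval, IntervalIndex
from .records import EqtlRecord, GeneRecord, LoopRecord
from .colocation import distinct_anchors

EQTL_CATEGORIES = ("same_anchor", "cross_anchor_same_loop", "other")


@dataclass(frozen=True)
class EqtlLoopClass:
    eqtl_id: str
    category: str
    anchor_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in EQTL_CATEGORIES:
            raise ValueError(f"unknown eQTL category {self.category!r}")
        if self.category == "same_anchor" and len(self.anchor_ids) != 1:
            raise ValueError("same_anchor must carry exactly one anchor id")
        if self.category == "cross_anchor_same_loop" and len(self.anchor_ids) != 2:
            raise ValueError("cross_anchor_same_loop must carry two anchor ids")


def _anchor_key(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def colocate_eqtls(
    eqtls: Sequence[EqtlRecord],
    loops: Sequence[LoopRecord],
    genes: Sequence[GeneRecord],
    trait_location: str = "span",
) -> Tuple[list[EqtlLoopClass], dict]:
    """Classify each eQTL against the loop anchors, in distinct-anchor space.

    The trait is located by the associated gene's full span (or its TSS with
    ``trait_location="tss"``). eQTLs whose gene id is unresolvable fall in
    ``other``. The summary reports category counts, the number of distinct
    anchors on which same-anchor co-location occurred, and the unique-SNP
    anchor overlap counts.
    """
    anchors = distinct_anchors(loops)
    idx = IntervalIndex((iv, _anchor_key(iv)) for iv in anchors)
    gene_by_id: Dict[str, GeneRecord] = {g.gene_id: g for g in genes}
    # anchors of each loop, keyed by loop id, for the cross-anchor test
    loop_anchors = {lp.loop_id: (lp.anchor1, lp.anchor2) for lp in loops}
    anchor_loops: Dict[str, list] = {}
    for lp in loops:
        anchor_loops.setdefault(_anchor_key(lp.anchor1), []).append((lp.loop_id, 1))
        anchor_loops.setdefault(_anchor_key(lp.anchor2), []).append((lp.loop_id, 2))

    classes = []
    n_unresolved = 0
    coloc_anchor_ids = set()
    for q in eqtls:
        gene = gene_by_id.get(q.gene_id)
        if gene is None:
            n_unresolved += 1
            classes.append(EqtlLoopClass(q.eqtl_id, "other"))
            continue
        if trait_location == "tss":
            tss = gene.span.start if gene.span.strand == "+" else gene.span.end - 1
            trait = GenomicInterval(gene.span.chrom, tss, tss + 1)
        else:
            trait = gene.span
        snp_anchors = {aid for _iv, aid in idx.overlapping(q.lead_snp)}
        trait_anchors = {aid for _iv, aid in idx.overlapping(trait)}
        shared = sorted(snp_anchors & trait_anchors)
        if shared:
            classes.append(EqtlLoopClass(q.eqtl_id, "same_anchor", (shared[0],)))
            coloc_anchor_ids.update(shared)
            continue
        cross = None
        for aid in sorted(snp_anchors):
            for loop_id, slot in anchor_loops.get(aid, ()):
                other = loop_anchors[loop_id][2 - slot]
                if _anchor_key(other) in trait_anchors:
                    cross = (aid, _anchor_key(other))
                    break
            if cross:
                break
        if cross:
            classes.append(EqtlLoopClass(q.eqtl_id, "cross_anchor_same_loop", cross))
            coloc_anchor_ids.update(cross)
        else:
            classes.append(EqtlLoopClass(q.eqtl_id, "other"))
    unique_snps, snps_on_anchors = unique_snp_anchor_overlap(eqtls, loops)
    counts = Counter(c.category for c in classes)
    summary = {
        "same_anchor": counts.get("same_anchor", 0),
        "cross_anchor": counts.get("cross_anchor_same_loop", 0),
        "other": counts.get("other", 0),
        "unresolved_genes": n_unresolved,
        "distinct_anchors": len(coloc_anchor_ids),
        "unique_snps": unique_snps,
        "snps_on_anchors": snps_on_anchors,
    }
    return classes, summary


def unique_snp_anchor_overlap(
    eqtls: Sequence[EqtlRecord], loops: Sequence[LoopRecord]
) -> Tuple[int, int]:
    """(number of unique SNP positions, number overlapping >=1 anchor).

    SNPs are deduplicated by exact (chrom, position); a SNP at an anchor's
    half-open end coordinate does not overlap it.
    """
    positions = {(q.lead_snp.chrom, q.lead_snp.start) for q in eqtls}
    idx = IntervalIndex(
        (iv, None) for iv in distinct_anchors(loops)
    )
    n_on = sum(
        1
        for chrom, pos in positions
        if idx.any_overlap(GenomicInterval(chrom, pos, pos + 1))
    )
    return len(positions), n_on
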