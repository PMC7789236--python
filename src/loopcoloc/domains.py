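"""Nested TAD-like domain hierarchy and loop-versus-domain classification.

Level-0 domains are roots; sub-domains (levels 1..6) nest inside them. Each
loop span is attributed to the deepest domain fully containing it and
classified as embedded, or as having one or two anchors co-located with that
domain's boundaries (a 2 kb window around each boundary by default). Loops
contained in no domain are split into inter-domain (anchors in two distinct
level-0 domains) and no-overlap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .intervals import GenomicInterval, IntervalIndex, overlap_length
from .records import DomainRecord, LoopRecord

LOOP_DOMAIN_CATEGORIES = (
    "embedded",
    "one_colocated_anchor",
    "two_colocated_anchors",
    "inter_domain",
    "no_overlap",
)
IN_DOMAIN_CATEGORIES = LOOP_DOMAIN_CATEGORIES[:3]


@dataclass(frozen=True)
class LoopDomainClass:
    """A loop's single domain category; level is set for in-domain categories."""

    loop_id: str
    category: str
    level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in LOOP_DOMAIN_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.level is not None) != (self.category in IN_DOMAIN_CATEGORIES):
            raise ValueError(
                f"level must be set exactly for in-domain categories "
                f"({self.loop_id}: {self.category}, level={self.level})"
            )


@dataclass
class DomainHierarchy:
    """Domains with containment links; orphan sub-domains are flagged, not dropped."""

    nodes: List[DomainRecord]
    children: Dict[int, List[int]] = field(default_factory=dict)  # node idx -> child idxs
    orphans: List[int] = field(default_factory=list)
    _index: IntervalIndex = field(default=None, repr=False)

    def containing(self, span: GenomicInterval) -> List[DomainRecord]:
        """All domains fully containing *span* (any level)."""
        return [
            d
            for _iv, d in self._index.overlapping(span)
            if d.span.contains(span)
        ]

    def level0_of(self, point_interval: GenomicInterval) -> Optional[DomainRecord]:
        """The level-0 domain containing the interval's midpoint, if any."""
        mid = point_interval.midpoint
        probe = GenomicInterval(point_interval.chrom, mid, mid + 1)
        hits = [
            d
            for _iv, d in self._index.overlapping(probe)
            if d.level == 0 and d.span.contains(probe)
        ]
        if not hits:
            return None
        # overlapping level-0 calls: take the first by coordinate
        return min(hits, key=lambda d: (d.span.start, d.span.end))


def build_hierarchy(domains: Sequence[DomainRecord]) -> DomainHierarchy:
    """Compute containment links between domains and flag orphan sub-domains.

    A node of level k > 0 is linked to every lower-level node whose span
    contains it; sub-domains with no containing lower-level node are flagged
    as orphans but kept.
    """
    nodes = sorted(domains, key=lambda d: (d.span.chrom, d.span.start, d.span.end, d.level))
    index = IntervalIndex((d.span, i) for i, d in enumerate(nodes))
    children: Dict[int, List[int]] = {}
    orphans: List[int] = []
    for i, d in enumerate(nodes):
        if d.level == 0:
            continue
        parents = [
            j
            for _iv, j in index.overlapping(d.span)
            if nodes[j].level < d.level and nodes[j].span.contains(d.span)
        ]
        if not parents:
            orphans.append(i)
            continue
        # prefer the immediate (deepest lower-level) parents
        best_level = max(nodes[j].level for j in parents)
        for j in parents:
            if nodes[j].level == best_level:
                children.setdefault(j, []).append(i)
    h = DomainHierarchy(nodes=nodes, children=children, orphans=orphans)
    h._index = IntervalIndex((d.span, d) for d in nodes)
    return h


def classify_loop_vs_domains(
    loop: LoopRecord,
    hierarchy: DomainHierarchy,
    flank_bp: int = 2000,
    boundary_rule: str = "flank_window",
) -> LoopDomainClass:
    """Classify one loop against the domain hierarchy.

    The loop is attributed to the deepest domain fully containing its span
    (ties broken by coordinate). Within that domain, an anchor is
    boundary-co-located when it intersects the window
    ``[boundary - flank_bp, boundary + flank_bp)`` around either domain edge
    (``boundary_rule="min_overlap_2kb"`` instead requires >= flank_bp of
    overlap with the window). Two co-located anchors beat one, which beats
    embedded. Loops contained in no domain are inter-domain when their anchor
    midpoints fall in two distinct level-0 domains, else no-overlap.
    """
    span = loop.span
    containing = hierarchy.containing(span)
    if containing:
        deepest_level = max(d.level for d in containing)
        domain = min(
            (d for d in containing if d.level == deepest_level),
            key=lambda d: (d.span.start, d.span.end),
        )
        n_coloc = 0
        for anchor in (loop.anchor1, loop.anchor2):
            hit = False
            for boundary in (domain.span.start, domain.span.end):
                window = GenomicInterval(
                    domain.span.chrom, max(0, boundary - flank_bp), boundary + flank_bp
                )
                ov = overlap_length(anchor, window)
                if boundary_rule == "flank_window":
                    hit = hit or ov >= 1
                elif boundary_rule == "min_overlap_2kb":
                    hit = hit or ov >= flank_bp
                else:
                    raise ValueError(f"unknown boundary_rule {boundary_rule!r}")
            if hit:
                n_coloc += 1
        category = IN_DOMAIN_CATEGORIES[n_coloc]
        return LoopDomainClass(loop.loop_id, category, deepest_level)
    d1 = hierarchy.level0_of(loop.anchor1)
    d2 = hierarchy.level0_of(loop.anchor2)
    if d1 is not None and d2 is not None and d1 != d2:
        return LoopDomainClass(loop.loop_id, "inter_domain")
    return LoopDomainClass(loop.loop_id, "no_overlap")


def classify_loops(
    loops: Sequence[LoopRecord],
    hierarchy: DomainHierarchy,
    flank_bp: int = 2000,
    boundary_rule: str = "flank_window",
) -> list[LoopDomainClass]:
    return [
        classify_loop_vs_domains(lp, hierarchy, flank_bp, boundary_rule)
        for lp in loops
    ]


def per_level_count_matrix(classes: Iterable[LoopDomainClass]) -> pd.DataFrame:
    """Per-level counts of embedded / one- / two-co-located-anchor loops.

    Rows are domain levels; columns the three in-domain categories — the
    shape of the replicate loop-vs-domain overlap tables.
    """
    counts: Counter = Counter()
    max_level = -1
    for c in classes:
        if c.level is not None:
            counts[(c.level, c.category)] += 1
            max_level = max(max_level, c.level)
    rows = []
    for level in range(max_level + 1):
        rows.append(
            {
                "level": level,
                **{cat: counts.get((level, cat), 0) for cat in IN_DOMAIN_CATEGORIES},
            }
        )
    return pd.DataFrame(rows, columns=["level", *IN_DOMAIN_CATEGORIES])


def domain_class_summary(classes: Sequence[LoopDomainClass]) -> dict:
    """Totals over the five categories plus derived shares.

    ``embedded_pct_of_total`` is the headline "fraction of all loops fully
    embedded in a domain"; ``embedded_pct_of_overlapping`` conditions on the
    loops that overlap a domain at all.
    """
    counts = Counter(c.category for c in classes)
    total = len(classes)
    overlapping = sum(counts.get(cat, 0) for cat in IN_DOMAIN_CATEGORIES)
    embedded = counts.get("embedded", 0)
    return {
        "total_loops": total,
        **{cat: counts.get(cat, 0) for cat in LOOP_DOMAIN_CATEGORIES},
        "overlapping_total": overlapping,
        "embedded_pct_of_total": 100.0 * embedded / total if total else float("nan"),
        "embedded_pct_of_overlapping": (
            100.0 * embedded / overlapping if overlapping else float("nan")
        ),
    }


def three_way_grouping(classes: Sequence[LoopDomainClass]) -> Dict[str, List[str]]:
    """Group loop ids into Inter / Intra / 1-2 overlap.

    Intra = fully embedded; 1-2 overlap = contained with one or both anchors
    on a boundary; Inter = anchors in distinct level-0 domains. No-overlap
    loops are excluded from the grouping.
    """
    groups: Dict[str, List[str]] = {"Inter": [], "Intra": [], "1-2 overlap": []}
    for c in classes:
        if c.category == "embedded":
            groups["Intra"].append(c.loop_id)
        elif c.category in ("one_colocated_anchor", "two_colocated_anchors"):
            groups["1-2 overlap"].append(c.loop_id)
        elif c.category == "inter_domain":
            groups["Inter"].append(c.loop_id)
    return groups
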