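"""Prioritized feature-to-loop assignment and loop-to-loop anchor co-location.

Because many loops share an anchor, a feature can touch an anchor of one loop
and the interior of another; assignments are therefore prioritized
anchor > interior > outside, so every feature lands in exactly one zone.
Loop pairs are compared anchor-wise (left anchor to left anchor, right to
right, after coordinate ordering) either at a >=1 bp criterion or at a
fractional-overlap threshold (e.g. at least 50% of the query anchor).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

from .intervals import GenomicInterval, IntervalIndex, overlap_length
from .records import LoopRecord

ZONES = ("anchor", "interior", "outside")
INTERACTION_CATEGORIES = (
    "anchor_to_anchor",
    "anchor_to_interior",
    "interior_to_interior",
    "unmapped",
)


@dataclass(frozen=True)
class LoopAssignment:
    """A feature's single highest-priority zone across all loops."""

    feature_id: str
    zone: str
    witness_loop: Optional[str] = None


@dataclass(frozen=True)
class SharedAnchorClass:
    """How many anchors of a loop are co-located with some partner loop (2/1/0)."""

    loop_id: str
    n_shared: int
    partner: Optional[str] = None


@dataclass(frozen=True)
class InteractionMapping:
    """Zone-pair category of a high-resolution interaction against Hi-C loops."""

    interaction_id: str
    category: str


def anchor_index(loops: Sequence[LoopRecord]) -> IntervalIndex:
    """Index of all anchors; payload = (loop_id, anchor slot 1|2)."""
    items = []
    for lp in loops:
        items.append((lp.anchor1, (lp.loop_id, 1)))
        items.append((lp.anchor2, (lp.loop_id, 2)))
    return IntervalIndex(items)


def interior_index(loops: Sequence[LoopRecord]) -> IntervalIndex:
    items = []
    for lp in loops:
        interior = lp.interior
        if interior is not None:
            items.append((interior, (lp.loop_id, 0)))
    return IntervalIndex(items)


def assign_features_to_loops(
    features: Dict[str, GenomicInterval],
    loops: Sequence[LoopRecord],
    min_overlap_bp: int = 1,
) -> Tuple[list[LoopAssignment], Counter]:
    """Assign each feature to its highest-priority zone across all loops.

    Priority: anchor > interior > outside. Returns the per-feature
    assignments (in feature order) and a Counter whose zone counts partition
    the feature set.
    """
    anchors = anchor_index(loops)
    interiors = interior_index(loops)
    assignments = []
    counts: Counter = Counter({z: 0 for z in ZONES})
    for fid, iv in features.items():
        hit = anchors.overlapping(iv, min_overlap_bp)
        if hit:
            zone, witness = "anchor", hit[0][1][0]
        else:
            hit = interiors.overlapping(iv, min_overlap_bp)
            if hit:
                zone, witness = "interior", hit[0][1][0]
            else:
                zone, witness = "outside", None
        assignments.append(LoopAssignment(fid, zone, witness))
        counts[zone] += 1
    return assignments, counts


def _anchor_match(
    a: GenomicInterval,
    b: GenomicInterval,
    min_overlap_bp: int,
    min_frac: Optional[float],
    frac_of: str,
) -> bool:
    ov = overlap_length(a, b)
    if min_frac is None:
        return ov >= min_overlap_bp
    if frac_of == "query":
        denom = a.length
    elif frac_of == "subject":
        denom = b.length
    elif frac_of == "either":
        denom = min(a.length, b.length)
    else:
        raise ValueError(f"frac_of must be query|subject|either, got {frac_of!r}")
    return ov >= min_frac * denom


def classify_shared_anchors(
    set_a: Sequence[LoopRecord],
    set_b: Sequence[LoopRecord],
    min_overlap_bp: int = 1,
    min_frac: Optional[float] = None,
    frac_of: str = "query",
    require_same_loop: bool = True,
) -> list[SharedAnchorClass]:
    """Per set_a loop: 2, 1 or 0 anchors co-located with set_b loops.

    Class 2 requires a single partner loop whose left/right anchors match the
    query's left/right anchors pairwise (``require_same_loop=False`` relaxes
    this to independent matches). Class 1 means any single anchor matches any
    set_b anchor. Each loop is counted once, prioritized 2 > 1 > 0.
    """
    idx = anchor_index(set_b)
    by_id = {lp.loop_id: lp for lp in set_b}
    out = []
    for lp in set_a:
        hits1 = idx.overlapping(lp.anchor1, 1)
        hits2 = idx.overlapping(lp.anchor2, 1)
        m1 = {}
        for iv, (bid, slot) in hits1:
            if slot == 1 and _anchor_match(lp.anchor1, iv, min_overlap_bp, min_frac, frac_of):
                m1[bid] = True
        m2 = {}
        for iv, (bid, slot) in hits2:
            if slot == 2 and _anchor_match(lp.anchor2, iv, min_overlap_bp, min_frac, frac_of):
                m2[bid] = True
        partner = None
        if require_same_loop:
            both = sorted(set(m1) & set(m2))
            if both:
                partner = both[0]
        elif m1 and m2:
            partner = sorted(m1)[0]
        if partner is not None:
            out.append(SharedAnchorClass(lp.loop_id, 2, partner))
            continue
        any1 = any(
            _anchor_match(lp.anchor1, iv, min_overlap_bp, min_frac, frac_of)
            for iv, _ in hits1
        )
        any2 = any(
            _anchor_match(lp.anchor2, iv, min_overlap_bp, min_frac, frac_of)
            for iv, _ in hits2
        )
        if any1 or any2:
            out.append(SharedAnchorClass(lp.loop_id, 1, None))
        else:
            out.append(SharedAnchorClass(lp.loop_id, 0, None))
    return out


def pair_loops_by_anchor_overlap(
    set_a: Sequence[LoopRecord],
    set_b: Sequence[LoopRecord],
    min_overlap_bp: int = 1,
) -> Tuple[list[SharedAnchorClass], Counter]:
    """Replicate-style loop sharing at the >=1 bp anchor-overlap criterion.

    Counted in set_a's frame: each set_a loop contributes once to the class
    totals even with multiple partners.
    """
    classes = classify_shared_anchors(set_a, set_b, min_overlap_bp=min_overlap_bp)
    return classes, Counter(c.n_shared for c in classes)


def colocate_highres_loops(
    highres: Sequence[LoopRecord],
    hic: Sequence[LoopRecord],
    min_frac: float = 0.5,
    frac_of: str = "query",
    require_same_loop: bool = True,
) -> Counter:
    """Count high-resolution loops with 2, 1 or 0 anchors co-located with Hi-C
    loops at a fractional-overlap criterion (default: >=50% of the
    high-resolution anchor)."""
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    classes = classify_shared_anchors(
        highres,
        hic,
        min_frac=min_frac,
        frac_of=frac_of,
        require_same_loop=require_same_loop,
    )
    counts = Counter(c.n_shared for c in classes)
    return Counter({k: counts.get(k, 0) for k in (2, 1, 0)})


def map_interactions_to_zones(
    highres: Sequence[LoopRecord],
    hic: Sequence[LoopRecord],
    min_frac: Optional[float] = 0.5,
    frac_of: str = "query",
    min_overlap_bp: int = 1,
) -> Tuple[list[InteractionMapping], Counter]:
    """Categorize each high-resolution interaction by the Hi-C zones its two
    anchors fall in: anchor-to-anchor, anchor-to-interior,
    interior-to-interior, or unmapped.

    Each anchor's zone is anchor > interior > outside (same prioritization as
    feature assignment); an interaction with an outside anchor is unmapped.
    ``min_frac=None`` switches the anchor-zone criterion to plain >=1 bp.
    """
    anchors = anchor_index(hic)
    interiors = interior_index(hic)

    def anchor_zone(iv: GenomicInterval) -> str:
        for cand, _payload in anchors.overlapping(iv, min_overlap_bp):
            if _anchor_match(iv, cand, min_overlap_bp, min_frac, frac_of):
                return "anchor"
        for cand, _payload in interiors.overlapping(iv, min_overlap_bp):
            if _anchor_match(iv, cand, min_overlap_bp, min_frac, frac_of):
                return "interior"
        return "outside"

    mappings = []
    for lp in highres:
        z1, z2 = anchor_zone(lp.anchor1), anchor_zone(lp.anchor2)
        zones = {z1, z2}
        if zones == {"anchor"}:
            cat = "anchor_to_anchor"
        elif zones == {"anchor", "interior"}:
            cat = "anchor_to_interior"
        elif zones == {"interior"}:
            cat = "interior_to_interior"
        else:
            cat = "unmapped"
        mappings.append(InteractionMapping(lp.loop_id, cat))
    counts = Counter(m.category for m in mappings)
    return mappings, Counter({k: counts.get(k, 0) for k in INTERACTION_CATEGORIES})


def distinct_anchors(
    loops: Sequence[LoopRecord],
) -> Dict[GenomicInterval, list[str]]:
    """Deduplicate anchors by exact (chrom, start, end); value = loop ids sharing it.

    Multiplicity (how many loop-anchor slots map to the interval) is
    ``len(value)``; an anchor used twice by one loop appears twice.
    """
    out: Dict[GenomicInterval, list[str]] = {}
    for lp in loops:
        out.setdefault(lp.anchor1, []).append(lp.loop_id)
        out.setdefault(lp.anchor2, []).append(lp.loop_id)
    return dict(
        sorted(out.items(), key=lambda kv: (kv[0].chrom, kv[0].start, kv[0].end))
    )
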