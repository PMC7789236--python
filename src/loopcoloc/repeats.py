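"""Per-loop repeat coverage of anchor versus interior regions.

Each loop is treated as the union of its two anchors plus an interior; for
each part, the fraction of positions covered by at least one repeat element
is computed with union (bedtools-coverage) semantics. The anchor/interior
contrast quantifies the enrichment of repeats inside loops relative to the
anchors flanking them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval, IntervalIndex, covered_positions
from .records import LoopRecord, RepeatRecord


@dataclass(frozen=True)
class LoopRepeatDensity:
    """Repeat-covered fraction of a loop's anchor union and interior.

    ``interior_fraction`` is None when the anchors touch or overlap (no
    interior).
    """

    loop_id: str
    anchor_fraction: float
    interior_fraction: Optional[float]


def loop_repeat_density(
    loop: LoopRecord, repeats: Sequence[RepeatRecord] | IntervalIndex
) -> LoopRepeatDensity:
    """Coverage fractions for one loop; repeats are clipped to each region and
    counted with union semantics (strand ignored)."""
    if isinstance(repeats, IntervalIndex):
        idx = repeats
    else:
        idx = IntervalIndex((r.span, None) for r in repeats)

    def frac(region: GenomicInterval) -> float:
        spans = [iv for iv, _ in idx.overlapping(region)]
        return covered_positions(region, spans) / region.length

    anchor_len = loop.anchor1.length + loop.anchor2.length
    covered = sum(
        covered_positions(a, [iv for iv, _ in idx.overlapping(a)])
        for a in (loop.anchor1, loop.anchor2)
    )
    # anchors of one loop never overlap each other after normalization when an
    # interior exists; if they do overlap, count the union once
    if loop.anchor1.end > loop.anchor2.start:
        union = GenomicInterval(
            loop.chrom, loop.anchor1.start, max(loop.anchor1.end, loop.anchor2.end)
        )
        covered = covered_positions(union, [iv for iv, _ in idx.overlapping(union)])
        anchor_len = union.length
    anchor_fraction = covered / anchor_len
    interior = loop.interior
    interior_fraction = frac(interior) if interior is not None else None
    return LoopRepeatDensity(loop.loop_id, anchor_fraction, interior_fraction)


def compute_densities(
    loops: Sequence[LoopRecord], repeats: Sequence[RepeatRecord]
) -> list[LoopRepeatDensity]:
    idx = IntervalIndex((r.span, None) for r in repeats)
    return [loop_repeat_density(lp, idx) for lp in loops]


def density_summary(densities: Iterable[LoopRepeatDensity]) -> dict:
    """Mean anchor/interior fractions and the share of loops where the
    interior is denser than the anchors.

    Loops without an interior are excluded from the interior statistics and
    counted separately.
    """
    densities = list(densities)
    if not densities:
        raise ValueError("density_summary requires at least one loop")
    with_interior = [d for d in densities if d.interior_fraction is not None]
    if not with_interior:
        raise ValueError("density_summary requires at least one loop with an interior")
    n = len(with_interior)
    return {
        "n_loops": len(densities),
        "n_with_interior": n,
        "n_without_interior": len(densities) - n,
        "mean_anchor_fraction": sum(d.anchor_fraction for d in with_interior) / n,
        "mean_interior_fraction": sum(d.interior_fraction for d in with_interior) / n,
        "fraction_interior_gt_anchor": (
            sum(1 for d in with_interior if d.interior_fraction > d.anchor_fraction) / n
        ),
    }
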