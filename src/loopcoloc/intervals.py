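"""Genomic interval primitives with bedtools-compatible semantics.

Every coordinate in this package is 0-based, half-open ``[start, end)`` on a
named chromosome. The three operations here — overlap length, union-coverage
fraction, and signed nearest-feature search — reproduce the behaviour of
``bedtools intersect``, ``bedtools coverage`` and ``bedtools closest`` on
in-memory records, and every downstream classification is built on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``Chr``/``chr`` prefix so labels match across files."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span ``[start, end)`` on a chromosome; the universal coordinate currency.

    Parameters
    ----------
    chrom : str
        Chromosome label, e.g. ``"1"``..``"10"`` or ``"0"`` for the AGPv4
        unplaced pseudo-chromosome (``Chr0``).
    start, end : int
        0-based half-open bounds; ``end > start >= 0``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True, order=True)
class StrandedInterval(GenomicInterval):
    """A :class:`GenomicInterval` carrying a strand, used for gene models."""

    strand: str = "+"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SignedDistance:
    """Signed gap between two intervals, in the bedtools-closest convention.

    ``value`` is 0 on any overlap; negative when the reported feature lies
    left of the query; positive when it lies right of it. ``side`` names the
    same fact symbolically.
    """

    value: int
    side: str  # {"overlap", "left", "right"}

    def __post_init__(self) -> None:
        expected = "overlap" if self.value == 0 else ("left" if self.value < 0 else "right")
        if self.side != expected:
            raise ValueError(
                f"side {self.side!r} inconsistent with value {self.value}"
            )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared base positions between two intervals (0 if none)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Iterable[Tuple[int, int]]
) -> list[Tuple[int, int]]:
    """Merge possibly-overlapping ``(start, end)`` pairs into a disjoint union."""
    merged: list[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def covered_positions(
    target: GenomicInterval, features: Iterable[GenomicInterval]
) -> int:
    """Count positions of *target* covered by at least one feature.

    Union semantics: a position under several overlapping features counts
    once, matching how ``bedtools coverage`` counts covered bases.
    """
    clipped = []
    for f in features:
        if f.chrom != target.chrom:
            continue
        s, e = max(f.start, target.start), min(f.end, target.end)
        if e > s:
            clipped.append((s, e))
    return sum(e - s for s, e in merge_intervals(clipped))


def coverage_fraction(
    target: GenomicInterval, features: Iterable[GenomicInterval]
) -> float:
    """Fraction of *target* positions covered by >=1 feature, in [0, 1]."""
    return covered_positions(target, features) / target.length


class NoNeighborError(LookupError):
    """Raised when a closest-feature query has no candidate on its chromosome."""


def signed_distance(query: GenomicInterval, feature: GenomicInterval) -> SignedDistance:
    """Distance from *query* to *feature*: 0 on overlap, else the signed gap.

    The magnitude is the smallest absolute difference between the half-open
    endpoints of the two intervals (i.e. the size of the gap between them),
    negative when the feature lies left of the query. Bookended intervals
    (gap 0 but no shared position) are reported at distance +-1, so distance
    0 always means a true overlap.
    """
    if overlap_length(query, feature) > 0:
        return SignedDistance(0, "overlap")
    if feature.end <= query.start:
        gap = query.start - feature.end
        return SignedDistance(-max(gap, 1), "left")
    gap = feature.start - query.end
    return SignedDistance(max(gap, 1), "right")


def closest_feature(
    query: GenomicInterval,
    candidates: Sequence[GenomicInterval],
    key=None,
) -> Tuple[GenomicInterval, SignedDistance]:
    """Nearest candidate to *query* on its chromosome, bedtools-closest style.

    Overlapping candidates are reported at distance 0. Ties on |distance| are
    broken by leftmost candidate start, then by ``key(candidate)`` (an
    identifier) lexicographically, so output is deterministic.

    Raises
    ------
    NoNeighborError
        If no candidate shares the query's chromosome.
    """
    best: Optional[Tuple[int, int, str]] = None
    best_pair: Optional[Tuple[GenomicInterval, SignedDistance]] = None
    for cand in candidates:
        if cand.chrom != query.chrom:
            continue
        d = signed_distance(query, cand)
        ident = str(key(cand)) if key is not None else ""
        rank = (abs(d.value), cand.start, ident)
        if best is None or rank < best:
            best = rank
            best_pair = (cand, d)
    if best_pair is None:
        raise NoNeighborError(
            f"no candidate on chromosome {query.chrom!r} for {query}"
        )
    return best_pair


class IntervalIndex:
    """Per-chromosome interval tree supporting overlap queries with a
    minimum-overlap threshold.

    Backed by :mod:`intervaltree`; results are sorted by (start, end) so
    iteration order is deterministic.
    """

    def __init__(self, items: Iterable[Tuple[GenomicInterval, object]] = ()):
        from intervaltree import IntervalTree

        self._trees: dict[str, IntervalTree] = {}
        for iv, payload in items:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (iv, payload)
            )

    def overlapping(
        self, query: GenomicInterval, min_overlap_bp: int = 1
    ) -> list[Tuple[GenomicInterval, object]]:
        """All indexed intervals overlapping *query* by >= ``min_overlap_bp``."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = []
        for node in tree.overlap(query.start, query.end):
            if min(node.end, query.end) - max(node.begin, query.start) >= min_overlap_bp:
                hits.append(node.data)
        hits.sort(key=lambda pair: (pair[0].start, pair[0].end, str(pair[1])))
        return hits

    def any_overlap(self, query: GenomicInterval, min_overlap_bp: int = 1) -> bool:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return False
        for node in tree.overlap(query.start, query.end):
            if min(node.end, query.end) - max(node.begin, query.start) >= min_overlap_bp:
                return True
        return False
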