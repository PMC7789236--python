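"""Interval primitives against brute-force position marking and bedtools."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopcoloc.intervals import (
    GenomicInterval,
    IntervalIndex,
    NoNeighborError,
    SignedDistance,
    StrandedInterval,
    closest_feature,
    coverage_fraction,
    overlap_length,
    signed_distance,
)


def iv(start, end, chrom="1"):
    return GenomicInterval(chrom, start, end)


def brute_coverage(target, features):
    """Mark every position of the target; the independent oracle."""
    marked = np.zeros(target.length, dtype=bool)
    for f in features:
        if f.chrom != target.chrom:
            continue
        s = max(f.start, target.start) - target.start
        e = min(f.end, target.end) - target.start
        if e > s:
            marked[s:e] = True
    return marked.sum() / target.length


class TestValidation:
    def test_rejects_empty_and_negative_intervals(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("1", -1, 5)
        with pytest.raises(ValueError):
            StrandedInterval("1", 0, 5, "*")

    def test_signed_distance_consistency_enforced(self):
        with pytest.raises(ValueError):
            SignedDistance(5, "left")
        with pytest.raises(ValueError):
            SignedDistance(0, "right")


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (iv(0, 10), iv(10, 20), 0),  # half-open adjacency
            (iv(0, 10), iv(0, 10), 10),  # identity
            (iv(5, 25), iv(20, 40), 5),
            (iv(0, 10), iv(0, 10, chrom="2"), 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_length(a, b) == expected

    @given(
        st.integers(0, 500), st.integers(1, 200),
        st.integers(0, 500), st.integers(1, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_self(self, s1, l1, s2, l2):
        a, b = iv(s1, s1 + l1), iv(s2, s2 + l2)
        assert overlap_length(a, b) == overlap_length(b, a)
        assert overlap_length(a, a) == a.length
        # brute-force position count
        shared = len(set(range(s1, s1 + l1)) & set(range(s2, s2 + l2)))
        assert overlap_length(a, b) == shared


class TestCoverageFraction:
    def test_empty_feature_set(self):
        assert coverage_fraction(iv(0, 100), []) == 0.0

    def test_full_cover_is_clipped(self):
        assert coverage_fraction(iv(0, 100), [iv(0, 200)]) == 1.0

    def test_union_not_sum(self):
        assert coverage_fraction(iv(0, 100), [iv(10, 20), iv(15, 30)]) == 0.20

    def test_randomized_against_position_marking(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            ts = int(rng.integers(0, 5000))
            t = iv(ts, ts + int(rng.integers(1, 2000)))
            feats = []
            for _k in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, 7000))
                feats.append(iv(s, s + int(rng.integers(1, 900))))
            assert coverage_fraction(t, feats) == pytest.approx(brute_coverage(t, feats))

    def test_monotone_under_feature_growth(self):
        rng = np.random.default_rng(7)
        t = iv(0, 3000)
        feats = []
        prev = 0.0
        for _ in range(50):
            s = int(rng.integers(0, 3500))
            feats.append(iv(s, s + int(rng.integers(1, 400))))
            cur = coverage_fraction(t, feats)
            assert cur >= prev - 1e-12
            prev = cur


class TestClosestFeature:
    def test_overlap_reports_zero(self):
        f, d = closest_feature(iv(1000, 2000), [iv(1500, 1600)])
        assert d.value == 0 and d.side == "overlap"

    def test_right_neighbor_signed(self):
        _f, d = closest_feature(iv(1000, 2000), [iv(2500, 2600)])
        assert (d.value, d.side) == (500, "right")

    def test_nearer_right_beats_farther_left(self):
        f, d = closest_feature(iv(1000, 2000), [iv(200, 300), iv(2500, 2600)])
        assert f == iv(2500, 2600) and d.value == 500
        # removing the right candidate exposes the left one
        _f, d = closest_feature(iv(1000, 2000), [iv(200, 300)])
        assert (d.value, d.side) == (-700, "left")

    def test_no_candidate_on_chromosome(self):
        with pytest.raises(NoNeighborError):
            closest_feature(iv(0, 10), [iv(0, 10, chrom="2")])

    def test_bookended_is_distance_one_not_overlap(self):
        _f, d = closest_feature(iv(0, 10), [iv(10, 20)])
        assert (d.value, d.side) == (1, "right")

    def test_randomized_against_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            qs = int(rng.integers(0, 5000))
            q = iv(qs, qs + int(rng.integers(1, 500)))
            cands = []
            for _k in range(int(rng.integers(1, 10))):
                s = int(rng.integers(0, 8000))
                cands.append(iv(s, s + int(rng.integers(1, 600))))
            best, d = closest_feature(q, cands)
            dists = [abs(signed_distance(q, c).value) for c in cands]
            assert abs(d.value) == min(dists)
            assert best in cands

    def test_deterministic_tie_break_leftmost(self):
        q = iv(1000, 2000)
        best, _d = closest_feature(q, [iv(2100, 2200), iv(800, 900)])
        assert best == iv(800, 900)  # equal |distance| 100; leftmost start wins


class TestIntervalIndex:
    def test_matches_linear_scan(self):
        rng = np.random.default_rng(11)
        items = []
        for k in range(300):
            s = int(rng.integers(0, 50_000))
            items.append((iv(s, s + int(rng.integers(1, 3000))), k))
        index = IntervalIndex(items)
        for _ in range(200):
            s = int(rng.integers(0, 52_000))
            q = iv(s, s + int(rng.integers(1, 2500)))
            got = {p for _iv, p in index.overlapping(q)}
            want = {p for v, p in items if overlap_length(v, q) >= 1}
            assert got == want
            assert index.any_overlap(q) == bool(want)


@pytest.mark.parametrize("trial_seed", [0, 1])
def test_bedtools_agrees_on_coverage_and_closest(tmp_path, trial_seed):
    """Independent oracle: bedtools coverage/closest on random fixtures.

    bedtools reports non-overlap distances as gap+1 (1-based inclusive
    endpoints); ours is the half-open gap, so |ours| <= bedtools <= |ours|+1.
    """
    rng = np.random.default_rng(trial_seed)
    target = iv(1000, 9000)
    feats = sorted(
        (int(s), int(s) + int(rng.integers(50, 900)))
        for s in rng.integers(0, 11_000, size=12)
    )
    a = tmp_path / "a.bed"
    b = tmp_path / "b.bed"
    a.write_text(f"1\t{target.start}\t{target.end}\n")
    b.write_text("".join(f"1\t{s}\t{e}\n" for s, e in feats))
    cov = subprocess.run(
        ["bedtools", "coverage", "-a", str(a), "-b", str(b)],
        capture_output=True, text=True, check=True,
    ).stdout.split("\t")
    ours = coverage_fraction(target, [iv(s, e) for s, e in feats])
    assert ours == pytest.approx(float(cov[-1]), abs=1e-6)

    query = iv(4200, 4300)
    a.write_text(f"1\t{query.start}\t{query.end}\n")
    out = subprocess.run(
        ["bedtools", "closest", "-a", str(a), "-b", str(b), "-d", "-t", "first"],
        capture_output=True, text=True, check=True,
    ).stdout.split("\t")
    bed_d = int(out[-1])
    _f, d = closest_feature(query, [iv(s, e) for s, e in feats])
    assert abs(d.value) <= bed_d <= abs(d.value) + 1
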