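"""Prioritized zone assignment and loop-loop anchor co-location."""

from collections import Counter

import numpy as np
import pytest

from loopcoloc.colocation import (
    assign_features_to_loops,
    colocate_highres_loops,
    distinct_anchors,
    map_interactions_to_zones,
    pair_loops_by_anchor_overlap,
)
from loopcoloc.intervals import GenomicInterval, overlap_length
from loopcoloc.records import LoopRecord


def loop(chrom, x1, x2, y1, y2, lid):
    return LoopRecord.make(chrom, x1, x2, y1, y2, lid)


TOY_LOOPS = [
    loop("1", 1000, 2000, 9000, 10_000, "A"),  # interior [2000, 9000)
    loop("1", 9500, 10_500, 20_000, 21_000, "B"),  # shares span with A's anchor2
]


class TestAssignFeatures:
    def test_anchor_priority_beats_interior(self):
        # feature on A's interior AND B's anchor1 -> anchor wins
        feats = {"f": GenomicInterval("1", 9_600, 9_700)}
        # also overlaps A's anchor2 region? [9000,10000) yes; use one clearly in both
        assignments, counts = assign_features_to_loops(feats, TOY_LOOPS)
        assert assignments[0].zone == "anchor"
        assert counts["anchor"] == 1

    def test_interior_only_feature(self):
        feats = {"f": GenomicInterval("1", 5_000, 5_100)}
        assignments, _ = assign_features_to_loops(feats, TOY_LOOPS)
        assert assignments[0].zone == "interior" and assignments[0].witness_loop == "A"

    def test_outside_feature(self):
        feats = {"f": GenomicInterval("1", 50_000, 50_100)}
        assignments, _ = assign_features_to_loops(feats, TOY_LOOPS)
        assert assignments[0].zone == "outside" and assignments[0].witness_loop is None

    def test_counts_partition_feature_set(self, bundle):
        feats = {g.gene_id: g.span for g in bundle.genes}
        _a, counts = assign_features_to_loops(feats, bundle.loops)
        assert sum(counts.values()) == len(feats)

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        loops = []
        for i in range(40):
            x1 = int(rng.integers(0, 400_000))
            a1 = int(rng.integers(500, 5_000))
            gap = int(rng.integers(1_000, 50_000))
            a2 = int(rng.integers(500, 5_000))
            loops.append(loop("1", x1, x1 + a1, x1 + a1 + gap, x1 + a1 + gap + a2, f"L{i}"))
        feats = {}
        for i in range(300):
            s = int(rng.integers(0, 500_000))
            feats[f"f{i}"] = GenomicInterval("1", s, s + int(rng.integers(1, 2_000)))
        assignments, _ = assign_features_to_loops(feats, loops)
        by_id = {a.feature_id: a.zone for a in assignments}
        for fid, iv in feats.items():
            on_anchor = any(
                overlap_length(iv, a) >= 1
                for lp in loops
                for a in (lp.anchor1, lp.anchor2)
            )
            on_interior = any(
                lp.interior is not None and overlap_length(iv, lp.interior) >= 1
                for lp in loops
            )
            expected = "anchor" if on_anchor else ("interior" if on_interior else "outside")
            assert by_id[fid] == expected

    def test_zone_recovery_exact_on_generator_truth(self, bundle, bundle_outputs):
        assert bundle_outputs["gene_zones"] == bundle.truth.gene_zone
        assert bundle_outputs["peak_zones"] == bundle.truth.peak_zone


class TestPairLoops:
    def test_set_against_itself_all_share_two(self, bundle):
        classes, counts = pair_loops_by_anchor_overlap(bundle.loops, bundle.loops)
        assert counts[2] == len(bundle.loops)
        assert all(c.partner is not None for c in classes)

    def test_class_totals_partition_set(self, bundle):
        _c, counts = pair_loops_by_anchor_overlap(bundle.loops_rep2, bundle.loops)
        assert sum(counts.values()) == len(bundle.loops_rep2)

    def test_one_shared_anchor(self):
        a = [loop("1", 1000, 2000, 9000, 10_000, "A")]
        b = [loop("1", 1500, 2500, 50_000, 51_000, "B")]
        _c, counts = pair_loops_by_anchor_overlap(a, b)
        assert counts[1] == 1

    def test_slotwise_matching_no_cross(self):
        # a's anchor1 overlaps b's anchor2 only: that is a 1, not a 2
        a = [loop("1", 9000, 10_000, 20_000, 21_000, "A")]
        b = [loop("1", 1000, 2000, 9_000, 10_000, "B")]
        classes, counts = pair_loops_by_anchor_overlap(a, b)
        assert counts[1] == 1 and classes[0].partner is None

    def test_generator_truth_recovered(self, bundle, bundle_outputs):
        got = {c.loop_id: c.n_shared for c in bundle_outputs["rep2_shared"]}
        assert got == bundle.truth.rep2_shared


class TestHighresColocation:
    def test_identical_loop_is_class_two(self):
        hic = [loop("1", 1000, 2000, 9000, 10_000, "A")]
        counts = colocate_highres_loops(hic, hic, 0.5)
        assert counts[2] == 1

    def test_forty_percent_overlap_fails_half_criterion(self):
        hic = [loop("1", 1000, 2000, 9000, 10_000, "A")]
        # high-res anchors 1000 bp long; first overlaps a Hi-C anchor by 400 bp
        hr = [loop("1", 400, 1400, 9100, 10_100, "H")]
        assert colocate_highres_loops(hr, hic, 0.5)[2] == 0
        assert colocate_highres_loops(hr, hic, 0.4)[2] == 1

    def test_monotone_in_min_frac(self, bundle):
        prev = None
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            n2 = colocate_highres_loops(bundle.highres, bundle.loops, frac)[2]
            if prev is not None:
                assert n2 <= prev
            prev = n2

    def test_invalid_min_frac(self):
        with pytest.raises(ValueError):
            colocate_highres_loops([], [], 0.0)

    def test_generator_truth_recovered(self, bundle, bundle_outputs):
        counts = bundle_outputs["highres_counts"]
        truth_counts = Counter(bundle.truth.highres_shared.values())
        assert {k: counts.get(k, 0) for k in (2, 1, 0)} == {
            k: truth_counts.get(k, 0) for k in (2, 1, 0)
        }


class TestInteractionZones:
    def test_category_priority_and_partition(self):
        hic = [loop("1", 1000, 2000, 90_000, 91_000, "A")]
        hr = [
            loop("1", 1200, 1400, 90_200, 90_400, "a2a"),
            loop("1", 1200, 1400, 50_000, 50_200, "a2i"),
            loop("1", 30_000, 30_200, 50_000, 50_200, "i2i"),
            loop("1", 200_000, 200_200, 300_000, 300_200, "none"),
        ]
        mappings, counts = map_interactions_to_zones(hr, hic, min_frac=0.5)
        got = {m.interaction_id: m.category for m in mappings}
        assert got == {
            "a2a": "anchor_to_anchor",
            "a2i": "anchor_to_interior",
            "i2i": "interior_to_interior",
            "none": "unmapped",
        }
        assert sum(counts.values()) == len(hr)

    def test_generator_zone_pairs_recovered(self, bundle):
        mappings, _ = map_interactions_to_zones(bundle.highres, bundle.loops, min_frac=0.5)
        got = {m.interaction_id: m.category for m in mappings}
        assert got == bundle.truth.highres_zone_pair


class TestDistinctAnchors:
    def test_exact_coordinate_dedup(self):
        loops = [
            loop("1", 1000, 2000, 9000, 10_000, "A"),
            loop("1", 1000, 2000, 50_000, 51_000, "B"),  # shares anchor1 exactly
            loop("1", 1001, 2000, 70_000, 71_000, "C"),  # off by 1 bp: distinct
        ]
        anchors = distinct_anchors(loops)
        assert len(anchors) == 5
        assert anchors[GenomicInterval("1", 1000, 2000)] == ["A", "B"]

    def test_multiplicity_totals(self, bundle):
        anchors = distinct_anchors(bundle.highres)
        assert sum(len(v) for v in anchors.values()) == 2 * len(bundle.highres)
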