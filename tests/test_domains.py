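"""Domain hierarchy construction and loop-vs-domain classification."""

from collections import Counter

import pytest

from loopcoloc.domains import (
    LoopDomainClass,
    build_hierarchy,
    classify_loop_vs_domains,
    classify_loops,
    domain_class_summary,
    per_level_count_matrix,
    three_way_grouping,
)
from loopcoloc.intervals import GenomicInterval
from loopcoloc.records import DomainRecord, LoopRecord


def dom(chrom, s, e, level):
    return DomainRecord(GenomicInterval(chrom, s, e), level)


def loop(chrom, x1, x2, y1, y2, lid="L"):
    return LoopRecord.make(chrom, x1, x2, y1, y2, lid)


class TestBuildHierarchy:
    def test_single_parent_child_link(self):
        h = build_hierarchy([dom("1", 0, 1_000_000, 0), dom("1", 100_000, 400_000, 1)])
        assert len(h.nodes) == 2
        (children,) = h.children.values()
        assert [h.nodes[c].level for c in children] == [1]
        assert h.orphans == []

    def test_orphan_subdomain_flagged_not_dropped(self):
        h = build_hierarchy([dom("1", 0, 100_000, 0), dom("1", 500_000, 600_000, 1)])
        assert len(h.nodes) == 2
        assert len(h.orphans) == 1
        assert h.nodes[h.orphans[0]].level == 1

    def test_containment_query(self):
        h = build_hierarchy([dom("1", 0, 1_000_000, 0), dom("1", 100_000, 400_000, 1)])
        inner = GenomicInterval("1", 150_000, 300_000)
        assert sorted(d.level for d in h.containing(inner)) == [0, 1]


HIER = build_hierarchy(
    [
        dom("1", 0, 1_000_000, 0),
        dom("1", 50_000, 450_000, 1),
        dom("1", 550_000, 950_000, 1),
        dom("1", 1_100_000, 2_000_000, 0),
    ]
)


class TestClassifyLoop:
    def test_embedded_away_from_boundaries(self):
        lp = loop("1", 10_000, 20_000, 80_000, 90_000)
        got = classify_loop_vs_domains(lp, build_hierarchy([dom("1", 0, 100_000, 0)]))
        assert (got.category, got.level) == ("embedded", 0)

    def test_anchor_in_boundary_window_is_one_colocated(self):
        # domain [15k, 150k): window around 15k is [13k, 17k); anchor [15k*, ...]
        h = build_hierarchy([dom("1", 15_000, 150_000, 0)])
        lp = loop("1", 16_000, 26_000, 80_000, 90_000)
        got = classify_loop_vs_domains(lp, h)
        assert (got.category, got.level) == ("one_colocated_anchor", 0)

    def test_both_anchors_on_boundaries(self):
        h = build_hierarchy([dom("1", 15_000, 150_000, 0)])
        lp = loop("1", 15_500, 25_000, 140_000, 149_500)
        got = classify_loop_vs_domains(lp, h)
        assert got.category == "two_colocated_anchors"

    def test_deepest_containment_attribution(self):
        # fits in the level-1 sub-domain -> counted at level 1, not 0
        lp = loop("1", 60_000, 70_000, 400_000, 410_000)
        got = classify_loop_vs_domains(lp, HIER)
        assert (got.category, got.level) == ("embedded", 1)
        # brute force: deepest domain containing the span
        containing = [d for d in HIER.nodes if d.span.contains(lp.span)]
        assert got.level == max(d.level for d in containing)

    def test_anchors_in_distinct_level0_domains_is_inter(self):
        lp = loop("1", 500_000, 510_000, 1_200_000, 1_210_000)
        assert classify_loop_vs_domains(lp, HIER).category == "inter_domain"

    def test_span_hitting_no_domain_is_no_overlap(self):
        lp = loop("1", 3_000_000, 3_010_000, 3_100_000, 3_110_000)
        assert classify_loop_vs_domains(lp, HIER).category == "no_overlap"

    def test_min_overlap_2kb_boundary_rule_stricter(self):
        h = build_hierarchy([dom("1", 15_000, 150_000, 0)])
        # anchor pokes 1 bp into the window: passes flank_window, fails 2 kb rule
        lp = loop("1", 16_999, 26_999, 80_000, 90_000)
        assert classify_loop_vs_domains(lp, h, boundary_rule="flank_window").category == (
            "one_colocated_anchor"
        )
        assert classify_loop_vs_domains(lp, h, boundary_rule="min_overlap_2kb").category == (
            "embedded"
        )

    def test_level_only_for_in_domain_categories(self):
        with pytest.raises(ValueError):
            LoopDomainClass("L", "inter_domain", level=0)
        with pytest.raises(ValueError):
            LoopDomainClass("L", "embedded", level=None)


class TestAggregation:
    def test_categories_partition_loop_set(self, bundle, bundle_outputs):
        classes = bundle_outputs["domain_classes"]
        assert len(classes) == len(bundle.loops)
        counts = Counter(c.category for c in classes)
        assert sum(counts.values()) == len(bundle.loops)
        summary = bundle_outputs["domain_summary"]
        assert (
            summary["overlapping_total"]
            + summary["inter_domain"]
            + summary["no_overlap"]
            == summary["total_loops"]
        )

    def test_matrix_cells_sum_to_overlapping_total(self, bundle_outputs):
        matrix = bundle_outputs["domain_matrix"]
        cats = ["embedded", "one_colocated_anchor", "two_colocated_anchors"]
        assert matrix[cats].to_numpy().sum() == bundle_outputs["domain_summary"]["overlapping_total"]

    def test_embedded_implies_span_contained(self, bundle, bundle_outputs):
        h = build_hierarchy(bundle.domains)
        by_id = {lp.loop_id: lp for lp in bundle.loops}
        for c in bundle_outputs["domain_classes"]:
            if c.category == "embedded":
                assert any(d.span.contains(by_id[c.loop_id].span) for d in h.nodes)

    def test_generator_truth_recovered_exactly(self, bundle, bundle_outputs):
        got = {c.loop_id: (c.category, c.level) for c in bundle_outputs["domain_classes"]}
        for lid, cat in bundle.truth.loop_domain_category.items():
            if cat is None:
                continue
            assert got[lid][0] == cat
            assert got[lid][1] == bundle.truth.loop_domain_level[lid]

    def test_three_way_grouping_excludes_no_overlap(self, bundle_outputs):
        groups = three_way_grouping(bundle_outputs["domain_classes"])
        n = sum(len(v) for v in groups.values())
        s = bundle_outputs["domain_summary"]
        assert n == s["total_loops"] - s["no_overlap"]
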