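"""Anchor annotation categories and loop content summaries."""

import pytest

from loopcoloc.annotation import (
    annotate_anchors,
    annotation_summary,
    summarize_loop_content,
    write_annotations,
)
from loopcoloc.intervals import GenomicInterval, StrandedInterval
from loopcoloc.records import ExpressionRecord, GeneRecord, LoopRecord, PeakRecord


def gene(chrom, s, e, gid, strand="+"):
    return GeneRecord(StrandedInterval(chrom, s, e, strand), gid)


def expr(gid, mean):
    return ExpressionRecord(gid, (mean,) * 4, mean, mean >= 1.0)


def peak(chrom, s, e, pid):
    return PeakRecord(GenomicInterval(chrom, s, e), pid)


LOOPS = [
    LoopRecord.make("1", 10_000, 20_000, 80_000, 90_000, "L1"),
    LoopRecord.make("1", 10_000, 20_000, 150_000, 160_000, "L2"),  # shares anchor1
]


class TestAnnotateAnchors:
    def test_bare_anchor_has_all_zero_counts(self):
        ann = annotate_anchors(LOOPS, [], {}, [])
        assert all(a.bare for a in ann)
        assert len(ann) == 3  # shared anchor deduplicated by exact coordinates

    def test_expressed_gene_with_overlapping_peak_is_eo(self):
        genes = [gene("1", 12_000, 15_000, "GA")]
        peaks = [peak("1", 13_000, 13_200, "P1")]
        ann = annotate_anchors(LOOPS, genes, {"GA": expr("GA", 5.0)}, peaks)
        a = next(x for x in ann if x.anchor.start == 10_000)
        assert a.counts["eo"] == 1 and not a.bare
        assert a.counts["mp"] == 1
        # peak's nearest expressed gene overlaps it -> not a distal peak
        assert a.counts["mpfe"] == 0

    def test_gene_without_expression_record_is_unexpressed(self):
        genes = [gene("1", 12_000, 15_000, "GA")]
        ann = annotate_anchors(LOOPS, genes, {}, [])
        a = next(x for x in ann if x.anchor.start == 10_000)
        assert a.counts["uf"] == 1 and a.counts["ef"] == 0

    def test_strand_decides_upstream_vs_downstream(self):
        genes = [gene("1", 12_000, 15_000, "GA", strand="-")]
        peaks = [peak("1", 15_500, 15_600, "P1")]  # right of gene, minus strand => 5'
        ann = annotate_anchors(LOOPS, genes, {"GA": expr("GA", 5.0)}, peaks)
        a = next(x for x in ann if x.anchor.start == 10_000)
        assert a.counts["en5"] == 1

    def test_mpfe_counts_distal_peaks_only(self):
        genes = [gene("1", 12_000, 15_000, "GA")]
        peaks = [peak("1", 18_000, 18_200, "P1")]  # 3 kb from the expressed gene
        ann = annotate_anchors(LOOPS, genes, {"GA": expr("GA", 5.0)}, peaks)
        a = next(x for x in ann if x.anchor.start == 10_000)
        assert a.counts["mp"] == 1 and a.counts["mpfe"] == 1
        assert a.counts["ef"] == 1  # the gene's nearest peak is > 2 kb away

    def test_removing_peaks_flows_categories_to_ef(self, bundle, bundle_outputs):
        """Category-flow property: without peaks every expressed gene is ef
        and mp/mpfe vanish."""
        expr_map = {r.gene_id: r for r in bundle.expression}
        with_peaks = bundle_outputs["annotations"]
        without = annotate_anchors(bundle.loops, bundle.genes, expr_map, [])
        by_anchor = {a.anchor: a for a in without}
        for a in with_peaks:
            b = by_anchor[a.anchor]
            assert b.counts["mp"] == 0 and b.counts["mpfe"] == 0
            assert b.counts["ef"] == a.n_expressed_genes
            assert b.counts["eo"] == b.counts["en3"] == b.counts["en5"] == 0
            assert b.n_genes == a.n_genes

    def test_anchor_accounting_partition(self, bundle_outputs):
        ann = bundle_outputs["annotations"]
        s = annotation_summary(ann)
        non_bare = sum(1 for a in ann if not a.bare)
        assert non_bare + s["bare_anchors"] == s["distinct_anchors"] == len(ann)
        assert all(a.counts["mpfe"] <= a.counts["mp"] for a in ann)

    def test_written_table_shape(self, tmp_path, bundle_outputs):
        out = tmp_path / "ann.tsv"
        write_annotations(bundle_outputs["annotations"], out)
        lines = out.read_text().splitlines()
        header = lines[0].split("\t")
        assert header[:5] == ["seqid", "start", "end", "locus", "bare"]
        assert header[5:] == ["ef", "uf", "en3", "un3", "en5", "un5", "eo", "uo", "mp", "mpfe"]
        assert len(lines) == 1 + len(bundle_outputs["annotations"])


class TestLoopContent:
    def test_all_bare_annotations(self):
        ann = annotate_anchors(LOOPS, [], {}, [])
        content = summarize_loop_content(LOOPS, ann)
        assert content.bare_bare_loop_count == len(LOOPS)
        assert content.loops_both_anchors_expressed == 0
        assert content.anchors_peak_no_gene == 0

    def test_two_loop_manual_enumeration(self):
        genes = [
            gene("1", 12_000, 15_000, "GA"),  # expressed, in shared anchor
            gene("1", 82_000, 85_000, "GB"),  # expressed, in L1 anchor2
        ]
        peaks = [
            peak("1", 13_000, 13_200, "P1"),  # in shared anchor
            peak("1", 86_000, 86_200, "P2"),  # in L1 anchor2
            peak("1", 155_000, 155_200, "P3"),  # in L2 anchor2, no gene there
        ]
        expr_map = {"GA": expr("GA", 5.0), "GB": expr("GB", 2.0)}
        ann = annotate_anchors(LOOPS, genes, expr_map, peaks)
        content = summarize_loop_content(LOOPS, ann)
        # L1: both anchors expressed and peaked; L2: anchor2 has peak, no gene
        assert content.loops_both_anchors_expressed == 1
        assert content.loops_both_anchors_expressed_and_peaked == 1
        assert content.anchors_peak_no_gene == 1
        # L2's peak-only anchor faces the shared anchor (gene + peak): counted
        assert content.anchors_peak_no_gene_opposite_gene_and_peak == 1
        assert content.bare_bare_loop_count == 0

    def test_nested_counts_bounded(self, bundle, bundle_outputs):
        c = bundle_outputs["loop_content"]
        assert c.loops_both_anchors_expressed_and_peaked <= c.loops_both_anchors_expressed
        assert c.anchors_peak_no_gene_opposite_gene_and_peak <= c.anchors_peak_no_gene
        assert c.bare_bare_loop_count <= len(bundle.loops)

    def test_missing_anchor_annotation_fatal(self):
        ann = annotate_anchors(LOOPS[:1], [], {}, [])
        with pytest.raises(ValueError, match="missing"):
            summarize_loop_content(LOOPS, ann)
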