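"""Expression thresholding, consensus peaks, and peak-gene proximity."""

import pandas as pd
import pytest

from loopcoloc.features import (
    build_consensus_peaks,
    classify_gene_nearest_peak,
    classify_peak_gene_proximity,
    compute_expression,
)
from loopcoloc.intervals import GenomicInterval, StrandedInterval, overlap_length
from loopcoloc.records import GeneRecord, PeakRecord


def expr_table(rows):
    return pd.DataFrame(
        [{"gene_id": g, **{f"tpm_rep{i+1}": v for i, v in enumerate(t)}} for g, t in rows]
    )


class TestComputeExpression:
    def test_threshold_boundary_is_inclusive(self):
        (r,) = compute_expression(expr_table([("GA", (1.0, 1.0, 1.0, 1.0))]))
        assert r.expressed and r.mean_tpm == 1.0

    def test_all_zero_is_unexpressed(self):
        (r,) = compute_expression(expr_table([("GA", (0, 0, 0, 0))]))
        assert not r.expressed

    def test_arithmetic_mean(self):
        (r,) = compute_expression(expr_table([("GA", (0.5, 1.5, 0.9, 1.2))]))
        assert r.mean_tpm == pytest.approx(1.025)
        assert r.expressed

    def test_negative_tpm_fatal(self):
        with pytest.raises(ValueError, match="negative"):
            compute_expression(expr_table([("GA", (1.0, -0.1, 0.0, 0.0))]))


def peak(chrom, s, e, pid="p", rep=None):
    return PeakRecord(GenomicInterval(chrom, s, e), pid, rep)


class TestBuildConsensusPeaks:
    def test_single_replicate_yields_nothing_at_support_two(self):
        assert build_consensus_peaks([[peak("1", 0, 100)]], min_support=2) == []

    def test_component_union_across_replicates(self):
        out = build_consensus_peaks(
            [[peak("1", 100, 200, rep="1")], [peak("1", 150, 250, rep="2")], []],
            min_support=2,
        )
        assert len(out) == 1
        assert (out[0].span.start, out[0].span.end, out[0].support) == (100, 250, 2)

    def test_disjoint_replicate_peaks_make_no_consensus(self):
        out = build_consensus_peaks(
            [[peak("1", 0, 50)], [peak("1", 60, 100)]], min_support=2
        )
        assert out == []

    def test_empty_input_fatal_but_support_one_works(self):
        with pytest.raises(ValueError):
            build_consensus_peaks([], min_support=2)
        out = build_consensus_peaks([[peak("1", 0, 50)]], min_support=1)
        assert len(out) == 1 and out[0].support == 1

    def test_min_overlap_bp_threshold_breaks_weak_chains(self):
        reps = [[peak("1", 0, 100, rep="1")], [peak("1", 95, 200, rep="2")]]
        assert len(build_consensus_peaks(reps, min_support=2, min_overlap_bp=1)) == 1
        assert build_consensus_peaks(reps, min_support=2, min_overlap_bp=10) == []

    def test_consensus_peaks_never_overlap_and_support_holds(self, bundle):
        out = build_consensus_peaks(bundle.peak_replicates, min_support=2)
        for a, b in zip(out, out[1:]):
            assert overlap_length(a.span, b.span) == 0
        assert all(p.support >= 2 for p in out)
        # every consensus component is backed by >= 2 distinct replicates
        for p in out:
            reps = {
                member.replicate
                for rep_set in bundle.peak_replicates
                for member in rep_set
                if overlap_length(member.span, p.span) >= 1
            }
            assert len(reps) >= p.support >= 2


def gene(chrom, s, e, strand, gid="g"):
    return GeneRecord(StrandedInterval(chrom, s, e, strand), gid)


class TestProximityClassification:
    def test_overlap_is_distance_zero(self):
        g = gene("1", 10_000, 20_000, "+")
        got_gene, cls = classify_peak_gene_proximity(peak("1", 19_900, 20_050), [g])
        assert got_gene is g
        assert cls.category == "overlap" and cls.distance.value == 0

    def test_right_of_plus_gene_is_downstream(self):
        g = gene("1", 10_000, 20_000, "+")
        _g, cls = classify_peak_gene_proximity(peak("1", 21_000, 21_100), [g])
        assert cls.category == "downstream_lt2kb" and cls.distance.value == 1000

    def test_right_of_minus_gene_is_upstream(self):
        g = gene("1", 10_000, 20_000, "-")
        _g, cls = classify_peak_gene_proximity(peak("1", 21_000, 21_100), [g])
        assert cls.category == "upstream_lt2kb"

    def test_two_kb_boundary_counts_as_near(self):
        g = gene("1", 10_000, 20_000, "+")
        _g, cls = classify_peak_gene_proximity(peak("1", 22_000, 22_100), [g])
        assert cls.category == "downstream_lt2kb" and cls.distance.value == 2000
        _g, cls = classify_peak_gene_proximity(peak("1", 22_001, 22_100), [g])
        assert cls.category == "farther_2kb"

    def test_no_gene_on_chromosome_is_distal(self):
        got_gene, cls = classify_peak_gene_proximity(peak("5", 0, 100), [gene("1", 0, 10, "+")])
        assert got_gene is None and cls.category == "farther_2kb"

    def test_gene_to_peak_direction_mirrors(self):
        g = gene("1", 10_000, 20_000, "-")
        cls = classify_gene_nearest_peak(g, [GenomicInterval("1", 8_500, 8_600)])
        # peak left of a minus-strand gene lies 3' (downstream)
        assert cls.category == "downstream_lt2kb" and cls.distance.value == -1400

    def test_categories_partition_any_peak_set(self, bundle):
        genes = bundle.genes
        cats = [
            classify_peak_gene_proximity(p, genes)[1].category
            for p in bundle.truth_peaks
        ]
        assert all(
            c in ("overlap", "upstream_lt2kb", "downstream_lt2kb", "farther_2kb")
            for c in cats
        )
        # near/far split is exactly the 2 kb rule
        for p in bundle.truth_peaks:
            _g, cls = classify_peak_gene_proximity(p, genes)
            near = cls.category in ("overlap", "upstream_lt2kb", "downstream_lt2kb")
            assert near == (abs(cls.distance.value) <= 2000)

    def test_generator_placement_classes_recovered(self, bundle):
        """Peaks placed by the generator recover their intended proximity class."""
        genes = bundle.genes
        for p in bundle.truth_peaks:
            intended = bundle.truth.peak_gene_class[p.peak_id]
            got_gene, cls = classify_peak_gene_proximity(p, genes)
            assert got_gene.gene_id == bundle.truth.peak_host_gene[p.peak_id]
            if intended == "overlap":
                assert cls.category == "overlap"
            elif intended == "lt2kb":
                assert cls.category in ("upstream_lt2kb", "downstream_lt2kb")
            else:
                assert cls.category == "farther_2kb"
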