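"""Published reference counts from the maize B73 leaf Hi-C loop study.

These are the printed count tables and headline totals of the source study
(maize B73 v04 leaf tissue; two ultra-deep Hi-C replicates on AGPv4). They
serve as *inputs* to desk-scale arithmetic checks: the derived percentages
are always recomputed here, never stored.

Loop-vs-domain tables give, per hierarchy level, the number of loops fully
embedded in a domain and the number with one or two anchors co-located with
that domain's boundaries.
"""

from __future__ import annotations

import pandas as pd

from .domains import IN_DOMAIN_CATEGORIES

# replicate 1: loop overlap with hierarchical TAD-like domains, per level
REP1_LOOP_DOMAIN_TABLE = pd.DataFrame(
    {
        "level": [0, 1, 2, 3, 4, 5, 6],
        "embedded": [4272, 2484, 852, 185, 18, 2, 2],
        "one_colocated_anchor": [1214, 1024, 366, 76, 13, 3, 1],
        "two_colocated_anchors": [85, 103, 67, 7, 0, 0, 0],
    }
)
REP1_TOTAL_LOOPS_EXCL_CHR0 = 16_863

# replicate 2: same shape
REP2_LOOP_DOMAIN_TABLE = pd.DataFrame(
    {
        "level": [0, 1, 2, 3, 4, 5],
        "embedded": [5360, 3117, 1109, 213, 35, 3],
        "one_colocated_anchor": [2484, 2104, 769, 164, 19, 4],
        "two_colocated_anchors": [308, 371, 142, 30, 4, 0],
    }
)
REP2_TOTAL_LOOPS_EXCL_CHR0 = 25_628

# high-resolution loop co-location with replicate-2 Hi-C anchors
# (2 / 1 / 0 co-located anchors at the >=50%-overlap criterion)
HIGHRES_COLOCATION_TABLE = pd.DataFrame(
    {
        "dataset": ["ChIA-PET", "HiChIP_H3K27me3", "HiChIP_H3K4me3"],
        "two_colocated": [4511, 3612, 10021],
        "one_colocated": [15890, 24909, 45011],
        "zero_colocated": [3817, 11297, 11980],
        "total": [24218, 39818, 67012],
    }
)

# headline totals
INITIAL_LOOPS = {"rep1": 17_176, "rep2": 25_917}
DOMAINS_DETECTED = {"rep1": 17_978, "rep2": 18_739}
LOOPS_SHARED_BOTH_ANCHORS = 7_917
LOOPS_NO_SHARED_ANCHOR = {"rep1": 1_268, "rep2": 2_657}
GENES_CHR1_10 = 38_847
GENES_TOTAL = 44_474
EXPRESSED_GENES = 18_700
EXPRESSED_GENES_ON_ANCHORS = 13_918
CONSENSUS_NF_PEAKS = 19_532
PEAKS_ON_ANCHORS = 13_026
EQTL_UNIQUE_SNPS = 43_398
EQTL_SNPS_ON_ANCHORS = {"rep1": 25_162, "rep2": 27_252}
EQTL_SAME_ANCHOR = {"rep1": 10_938, "rep2": 17_020}
EQTL_CROSS_ANCHOR = {"rep1": 1_829, "rep2": 2_632}
ANCHORS_WITH_EXPRESSED_GENE_REP1 = 18_296
ANCHORS_WITH_ONE_EXPRESSED_GENE_REP1 = 15_058
BARE_ANCHORS_REP1 = 11_066
LOOPS_BOTH_ANCHORS_EXPRESSED_REP1 = 5_488


def domain_table_summary(table: pd.DataFrame, total_loops: int) -> dict:
    """Derived shares from a per-level loop-vs-domain count table.

    Returns the number of domain-overlapping loops, the embedded count, the
    embedded percentage of all loops and of overlapping loops.
    """
    counts = {cat: int(table[cat].sum()) for cat in IN_DOMAIN_CATEGORIES}
    overlapping = sum(counts.values())
    embedded = counts["embedded"]
    return {
        "overlapping": overlapping,
        "embedded": embedded,
        **counts,
        "embedded_pct_of_total": 100.0 * embedded / total_loops,
        "embedded_pct_of_overlapping": 100.0 * embedded / overlapping,
    }


def percentage(part: int, whole: int) -> float:
    return 100.0 * part / whole
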