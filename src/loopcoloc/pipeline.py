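"""Pipeline orchestration: run every stage in dependency order and collect a
single metrics dict, plus the desk-scale arithmetic on published counts and
the supplementary-table reproduction driver."""

from __future__ import annotations

import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from . import published
from .annotation import (
    annotate_anchors,
    annotation_summary,
    summarize_loop_content,
    write_annotations,
)
from .colocation import (
    assign_features_to_loops,
    colocate_highres_loops,
    classify_shared_anchors,
    distinct_anchors,
    map_interactions_to_zones,
    pair_loops_by_anchor_overlap,
)
from .domains import (
    build_hierarchy,
    classify_loops,
    domain_class_summary,
    per_level_count_matrix,
    three_way_grouping,
)
from .eqtl import colocate_eqtls
from .features import build_consensus_peaks
from .repeats import compute_densities, density_summary
from .synth import SynthBundle

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every tunable cut the analysis uses, with the study's values."""

    min_overlap_bp: int = 1  # "overlap" means >= 1 shared bp
    min_frac: float = 0.5  # high-resolution anchor co-location criterion
    flank_bp: int = 2000  # domain-boundary window half-width
    proximity_bp: int = 2000  # peak-gene near/far cut
    tpm_threshold: float = 1.0  # expressed-gene mean TPM cut
    min_support: int = 2  # consensus-peak replicate support

    def validate(self) -> None:
        if min(
            self.min_overlap_bp,
            self.flank_bp,
            self.proximity_bp,
            self.min_support,
        ) <= 0 or self.min_frac <= 0 or self.tpm_threshold <= 0:
            raise ValueError("all thresholds must be positive")


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: %.2fs", stage, time.perf_counter() - self.t0)

    return _T()


def analyze_bundle(
    bundle: SynthBundle, thresholds: Optional[Thresholds] = None
) -> dict:
    """Run every analysis stage on an in-memory synthetic bundle.

    Returns the stage outputs keyed the way :func:`loopcoloc.synth.truth_report`
    expects, together with derived summary metrics.
    """
    th = thresholds or Thresholds()
    th.validate()
    loops = bundle.loops
    out: dict = {"seed": bundle.config.seed}

    with _timed("assign"):
        gene_assign, gene_counts = assign_features_to_loops(
            {g.gene_id: g.span for g in bundle.genes}, loops, th.min_overlap_bp
        )
        out["gene_zones"] = {a.feature_id: a.zone for a in gene_assign}
        out["gene_zone_counts"] = dict(gene_counts)
        peak_assign, peak_counts = assign_features_to_loops(
            {p.peak_id: p.span for p in bundle.truth_peaks}, loops, th.min_overlap_bp
        )
        out["peak_zones"] = {a.feature_id: a.zone for a in peak_assign}
        out["peak_zone_counts"] = dict(peak_counts)

    with _timed("consensus"):
        out["consensus"] = build_consensus_peaks(
            bundle.peak_replicates, th.min_support, th.min_overlap_bp
        )

    with _timed("domains"):
        hierarchy = build_hierarchy(bundle.domains)
        out["domain_classes"] = classify_loops(loops, hierarchy, th.flank_bp)
        out["domain_summary"] = domain_class_summary(out["domain_classes"])
        out["domain_matrix"] = per_level_count_matrix(out["domain_classes"])

    with _timed("eqtl"):
        out["eqtl_classes"], out["eqtl_summary"] = colocate_eqtls(
            bundle.eqtls, loops, bundle.genes
        )

    with _timed("repeats"):
        out["densities"] = compute_densities(loops, bundle.repeats)
        out["density_summary"] = density_summary(out["densities"])

    with _timed("pairloops"):
        out["rep2_shared"], out["rep2_shared_counts"] = pair_loops_by_anchor_overlap(
            bundle.loops_rep2, loops, th.min_overlap_bp
        )

    with _timed("highres"):
        out["highres_classes"] = classify_shared_anchors(
            bundle.highres, loops, min_frac=th.min_frac, frac_of="query"
        )
        out["highres_counts"] = colocate_highres_loops(
            bundle.highres, loops, th.min_frac, frac_of="query"
        )
        _maps, out["interaction_zone_counts"] = map_interactions_to_zones(
            bundle.highres, loops, th.min_frac, frac_of="query"
        )

    with _timed("annotate"):
        expr = {r.gene_id: r for r in bundle.expression}
        consensus_as_peaks = [
            type(bundle.truth_peaks[0])(c.span, c.peak_id) for c in out["consensus"]
        ] if out["consensus"] else []
        out["annotations"] = annotate_anchors(
            loops, bundle.genes, expr, consensus_as_peaks, th.proximity_bp, th.min_overlap_bp
        )
        out["annotation_summary"] = annotation_summary(out["annotations"])
        out["loop_content"] = summarize_loop_content(loops, out["annotations"])

    # Fig-3-style grouping: share of loops per domain group with >= 1 peak on
    # an anchor, and mean TPM of genes overlapping anchors per group
    groups = three_way_grouping(out["domain_classes"])
    out["three_way_groups"] = {k: len(v) for k, v in groups.items()}
    return out


def desk_arithmetic() -> dict:
    """Headline percentages recomputed from the published count tables.

    All four are derived at run time by the package's summary arithmetic
    from printed counts: the embedded-loop share of all replicate-2 loops,
    the embedded share of domain-overlapping replicate-1 loops, the share of
    expressed genes primarily on loop anchors, and the share of unique eQTL
    SNPs on replicate-2 anchors.
    """
    rep2 = published.domain_table_summary(
        published.REP2_LOOP_DOMAIN_TABLE, published.REP2_TOTAL_LOOPS_EXCL_CHR0
    )
    rep1 = published.domain_table_summary(
        published.REP1_LOOP_DOMAIN_TABLE, published.REP1_TOTAL_LOOPS_EXCL_CHR0
    )
    return {
        "embedded_loop_pct_rep2": rep2["embedded_pct_of_total"],
        "embedded_pct_of_overlapping_rep1": rep1["embedded_pct_of_overlapping"],
        "rep1_overlapping_loops": rep1["overlapping"],
        "rep1_embedded_loops": rep1["embedded"],
        "expressed_gene_anchor_pct": published.percentage(
            published.EXPRESSED_GENES_ON_ANCHORS, published.EXPRESSED_GENES
        ),
        "eqtl_unique_snp_anchor_pct": published.percentage(
            published.EQTL_SNPS_ON_ANCHORS["rep2"], published.EQTL_UNIQUE_SNPS
        ),
    }


def compare_metrics(metrics: dict, expectations: dict) -> "pd.DataFrame":
    """Evaluate metrics against expectations with per-target comparators.

    ``expectations`` maps metric name to a dict with ``value``, ``cmp`` in
    {eq, le, ge} and optional ``round`` (decimal places applied to both sides
    before an eq comparison). Metrics absent from ``metrics`` are reported as
    untested, not failed.
    """
    import pandas as pd

    rows = []
    for name, spec in expectations.items():
        target = spec["value"]
        cmp_ = spec.get("cmp", "eq")
        if name not in metrics:
            rows.append(
                {"metric": name, "target": target, "actual": None, "cmp": cmp_, "status": "untested"}
            )
            continue
        actual = metrics[name]
        nd = spec.get("round")
        a, t = actual, target
        if nd is not None:
            a, t = round(actual, nd), round(target, nd)
        if cmp_ == "eq":
            ok = a == t
        elif cmp_ == "le":
            ok = a <= t
        elif cmp_ == "ge":
            ok = a >= t
        else:
            raise ValueError(f"unknown comparator {cmp_!r} for {name}")
        rows.append(
            {
                "metric": name,
                "target": target,
                "actual": actual,
                "cmp": cmp_,
                "status": "pass" if ok else "fail",
            }
        )
    return pd.DataFrame(rows, columns=["metric", "target", "actual", "cmp", "status"])


def reproduce_supplementary(data_dir, chromosomes=tuple(str(c) for c in range(1, 11))) -> dict:
    """Recompute the headline counts from the study's supplementary tables.

    Expects, under ``data_dir``: ``loops_rep1.tsv`` / ``loops_rep2.tsv``
    (6-column anchor tables), ``domains_rep1.tsv`` (seqid/start0/end0/level)
    and ``peaks_nf.tsv`` (consensus NF peak BED). Computes loop parse counts
    with and without Chr0, replicate anchor sharing, the loop-vs-domain
    classification, and — when gene/expression tables are also present —
    the anchor-annotation summaries.
    """
    from . import io as lio

    data_dir = Path(data_dir)

    def need(name: str) -> Path:
        p = data_dir / name
        if not p.exists():
            raise FileNotFoundError(
                f"supplementary table {name} not found under {data_dir}; "
                "download the study's loop/domain/peak tables and place them "
                "there with these names"
            )
        return p

    out: dict = {}
    loops1_all = lio.read_loops(need("loops_rep1.tsv"))
    out["rep1_loops_total"] = len(loops1_all)
    loops1 = lio.read_loops(data_dir / "loops_rep1.tsv", chromosome_filter=set(chromosomes))
    out["rep1_loops_excl_chr0"] = len(loops1)
    loops2 = lio.read_loops(need("loops_rep2.tsv"), chromosome_filter=set(chromosomes))
    _cls, counts = pair_loops_by_anchor_overlap(loops1, loops2)
    out["rep1_loops_shared_both_anchors"] = counts.get(2, 0)
    out["rep1_loops_shared_no_anchor"] = counts.get(0, 0)
    hierarchy = build_hierarchy(lio.read_domains(need("domains_rep1.tsv")))
    summary = domain_class_summary(classify_loops(loops1, hierarchy))
    out["rep1_loops_overlapping_domains"] = summary["overlapping_total"]
    out["rep1_loops_embedded"] = summary["embedded"]
    peaks = lio.read_table(need("peaks_nf.tsv"), "peaks")
    out["consensus_nf_peaks"] = len(peaks)
    genes_path = data_dir / "genes.gff3"
    expr_path = data_dir / "expression.tsv"
    if genes_path.exists() and expr_path.exists():
        genes = lio.read_gene_models(genes_path, chromosome_filter=set(chromosomes))
        expr = {r.gene_id: r for r in lio.read_table(expr_path, "expression")}
        ann = annotate_anchors(loops1, genes, expr, peaks)
        out.update(annotation_summary(ann))
        content = summarize_loop_content(loops1, ann)
        out["loops_both_anchors_expressed"] = content.loops_both_anchors_expressed
    return out


def run_synthetic_pipeline(seed: int, outdir=None, config=None) -> dict:
    """Generate a synthetic bundle, analyze it, and (optionally) write the
    report tables; returns {bundle, outputs, report}."""
    from .synth import SynthConfig, generate, truth_report

    cfg = config or SynthConfig(seed=seed)
    if config is not None:
        cfg.seed = seed
    bundle = generate(cfg)
    outputs = analyze_bundle(bundle)
    report = truth_report(bundle, outputs)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out_metrics = {
            "seed": seed,
            "gene_zone_counts": outputs["gene_zone_counts"],
            "peak_zone_counts": outputs["peak_zone_counts"],
            "domain_summary": outputs["domain_summary"],
            "eqtl_summary": outputs["eqtl_summary"],
            "density_summary": outputs["density_summary"],
            "rep2_shared_counts": {str(k): v for k, v in outputs["rep2_shared_counts"].items()},
            "highres_counts": {str(k): v for k, v in outputs["highres_counts"].items()},
            "interaction_zone_counts": dict(outputs["interaction_zone_counts"]),
            "annotation_summary": outputs["annotation_summary"],
            "three_way_groups": outputs["three_way_groups"],
            "truth_all_passed": bool(report["passed"].all()),
        }
        from .io import write_json

        outputs["domain_matrix"].to_csv(outdir / "domain_matrix.tsv", sep="\t", index=False)
        report.to_csv(outdir / "truth_report.tsv", sep="\t", index=False)
        write_annotations(outputs["annotations"], outdir / "anchor_annotation.tsv")
        write_json(out_metrics, outdir / "metrics.json")
    return {"bundle": bundle, "outputs": outputs, "report": report}
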