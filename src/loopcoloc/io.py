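"""Readers and writers for the analysis' table dialects.

All genomic tables are plain text. Loop and domain tables (HICCUPS / HiTAD
output) and BED-like peak/repeat tables are taken as 0-based half-open; GFF3
gene models are converted from 1-based inclusive on read and restored on
write. Chromosome labels are normalized by stripping an optional ``Chr``
prefix so the same chromosome matches across files.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, StrandedInterval, normalize_chrom
from .records import (
    GENE_FEATURE_TYPES,
    DomainRecord,
    EqtlRecord,
    ExpressionRecord,
    GeneRecord,
    LoopRecord,
    PeakRecord,
    RepeatRecord,
)

logger = logging.getLogger(__name__)

TABLE_SCHEMAS = ("peaks", "expression", "eqtl", "repeats", "highres_loops")


def _read_frame(path, n_numeric_cols: Sequence[int], names: Sequence[str]) -> pd.DataFrame:
    """Read a whitespace/tab/comma table, auto-detecting an optional header.

    The header is detected by checking whether the columns listed in
    ``n_numeric_cols`` parse as integers on the first row.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        return pd.DataFrame(columns=list(names))
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    fields = first.replace(",", "\t").split() if sep == r"\s+" else first.rstrip("\n").split(
        "\t" if sep == "\t" else ","
    )
    has_header = False
    for idx in n_numeric_cols:
        if idx < len(fields):
            try:
                int(float(fields[idx]))
            except ValueError:
                has_header = True
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python",
        header=0 if has_header else None,
        comment="#",
    )
    if df.shape[1] < len(names):
        raise ValueError(
            f"{path}: expected >= {len(names)} columns, found {df.shape[1]}"
        )
    df = df.iloc[:, : len(names)].copy()
    df.columns = list(names)
    return df


def read_loops(
    path,
    chromosome_filter: Optional[set] = None,
    id_prefix: str = "L",
) -> list[LoopRecord]:
    """Read a 6-column loop table (chr1, x1, x2, chr2, y1, y2).

    Anchors are normalized left-to-right. Inter-chromosomal rows are rejected
    (dropped with a logged count) since the analysis is intra-chromosomal
    only; malformed coordinates raise with the offending line number. Rows on
    chromosomes outside ``chromosome_filter`` (normalized labels) are dropped
    with a logged count.
    """
    df = _read_frame(path, n_numeric_cols=(1, 2, 4, 5), names=("chr1", "x1", "x2", "chr2", "y1", "y2"))
    loops: list[LoopRecord] = []
    n_inter = 0
    n_filtered = 0
    norm_filter = (
        {normalize_chrom(c) for c in chromosome_filter}
        if chromosome_filter is not None
        else None
    )
    for i, row in enumerate(df.itertuples(index=False), start=1):
        c1, c2 = normalize_chrom(row.chr1), normalize_chrom(row.chr2)
        x1, x2, y1, y2 = int(row.x1), int(row.x2), int(row.y1), int(row.y2)
        if x1 >= x2 or y1 >= y2 or x1 < 0 or y1 < 0:
            raise ValueError(f"{path} line {i}: invalid anchor coordinates")
        if c1 != c2:
            n_inter += 1
            continue
        if norm_filter is not None and c1 not in norm_filter:
            n_filtered += 1
            continue
        loops.append(LoopRecord.make(c1, x1, x2, y1, y2, f"{id_prefix}{len(loops) + 1}"))
    if n_inter:
        logger.warning("%s: dropped %d inter-chromosomal loop rows", path, n_inter)
    if n_filtered:
        logger.info("%s: dropped %d loops on filtered chromosomes", path, n_filtered)
    return loops


def write_loops(loops: Iterable[LoopRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chr1", "x1", "x2", "chr2", "y1", "y2"])
        for lp in loops:
            w.writerow(
                [
                    lp.anchor1.chrom,
                    lp.anchor1.start,
                    lp.anchor1.end,
                    lp.anchor2.chrom,
                    lp.anchor2.start,
                    lp.anchor2.end,
                ]
            )


def read_domains(path) -> list[DomainRecord]:
    """Read a HiTAD-style domain table (seqid, start0, end0, level)."""
    df = _read_frame(path, n_numeric_cols=(1, 2, 3), names=("seqid", "start0", "end0", "level"))
    domains = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        start, end, level = int(row.start0), int(row.end0), int(row.level)
        if end <= start or level < 0:
            raise ValueError(f"{path} line {i}: invalid domain row")
        domains.append(
            DomainRecord(GenomicInterval(normalize_chrom(row.seqid), start, end), level)
        )
    return domains


def write_domains(domains: Iterable[DomainRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["seqid", "start0", "end0", "level"])
        for d in domains:
            w.writerow([d.span.chrom, d.span.start, d.span.end, d.level])


def read_gene_models(
    path,
    chromosome_filter: Optional[set] = None,
    feature_types: frozenset = GENE_FEATURE_TYPES,
) -> list[GeneRecord]:
    """Read gene models from GFF3, keeping only whitelisted feature types.

    GFF3 1-based inclusive coordinates become 0-based half-open. ``ID=`` (with
    any ``gene:`` prefix stripped) names the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    norm_filter = (
        {normalize_chrom(c) for c in chromosome_filter}
        if chromosome_filter is not None
        else None
    )
    genes = []
    for ftype in sorted(feature_types):
        for feat in db.features_of_type(ftype):
            chrom = normalize_chrom(feat.seqid)
            if norm_filter is not None and chrom not in norm_filter:
                continue
            gene_id = feat.id.split(":", 1)[-1]
            genes.append(
                GeneRecord(
                    StrandedInterval(chrom, feat.start - 1, feat.end, feat.strand),
                    gene_id,
                    ftype,
                )
            )
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes


def write_gene_models(genes: Iterable[GeneRecord], path) -> None:
    """Write gene records back out as minimal GFF3 (restores 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.span.chrom,
                        "loopcoloc",
                        g.feature_type,
                        str(g.span.start + 1),
                        str(g.span.end),
                        ".",
                        g.span.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def _read_peaks(path, replicate: Optional[str]) -> list[PeakRecord]:
    df = _read_frame(path, n_numeric_cols=(1, 2), names=("chrom", "start", "end"))
    peaks = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        start, end = int(row.start), int(row.end)
        if end <= start:
            raise ValueError(f"{path} line {i}: invalid peak interval")
        peaks.append(
            PeakRecord(
                GenomicInterval(normalize_chrom(row.chrom), start, end),
                f"P{i}",
                replicate,
            )
        )
    return peaks


def _read_repeats(path) -> list[RepeatRecord]:
    df = _read_frame(path, n_numeric_cols=(1, 2), names=("chrom", "start", "end"))
    return [
        RepeatRecord(
            GenomicInterval(normalize_chrom(row.chrom), int(row.start), int(row.end)),
            f"R{i}",
        )
        for i, row in enumerate(df.itertuples(index=False), start=1)
    ]


def _read_expression(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'gene_id'")
    tpm_cols = [c for c in df.columns if str(c).lower().startswith("tpm")]
    if not tpm_cols:
        raise ValueError(f"{path}: missing required column(s) 'tpm*'")
    from .features import compute_expression

    return compute_expression(df[["gene_id", *tpm_cols]])


def _read_eqtls(path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"chrom", "region_start", "region_end", "snp_pos", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    n_flagged = 0
    for i, row in df.iterrows():
        chrom = normalize_chrom(row["chrom"])
        snp = GenomicInterval(chrom, int(row["snp_pos"]), int(row["snp_pos"]) + 1)
        rec = EqtlRecord(
            GenomicInterval(chrom, int(row["region_start"]), int(row["region_end"])),
            snp,
            str(row["gene_id"]),
            eqtl_id=str(row.get("eqtl_id", f"Q{i + 1}")),
        )
        if not rec.snp_in_region:
            n_flagged += 1
        records.append(rec)
    if n_flagged:
        logger.warning("%s: %d eQTL rows have the lead SNP outside the stated region", path, n_flagged)
    return records


def read_table(path, schema: str, replicate: Optional[str] = None, **kwargs):
    """Read a typed record table by schema name.

    Schemas: ``peaks`` (BED3+), ``repeats`` (BED3+), ``expression``
    (gene_id + tpm_* columns), ``eqtl`` (chrom, region_start, region_end,
    snp_pos, gene_id), ``highres_loops`` (6-column BEDPE-like).
    """
    if schema == "peaks":
        return _read_peaks(path, replicate)
    if schema == "repeats":
        return _read_repeats(path)
    if schema == "expression":
        return _read_expression(path)
    if schema == "eqtl":
        return _read_eqtls(path)
    if schema == "highres_loops":
        return read_loops(path, id_prefix=kwargs.pop("id_prefix", "H"), **kwargs)
    raise ValueError(f"unknown schema {schema!r}; expected one of {TABLE_SCHEMAS}")


def write_peaks(peaks: Iterable[PeakRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "start", "end", "peak_id"])
        for p in peaks:
            w.writerow([p.span.chrom, p.span.start, p.span.end, p.peak_id])


def write_repeats(repeats: Iterable[RepeatRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "start", "end"])
        for r in repeats:
            w.writerow([r.span.chrom, r.span.start, r.span.end])


def write_expression(records: Iterable[ExpressionRecord], path) -> None:
    records = list(records)
    n_rep = len(records[0].tpm_by_replicate) if records else 4
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id"] + [f"tpm_rep{i + 1}" for i in range(n_rep)])
        for r in records:
            w.writerow([r.gene_id] + [repr(float(t)) for t in r.tpm_by_replicate])


def write_eqtls(records: Iterable[EqtlRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["eqtl_id", "chrom", "region_start", "region_end", "snp_pos", "gene_id"])
        for q in records:
            w.writerow(
                [
                    q.eqtl_id,
                    q.region.chrom,
                    q.region.start,
                    q.region.end,
                    q.lead_snp.start,
                    q.gene_id,
                ]
            )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
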