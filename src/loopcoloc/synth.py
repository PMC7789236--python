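"""Seeded synthetic-genome generator with exact ground truth for every stage.

The generator emits the full input bundle the analysis consumes — nested
domain hierarchies, Hi-C-style loops whose anchors sit at domain boundaries
with configurable probability, a second loop replicate with controlled
anchor sharing, genes with log-scale expression, peaks placed at controlled
distances from genes, repeats tiled at different rates in anchors versus
interiors, eQTL SNP/gene pairs with configurable same-/cross-anchor rates,
and small high-resolution interactions — together with a ground-truth label
for every record.

Geometry is arranged so labels are exact, not merely probable:

* at most one loop per root-to-leaf chain of the domain tree, so no loop's
  anchors ever fall inside another loop's interior;
* all "outside"/relocated placements draw disjoint segments from a reserved
  chromosome tail, so class-0 anchors overlap nothing by construction;
* boundary anchors start within ``flank_bp`` of a domain edge while staying
  inside the domain, so the loop span stays contained and the boundary call
  is unambiguous.

A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, StrandedInterval, merge_intervals
from .records import (
    DomainRecord,
    EqtlRecord,
    ExpressionRecord,
    GeneRecord,
    LoopRecord,
    PeakRecord,
    RepeatRecord,
)

FLANK_BP = 2000  # boundary window half-width the classifier uses
_CHILD_MARGIN = 10_000  # min distance of a sub-domain edge from its parent's
_EMBED_GAP = (FLANK_BP + 1, 7_000)  # anchor gap from boundary for embedded loops
_BOUNDARY_GAP = (0, FLANK_BP - 1)  # anchor gap for boundary-co-located anchors


@dataclass
class SynthConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate the maize leaf study at reduced scale: 5-25 kb anchors
    (majority near 10 kb), loops tens of kb to ~1 Mb, ~48% of genes
    expressed (TPM >= 1), repeats denser in loop interiors than anchors,
    about a third of eQTLs with SNP and trait on one anchor, and replicate
    loop sets sharing both anchors for roughly half the loops.
    """

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {str(c): 36_000_000 for c in range(1, 6)}
    )
    n_level0_domains: int = 32  # per chromosome
    nesting_depth: int = 2
    nesting_branch: int = 2
    n_loops: int = 200
    anchor_len_range: Tuple[int, int] = (5_000, 25_000)
    loop_len_range: Tuple[int, int] = (30_000, 1_000_000)
    p_anchor_at_boundary: float = 0.15  # per anchor of an in-domain loop
    p_loop_inter_domain: float = 0.06
    p_loop_outside: float = 0.06
    p_shared_anchor: float = 0.0
    level_weights: Tuple[float, ...] = (0.45, 0.35, 0.20)
    # genes & expression
    gene_density: float = 8.0  # genes per Mb of genome
    gene_len_range: Tuple[int, int] = (1_000, 5_000)
    gene_zone_weights: Dict[str, float] = field(
        default_factory=lambda: {"anchor": 0.5, "interior": 0.3, "outside": 0.2}
    )
    p_expressed: float = 0.48
    tpm_log10_range: Tuple[float, float] = (0.0, 2.5)  # expressed-gene mean TPM
    n_boundary_tpm_genes: int = 3  # genes with mean TPM exactly 1.0
    # peaks
    n_peaks: int = 240
    peak_len_range: Tuple[int, int] = (80, 400)
    peak_placement: Dict[str, float] = field(
        default_factory=lambda: {"gene_overlap": 0.35, "lt2kb": 0.27, "gt2kb": 0.38}
    )
    n_peak_replicates: int = 3
    p_peak_in_replicate: float = 0.85
    n_noise_peaks: int = 15  # per replicate, support-1 peaks
    # repeats
    repeat_rate_anchor: float = 0.2
    repeat_rate_interior: float = 0.6
    repeat_rate_background: float = 0.0
    repeat_tile: int = 500
    # eQTLs
    n_eqtl: int = 400
    p_eqtl_same_anchor: float = 0.35
    p_eqtl_cross_anchor: float = 0.06
    # high-resolution interactions
    n_highres: int = 240
    highres_anchor_len_range: Tuple[int, int] = (500, 3_000)
    p_highres_two: float = 0.19
    p_highres_one: float = 0.66
    # second loop replicate
    p_rep2_both_anchors: float = 0.46
    p_rep2_one_anchor: float = 0.31

    def validate(self) -> None:
        fracs = [
            self.p_anchor_at_boundary,
            self.p_loop_inter_domain,
            self.p_loop_outside,
            self.p_shared_anchor,
            self.p_expressed,
            self.p_peak_in_replicate,
            self.repeat_rate_anchor,
            self.repeat_rate_interior,
            self.repeat_rate_background,
            self.p_eqtl_same_anchor,
            self.p_eqtl_cross_anchor,
            self.p_highres_two,
            self.p_highres_one,
            self.p_rep2_both_anchors,
            self.p_rep2_one_anchor,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_eqtl_same_anchor + self.p_eqtl_cross_anchor > 1.0:
            raise ValueError("eQTL class probabilities sum above 1")
        if self.p_highres_two + self.p_highres_one > 1.0:
            raise ValueError("high-resolution class probabilities sum above 1")
        if self.p_rep2_both_anchors + self.p_rep2_one_anchor > 1.0:
            raise ValueError("replicate-2 class probabilities sum above 1")
        if self.p_loop_inter_domain + self.p_loop_outside > 1.0:
            raise ValueError("loop placement probabilities sum above 1")
        if self.anchor_len_range[0] > self.anchor_len_range[1]:
            raise ValueError("anchor_len_range reversed")


@dataclass
class GroundTruth:
    """Intended label for every emitted record, plus the configured rates."""

    gene_zone: Dict[str, str] = field(default_factory=dict)
    peak_zone: Dict[str, str] = field(default_factory=dict)
    gene_expressed: Dict[str, bool] = field(default_factory=dict)
    peak_gene_class: Dict[str, str] = field(default_factory=dict)
    peak_host_gene: Dict[str, str] = field(default_factory=dict)
    peak_support: Dict[str, int] = field(default_factory=dict)
    loop_domain_category: Dict[str, Optional[str]] = field(default_factory=dict)
    loop_domain_level: Dict[str, Optional[int]] = field(default_factory=dict)
    eqtl_class: Dict[str, str] = field(default_factory=dict)
    rep2_shared: Dict[str, int] = field(default_factory=dict)
    highres_shared: Dict[str, int] = field(default_factory=dict)
    highres_zone_pair: Dict[str, str] = field(default_factory=dict)
    config_rates: Dict[str, float] = field(default_factory=dict)


@dataclass
class SynthBundle:
    """All generated record sets plus their ground truth."""

    config: SynthConfig
    domains: List[DomainRecord]
    loops: List[LoopRecord]
    loops_rep2: List[LoopRecord]
    genes: List[GeneRecord]
    expression: List[ExpressionRecord]
    peak_replicates: List[List[PeakRecord]]
    truth_peaks: List[PeakRecord]  # intended consensus peaks
    repeats: List[RepeatRecord]
    eqtls: List[EqtlRecord]
    highres: List[LoopRecord]
    truth: GroundTruth

    def write(self, outdir) -> Dict[str, str]:
        """Write every table in the dialect the readers expect; returns a
        manifest (also saved as ``manifest.json`` with file hashes)."""
        from . import io as lio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        lio.write_loops(self.loops, outdir / "loops_rep1.tsv")
        paths["loops_rep1"] = "loops_rep1.tsv"
        lio.write_loops(self.loops_rep2, outdir / "loops_rep2.tsv")
        paths["loops_rep2"] = "loops_rep2.tsv"
        lio.write_domains(self.domains, outdir / "domains.tsv")
        paths["domains"] = "domains.tsv"
        lio.write_gene_models(self.genes, outdir / "genes.gff3")
        paths["genes"] = "genes.gff3"
        lio.write_expression(self.expression, outdir / "expression.tsv")
        paths["expression"] = "expression.tsv"
        for r, peaks in enumerate(self.peak_replicates, start=1):
            lio.write_peaks(peaks, outdir / f"peaks_rep{r}.tsv")
            paths[f"peaks_rep{r}"] = f"peaks_rep{r}.tsv"
        lio.write_repeats(self.repeats, outdir / "repeats.tsv")
        paths["repeats"] = "repeats.tsv"
        lio.write_eqtls(self.eqtls, outdir / "eqtls.tsv")
        paths["eqtls"] = "eqtls.tsv"
        lio.write_loops(self.highres, outdir / "highres.tsv")
        paths["highres"] = "highres.tsv"
        with open(outdir / "truth.json", "w") as fh:
            json.dump(asdict(self.truth), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["truth"] = "truth.json"
        manifest = {
            "seed": self.config.seed,
            "config": _jsonable(asdict(self.config)),
            "files": {
                key: {
                    "path": rel,
                    "sha256": hashlib.sha256((outdir / rel).read_bytes()).hexdigest(),
                }
                for key, rel in paths.items()
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


class _TailAllocator:
    """Hands out disjoint segments from the reserved tail of each chromosome."""

    def __init__(self, cursors: Dict[str, int], limits: Dict[str, int]):
        self.cursors = dict(cursors)
        self.limits = dict(limits)

    def take(self, chrom: str, length: int, margin: int = 1_000) -> Tuple[int, int]:
        start = self.cursors[chrom] + margin
        end = start + length
        if end > self.limits[chrom]:
            raise ValueError(
                f"infeasible config: chromosome {chrom} tail exhausted "
                f"(need {length} bp past {start})"
            )
        self.cursors[chrom] = end
        return start, end

    def any_chrom(self, rng: np.random.Generator, length: int) -> Tuple[str, int, int]:
        chroms = sorted(
            c for c in self.cursors if self.limits[c] - self.cursors[c] > length + 2_000
        )
        if not chroms:
            raise ValueError("infeasible config: all chromosome tails exhausted")
        chrom = chroms[int(rng.integers(len(chroms)))]
        s, e = self.take(chrom, length)
        return chrom, s, e


@dataclass
class _Node:
    chrom: str
    start: int
    end: int
    level: int
    root: int  # index of the level-0 ancestor in the node list
    parent: Optional[int]

    @property
    def length(self) -> int:
        return self.end - self.start


def _build_domains(cfg: SynthConfig, rng: np.random.Generator) -> Tuple[List[_Node], Dict[str, int]]:
    """Place level-0 domains sequentially per chromosome and nest sub-domains.

    Returns the node list and the tail start per chromosome (domains occupy
    the head of the chromosome; the tail is reserved for outside placements).
    """
    nodes: List[_Node] = []
    tail_start: Dict[str, int] = {}
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        pos = int(rng.integers(10_000, 60_000))
        n_placed = 0
        root_budget = int(0.82 * size)
        while n_placed < cfg.n_level0_domains:
            length = int(rng.integers(600_000, 1_100_000))
            if pos + length > root_budget:
                break
            root_idx = len(nodes)
            nodes.append(_Node(chrom, pos, pos + length, 0, root_idx, None))
            _nest(cfg, rng, nodes, root_idx)
            pos += length + int(rng.integers(30_000, 80_000))
            n_placed += 1
        if n_placed < 4:
            raise ValueError(
                f"infeasible config: chromosome {chrom} fits only {n_placed} level-0 domains"
            )
        tail_start[chrom] = pos + 20_000
    return nodes, tail_start


def _nest(cfg: SynthConfig, rng: np.random.Generator, nodes: List[_Node], parent_idx: int) -> None:
    parent = nodes[parent_idx]
    if parent.level >= cfg.nesting_depth:
        return
    branch = cfg.nesting_branch
    inner_start = parent.start + _CHILD_MARGIN
    inner_end = parent.end - _CHILD_MARGIN
    gap = _CHILD_MARGIN
    usable = inner_end - inner_start - (branch - 1) * gap
    if usable < branch * 60_000:
        return
    base = usable // branch
    pos = inner_start
    for _b in range(branch):
        length = int(base * (0.85 + 0.3 * rng.random()))
        length = min(length, inner_end - pos)
        if length < 60_000:
            break
        child_idx = len(nodes)
        nodes.append(
            _Node(parent.chrom, pos, pos + length, parent.level + 1, parent.root, parent_idx)
        )
        _nest(cfg, rng, nodes, child_idx)
        pos += length + gap


def _subtree(nodes: List[_Node], idx: int) -> List[int]:
    out = [idx]
    for j, n in enumerate(nodes):
        if n.parent is not None:
            k = j
            while nodes[k].parent is not None:
                k = nodes[k].parent
                if k == idx:
                    out.append(j)
                    break
    return out


def _chain(nodes: List[_Node], idx: int) -> List[int]:
    """Node plus its ancestors and descendants (the exclusion set for placement)."""
    blocked = set(_subtree(nodes, idx))
    k = idx
    while nodes[k].parent is not None:
        k = nodes[k].parent
        blocked.add(k)
    return sorted(blocked)


def _place_in_domain_loop(
    cfg: SynthConfig, rng: np.random.Generator, node: _Node, loop_id: str
) -> Tuple[LoopRecord, str]:
    """Place one loop inside a domain node; returns the loop and its category."""
    amin, amax = cfg.anchor_len_range
    cap = (node.length - 44_000) // 2
    a1len = int(rng.integers(amin, min(amax, cap) + 1))
    a2len = int(rng.integers(amin, min(amax, cap) + 1))
    b1 = rng.random() < cfg.p_anchor_at_boundary
    b2 = rng.random() < cfg.p_anchor_at_boundary
    g1 = int(rng.integers(*_BOUNDARY_GAP)) if b1 else int(rng.integers(*_EMBED_GAP))
    g2 = int(rng.integers(*_BOUNDARY_GAP)) if b2 else int(rng.integers(*_EMBED_GAP))
    x1 = node.start + g1
    x2 = x1 + a1len
    y2 = node.end - g2
    y1 = y2 - a2len
    category = ("embedded", "one_colocated_anchor", "two_colocated_anchors")[int(b1) + int(b2)]
    return LoopRecord.make(node.chrom, x1, x2, y1, y2, loop_id), category


def _segments_minus(
    segments: List[Tuple[int, int]], holes: List[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """Subtract merged *holes* from merged *segments* (all on one chromosome)."""
    out = []
    hi = 0
    for s, e in segments:
        cur = s
        for hs, he in holes:
            if he <= cur:
                continue
            if hs >= e:
                break
            if hs > cur:
                out.append((cur, min(hs, e)))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


class _ZonePartition:
    """Anchor / interior / outside segments of the rep-1 loop geometry."""

    def __init__(self, loops: Sequence[LoopRecord], chrom_sizes: Dict[str, int]):
        anchors: Dict[str, list] = {c: [] for c in chrom_sizes}
        interiors: Dict[str, list] = {c: [] for c in chrom_sizes}
        spans: Dict[str, list] = {c: [] for c in chrom_sizes}
        for lp in loops:
            anchors[lp.chrom].append((lp.anchor1.start, lp.anchor1.end))
            anchors[lp.chrom].append((lp.anchor2.start, lp.anchor2.end))
            if lp.interior is not None:
                interiors[lp.chrom].append((lp.interior.start, lp.interior.end))
            spans[lp.chrom].append((lp.span.start, lp.span.end))
        self.anchor: Dict[str, list] = {}
        self.interior: Dict[str, list] = {}
        self.outside: Dict[str, list] = {}
        for c, size in chrom_sizes.items():
            a = merge_intervals(anchors[c])
            i = _segments_minus(merge_intervals(interiors[c]), a)
            self.anchor[c] = a
            self.interior[c] = i
            self.outside[c] = _segments_minus([(0, size)], merge_intervals(spans[c]))

    def zone_of(self, iv: GenomicInterval) -> str:
        """Zone by the same anchor > interior > outside priority, via a plain
        linear scan (independent of the interval-tree code path)."""
        for s, e in self.anchor.get(iv.chrom, []):
            if min(e, iv.end) - max(s, iv.start) >= 1:
                return "anchor"
        for s, e in self.interior.get(iv.chrom, []):
            if min(e, iv.end) - max(s, iv.start) >= 1:
                return "interior"
        return "outside"

    def segments(self, zone: str) -> List[Tuple[str, int, int]]:
        source = {"anchor": self.anchor, "interior": self.interior, "outside": self.outside}[zone]
        return [(c, s, e) for c in sorted(source) for s, e in source[c]]


def _weighted_segment_position(
    rng: np.random.Generator,
    segments: List[Tuple[str, int, int]],
    length: int,
    occupied: Dict[str, List[Tuple[int, int]]],
    min_sep: int,
    max_tries: int = 60,
) -> Optional[Tuple[str, int, int]]:
    usable = [(c, s, e) for c, s, e in segments if e - s > length + 2]
    if not usable:
        return None
    weights = np.array([e - s - length for _c, s, e in usable], dtype=float)
    weights /= weights.sum()
    for _try in range(max_tries):
        k = int(rng.choice(len(usable), p=weights))
        c, s, e = usable[k]
        start = int(rng.integers(s + 1, e - length))
        end = start + length
        clash = any(
            start - min_sep < oe and os < end + min_sep
            for os, oe in occupied.get(c, [])
        )
        if not clash:
            occupied.setdefault(c, []).append((start, end))
            return c, start, end
    return None


def generate(config: SynthConfig) -> SynthBundle:
    """Generate the full input bundle with ground truth; deterministic in seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    nodes, tail_start = _build_domains(cfg, rng)
    domains = sorted(
        (DomainRecord(GenomicInterval(n.chrom, n.start, n.end), n.level) for n in nodes),
        key=lambda d: (d.span.chrom, d.span.start, d.span.end),
    )
    tail = _TailAllocator(tail_start, {c: s - 5_000 for c, s in cfg.chrom_sizes.items()})

    # ---- replicate-1 loops ------------------------------------------------
    loops: List[LoopRecord] = []
    blocked: set = set()
    categories = rng.choice(
        ["inter", "outside", "indomain"],
        size=cfg.n_loops,
        p=[
            cfg.p_loop_inter_domain,
            cfg.p_loop_outside,
            1 - cfg.p_loop_inter_domain - cfg.p_loop_outside,
        ],
    )
    # inter-domain first: they consume whole adjacent root pairs
    roots_by_chrom: Dict[str, List[int]] = {}
    for i, n in enumerate(nodes):
        if n.level == 0:
            roots_by_chrom.setdefault(n.chrom, []).append(i)

    def new_id() -> str:
        return f"L{len(loops) + 1}"

    n_inter = int(np.sum(categories == "inter"))
    amin, amax = cfg.anchor_len_range
    for _k in range(n_inter):
        placed = False
        for _try in range(200):
            chrom = sorted(cfg.chrom_sizes)[int(rng.integers(len(cfg.chrom_sizes)))]
            ridx = roots_by_chrom.get(chrom, [])
            if len(ridx) < 2:
                continue
            j = int(rng.integers(len(ridx) - 1))
            r1, r2 = ridx[j], ridx[j + 1]
            if blocked & set(_subtree(nodes, r1)) or blocked & set(_subtree(nodes, r2)):
                continue
            d1, d2 = nodes[r1], nodes[r2]
            a1len = int(rng.integers(amin, amax + 1))
            a2len = int(rng.integers(amin, amax + 1))
            x1 = int(rng.integers(d1.start + 1_000, d1.end - a1len - 1_000))
            y1 = int(rng.integers(d2.start + 1_000, d2.end - a2len - 1_000))
            lp = LoopRecord.make(chrom, x1, x1 + a1len, y1, y1 + a2len, new_id())
            loops.append(lp)
            truth.loop_domain_category[lp.loop_id] = "inter_domain"
            truth.loop_domain_level[lp.loop_id] = None
            blocked.update(_subtree(nodes, r1))
            blocked.update(_subtree(nodes, r2))
            placed = True
            break
        if not placed:
            raise ValueError("infeasible config: no adjacent free level-0 domain pair")

    for cat in categories:
        if cat == "inter":
            continue  # placed above
        if cat == "outside":
            a1len = int(rng.integers(amin, amax + 1))
            a2len = int(rng.integers(amin, amax + 1))
            interior_len = int(rng.integers(30_000, 90_000))
            chrom, s, _e = tail.any_chrom(rng, a1len + a2len + interior_len)
            lp = LoopRecord.make(
                chrom, s, s + a1len, s + a1len + interior_len, s + a1len + interior_len + a2len, new_id()
            )
            loops.append(lp)
            truth.loop_domain_category[lp.loop_id] = "no_overlap"
            truth.loop_domain_level[lp.loop_id] = None
            continue
        # in-domain: draw a target level, fall back deeper then shallower
        want = int(rng.choice(len(cfg.level_weights), p=np.array(cfg.level_weights) / sum(cfg.level_weights)))
        node_idx = None
        for level in [want] + [l for l in range(cfg.nesting_depth, -1, -1) if l != want]:
            eligible = [
                i
                for i, n in enumerate(nodes)
                if n.level == level and i not in blocked and n.length >= 54_000
            ]
            if eligible:
                node_idx = eligible[int(rng.integers(len(eligible)))]
                break
        if node_idx is None:
            raise ValueError("infeasible config: domain tree exhausted for loop placement")
        lp, category = _place_in_domain_loop(cfg, rng, nodes[node_idx], new_id())
        loops.append(lp)
        truth.loop_domain_category[lp.loop_id] = category
        truth.loop_domain_level[lp.loop_id] = nodes[node_idx].level
        blocked.update(_chain(nodes, node_idx))

    # optional shared-anchor siblings (exercise prioritization; no domain truth)
    n_shared = int(round(cfg.p_shared_anchor * len(loops)))
    for k in range(n_shared):
        base = loops[int(rng.integers(len(loops)))]
        a2len = int(rng.integers(amin, amax + 1))
        y1 = base.anchor2.end + int(rng.integers(5_000, 20_000))
        if y1 + a2len >= cfg.chrom_sizes[base.chrom]:
            continue
        lp = LoopRecord.make(
            base.chrom, base.anchor1.start, base.anchor1.end, y1, y1 + a2len, new_id()
        )
        loops.append(lp)
        truth.loop_domain_category[lp.loop_id] = None
        truth.loop_domain_level[lp.loop_id] = None

    partition = _ZonePartition(loops, cfg.chrom_sizes)
    # keep genes (and the peaks attached to them) out of the reserved tail,
    # which later hands out segments for noise peaks and relocated anchors
    for c, ts in tail_start.items():
        partition.outside[c] = _segments_minus(
            partition.outside[c], [(max(0, ts - 20_000), cfg.chrom_sizes[c])]
        )

    # ---- genes & expression ----------------------------------------------
    genome_mb = sum(cfg.chrom_sizes.values()) / 1e6
    n_genes = int(round(cfg.gene_density * genome_mb))
    zone_names = sorted(cfg.gene_zone_weights)
    zone_p = np.array([cfg.gene_zone_weights[z] for z in zone_names])
    zone_p = zone_p / zone_p.sum()
    occupied_genes: Dict[str, List[Tuple[int, int]]] = {}
    genes: List[GeneRecord] = []
    for gi in range(n_genes):
        zone = (
            zone_names[int(rng.choice(len(zone_names), p=zone_p))]
            if loops
            else "outside"
        )
        length = int(rng.integers(*cfg.gene_len_range))
        spot = _weighted_segment_position(
            rng, partition.segments(zone), length, occupied_genes, min_sep=200
        )
        if spot is None:
            continue  # zone space saturated; realized density is the truth
        chrom, start, end = spot
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{len(genes) + 1:05d}"
        genes.append(GeneRecord(StrandedInterval(chrom, start, end, strand), gid, "gene"))
        truth.gene_zone[gid] = zone
    genes_by_id = {g.gene_id: g for g in genes}

    expression: List[ExpressionRecord] = []
    n_rep = 4
    for i, g in enumerate(genes):
        if i < cfg.n_boundary_tpm_genes:
            tpms = tuple([1.0] * n_rep)
        elif rng.random() < cfg.p_expressed:
            mean = 10.0 ** rng.uniform(*cfg.tpm_log10_range)
            tpms = tuple(float(max(0.0, mean * np.exp(rng.normal(0, 0.2)))) for _ in range(n_rep))
        elif rng.random() < 0.5:
            tpms = tuple([0.0] * n_rep)
        else:
            mean = 10.0 ** rng.uniform(-2.0, -0.1)
            tpms = tuple(float(max(0.0, mean * np.exp(rng.normal(0, 0.2)))) for _ in range(n_rep))
        m = sum(tpms) / n_rep
        expressed = m >= 1.0
        expression.append(ExpressionRecord(g.gene_id, tpms, m, expressed))
        truth.gene_expressed[g.gene_id] = expressed

    # ---- peaks ------------------------------------------------------------
    # hosts: genes with >= 12 kb clearance so the intended gene stays nearest
    clearance = 12_000
    by_chrom_genes: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.span.chrom, []).append(g)
    for gl in by_chrom_genes.values():
        gl.sort(key=lambda g: g.span.start)
    hosts = []
    for chrom, gl in sorted(by_chrom_genes.items()):
        for i, g in enumerate(gl):
            left_ok = i == 0 or g.span.start - gl[i - 1].span.end >= clearance
            right_ok = i == len(gl) - 1 or gl[i + 1].span.start - g.span.end >= clearance
            if left_ok and right_ok:
                hosts.append(g)
    if len(hosts) < cfg.n_peaks:
        raise ValueError(
            f"infeasible config: only {len(hosts)} isolated genes for {cfg.n_peaks} peaks"
        )
    host_idx = rng.choice(len(hosts), size=cfg.n_peaks, replace=False)
    place_names = sorted(cfg.peak_placement)
    place_p = np.array([cfg.peak_placement[k] for k in place_names])
    place_p = place_p / place_p.sum()
    truth_peaks: List[PeakRecord] = []
    for k, hi in enumerate(sorted(host_idx)):
        g = hosts[hi]
        plen = int(rng.integers(*cfg.peak_len_range))
        mode = place_names[int(rng.choice(len(place_names), p=place_p))]
        if mode == "gene_overlap":
            start = int(rng.integers(g.span.start, max(g.span.start + 1, g.span.end - plen)))
        else:
            gap = (
                int(rng.integers(1, 2_000 - plen))
                if mode == "lt2kb"
                else int(rng.integers(2_500, 4_500))
            )
            if rng.random() < 0.5:
                start = g.span.end + gap
            else:
                start = g.span.start - gap - plen
        start = max(0, start)
        pid = f"C{k + 1}"
        peak = PeakRecord(GenomicInterval(g.span.chrom, start, start + plen), pid)
        truth_peaks.append(peak)
        truth.peak_gene_class[pid] = {
            "gene_overlap": "overlap",
            "lt2kb": "lt2kb",
            "gt2kb": "farther_2kb",
        }[mode]
        truth.peak_host_gene[pid] = g.gene_id
        truth.peak_zone[pid] = partition.zone_of(peak.span)

    peak_replicates: List[List[PeakRecord]] = [[] for _ in range(cfg.n_peak_replicates)]
    for peak in truth_peaks:
        present = rng.random(cfg.n_peak_replicates) < cfg.p_peak_in_replicate
        truth.peak_support[peak.peak_id] = int(present.sum())
        for r in range(cfg.n_peak_replicates):
            if present[r]:
                j1 = int(rng.integers(0, 31))
                j2 = int(rng.integers(0, 31))
                peak_replicates[r].append(
                    PeakRecord(
                        GenomicInterval(
                            peak.span.chrom,
                            max(0, peak.span.start - j1),
                            peak.span.end + j2,
                        ),
                        f"{peak.peak_id}_r{r + 1}",
                        str(r + 1),
                    )
                )
    for r in range(cfg.n_peak_replicates):
        for k in range(cfg.n_noise_peaks):
            plen = int(rng.integers(*cfg.peak_len_range))
            chrom, s, _e = tail.any_chrom(rng, plen)
            peak_replicates[r].append(
                PeakRecord(GenomicInterval(chrom, s, s + plen), f"N{r + 1}_{k + 1}", str(r + 1))
            )
        peak_replicates[r].sort(key=lambda p: (p.span.chrom, p.span.start))

    # ---- repeats ----------------------------------------------------------
    repeats: List[RepeatRecord] = []
    tile = cfg.repeat_tile

    def tile_segments(segs: List[Tuple[str, int, int]], rate: float) -> None:
        if rate <= 0:
            return
        for chrom, s, e in segs:
            n_t = (e - s + tile - 1) // tile
            keep = rng.random(n_t) < rate
            for k in np.flatnonzero(keep):
                ts = s + int(k) * tile
                repeats.append(
                    RepeatRecord(GenomicInterval(chrom, ts, min(ts + tile, e)))
                )

    tile_segments(partition.segments("anchor"), cfg.repeat_rate_anchor)
    tile_segments(partition.segments("interior"), cfg.repeat_rate_interior)
    tile_segments(partition.segments("outside"), cfg.repeat_rate_background)
    repeats.sort(key=lambda r: (r.span.chrom, r.span.start))
    repeats = [
        RepeatRecord(r.span, f"R{i + 1}") for i, r in enumerate(repeats)
    ]

    # ---- eQTLs ------------------------------------------------------------
    anchor_genes: Dict[str, List[str]] = {}  # anchor key -> contained gene ids
    loop_anchor_genes: List[Tuple[LoopRecord, int, str]] = []  # (loop, gene slot, gene id)
    for lp in loops:
        for slot, anchor in ((1, lp.anchor1), (2, lp.anchor2)):
            for g in by_chrom_genes.get(lp.chrom, []):
                if anchor.contains(g.span):
                    key = f"{anchor.chrom}:{anchor.start}-{anchor.end}"
                    anchor_genes.setdefault(key, []).append(g.gene_id)
                    loop_anchor_genes.append((lp, slot, g.gene_id))
    if cfg.n_eqtl and loops and not loop_anchor_genes:
        raise ValueError("infeasible config: no genes contained in anchors for eQTL placement")
    eqtls: List[EqtlRecord] = []
    eq_classes = rng.choice(
        ["same", "cross", "other"],
        size=cfg.n_eqtl,
        p=[
            cfg.p_eqtl_same_anchor,
            cfg.p_eqtl_cross_anchor,
            1 - cfg.p_eqtl_same_anchor - cfg.p_eqtl_cross_anchor,
        ],
    )
    for qi, qcls in enumerate(eq_classes):
        qid = f"Q{qi + 1}"
        if not loops:
            qcls = "other"  # no anchors exist; every eQTL is unco-located
        if qcls == "same":
            lp, slot, gid = loop_anchor_genes[int(rng.integers(len(loop_anchor_genes)))]
            anchor = lp.anchor1 if slot == 1 else lp.anchor2
            pos = int(rng.integers(anchor.start, anchor.end))
            chrom = anchor.chrom
        elif qcls == "cross":
            lp, slot, gid = loop_anchor_genes[int(rng.integers(len(loop_anchor_genes)))]
            other = lp.anchor2 if slot == 1 else lp.anchor1
            pos = int(rng.integers(other.start, other.end))
            chrom = other.chrom
        else:
            gid = genes[int(rng.integers(len(genes)))].gene_id
            chrom, s, e = tail.any_chrom(rng, 1_000)
            pos = (s + e) // 2
        half = int(rng.integers(5_000, 50_000))
        region = GenomicInterval(chrom, max(0, pos - half), pos + half)
        eqtls.append(
            EqtlRecord(region, GenomicInterval(chrom, pos, pos + 1), gid, eqtl_id=qid)
        )
        truth.eqtl_class[qid] = {
            "same": "same_anchor",
            "cross": "cross_anchor_same_loop",
            "other": "other",
        }[qcls]

    # ---- high-resolution interactions -------------------------------------
    hmin, hmax = cfg.highres_anchor_len_range
    highres: List[LoopRecord] = []
    hr_classes = rng.choice(
        [2, 1, 0],
        size=cfg.n_highres,
        p=[cfg.p_highres_two, cfg.p_highres_one, 1 - cfg.p_highres_two - cfg.p_highres_one],
    )
    with_interior = [lp for lp in loops if lp.interior is not None and lp.interior.length > 2 * hmax + 8_000]

    def inside(iv: GenomicInterval, length: int, lo_margin: int = 100) -> Tuple[int, int]:
        s = int(rng.integers(iv.start + lo_margin, iv.end - lo_margin - length))
        return s, s + length

    for hi_, cls in enumerate(hr_classes):
        hid = f"H{len(highres) + 1}"
        l1 = int(rng.integers(hmin, hmax + 1))
        l2 = int(rng.integers(hmin, hmax + 1))
        if not loops:
            cls = 0  # no Hi-C anchors to co-locate with
        if cls == 2:
            lp = loops[int(rng.integers(len(loops)))]
            s1, e1 = inside(lp.anchor1, l1, 0)
            s2, e2 = inside(lp.anchor2, l2, 0)
            zone_pair = "anchor_to_anchor"
        elif cls == 1:
            lp = with_interior[int(rng.integers(len(with_interior)))]
            s1, e1 = inside(lp.anchor1, l1, 0)
            s2, e2 = inside(lp.interior, l2)
            zone_pair = "anchor_to_interior"
        elif rng.random() < 0.5 and with_interior:
            lp = with_interior[int(rng.integers(len(with_interior)))]
            interior = lp.interior
            mid = interior.midpoint
            s1, e1 = inside(GenomicInterval(interior.chrom, interior.start, mid), l1)
            s2, e2 = inside(GenomicInterval(interior.chrom, mid, interior.end), l2)
            zone_pair = "interior_to_interior"
        else:
            chrom, s1, e1 = tail.any_chrom(rng, l1)
            s2, e2 = tail.take(chrom, l2)
            lp = None
            zone_pair = "unmapped"
        chrom = lp.chrom if lp is not None else chrom
        hr = LoopRecord.make(chrom, s1, e1, s2, e2, hid)
        highres.append(hr)
        truth.highres_shared[hid] = int(cls)
        truth.highres_zone_pair[hid] = zone_pair

    # ---- replicate-2 loops -------------------------------------------------
    loops_rep2: List[LoopRecord] = []
    r2_classes = rng.choice(
        [2, 1, 0],
        size=len(loops),
        p=[
            cfg.p_rep2_both_anchors,
            cfg.p_rep2_one_anchor,
            1 - cfg.p_rep2_both_anchors - cfg.p_rep2_one_anchor,
        ],
    )

    def jitter(anchor: GenomicInterval) -> Tuple[int, int]:
        d = int(rng.integers(-FLANK_BP, FLANK_BP + 1))
        s = max(0, anchor.start + d)
        return s, s + anchor.length

    for lp, cls in zip(loops, r2_classes):
        rid = f"L{len(loops_rep2) + 1}"
        if cls == 2:
            s1, e1 = jitter(lp.anchor1)
            s2, e2 = jitter(lp.anchor2)
        elif cls == 1:
            s1, e1 = jitter(lp.anchor1)
            alen = int(rng.integers(amin, amax + 1))
            s2, e2 = tail.take(lp.chrom, alen)
        else:
            alen1 = int(rng.integers(amin, amax + 1))
            alen2 = int(rng.integers(amin, amax + 1))
            chrom, s1, e1 = tail.any_chrom(rng, alen1)
            s2, e2 = tail.take(chrom, alen2)
        chrom2 = lp.chrom if cls in (1, 2) else chrom
        r2 = LoopRecord.make(chrom2, s1, e1, s2, e2, rid)
        loops_rep2.append(r2)
        truth.rep2_shared[rid] = int(cls)

    truth.config_rates = {
        "p_anchor_at_boundary": cfg.p_anchor_at_boundary,
        "p_expressed": cfg.p_expressed,
        "repeat_rate_anchor": cfg.repeat_rate_anchor,
        "repeat_rate_interior": cfg.repeat_rate_interior,
        "p_eqtl_same_anchor": cfg.p_eqtl_same_anchor,
        "p_eqtl_cross_anchor": cfg.p_eqtl_cross_anchor,
    }
    return SynthBundle(
        config=cfg,
        domains=domains,
        loops=loops,
        loops_rep2=loops_rep2,
        genes=genes,
        expression=expression,
        peak_replicates=peak_replicates,
        truth_peaks=truth_peaks,
        repeats=repeats,
        eqtls=eqtls,
        highres=highres,
        truth=truth,
    )


def binomial_tolerance(p: float, n: int, k: float = 3.0) -> float:
    """k-sigma binomial half-width for a rate estimated from n trials."""
    if n <= 0:
        return 0.0
    return k * float(np.sqrt(p * (1 - p) / n))


def truth_report(bundle: SynthBundle, pipeline_outputs: dict) -> "pd.DataFrame":
    """Compare configured/intended quantities against pipeline-recovered ones.

    ``pipeline_outputs`` is the dict produced by
    :func:`loopcoloc.pipeline.analyze_bundle` on the same bundle (seed
    mismatch is fatal). Each row carries the deviation and a pass flag at a
    3-sigma binomial tolerance (exact-match rows use tolerance 0).
    """
    import pandas as pd

    if pipeline_outputs.get("seed") != bundle.config.seed:
        raise ValueError(
            f"seed mismatch: bundle {bundle.config.seed} vs outputs {pipeline_outputs.get('seed')}"
        )
    truth = bundle.truth
    rows = []

    def add(stage, quantity, expected, recovered, tol):
        rows.append(
            {
                "stage": stage,
                "quantity": quantity,
                "expected": expected,
                "recovered": recovered,
                "deviation": abs(recovered - expected),
                "tolerance": tol,
                "passed": abs(recovered - expected) <= tol,
            }
        )

    # zone assignment: exact recovery under non-overlapping placements
    for kind, zones_key, truth_map in (
        ("gene_zones", "gene_zones", truth.gene_zone),
        ("peak_zones", "peak_zones", truth.peak_zone),
    ):
        recovered = pipeline_outputs[zones_key]
        mism = sum(1 for fid, z in truth_map.items() if recovered.get(fid) != z)
        add("assign", f"{kind}_mismatches", 0, mism, 0)

    # domain classification: exact per labeled loop
    dom = {c.loop_id: c for c in pipeline_outputs["domain_classes"]}
    labeled = [lid for lid, cat in truth.loop_domain_category.items() if cat is not None]
    mism = sum(1 for lid in labeled if dom[lid].category != truth.loop_domain_category[lid])
    add("domains", "category_mismatches", 0, mism, 0)
    mism = sum(
        1
        for lid in labeled
        if truth.loop_domain_level[lid] is not None
        and dom[lid].level != truth.loop_domain_level[lid]
    )
    add("domains", "level_mismatches", 0, mism, 0)
    # embedded rate among in-domain loops vs configured (1 - p)^2
    in_dom = [
        lid
        for lid in labeled
        if truth.loop_domain_category[lid]
        in ("embedded", "one_colocated_anchor", "two_colocated_anchors")
    ]
    if in_dom:
        p_emb = (1 - bundle.config.p_anchor_at_boundary) ** 2
        rec = sum(1 for lid in in_dom if dom[lid].category == "embedded") / len(in_dom)
        add("domains", "embedded_rate", p_emb, rec, binomial_tolerance(p_emb, len(in_dom)))

    # eQTL classes
    eq = {c.eqtl_id: c.category for c in pipeline_outputs["eqtl_classes"]}
    mism = sum(1 for qid, cat in truth.eqtl_class.items() if eq[qid] != cat)
    add("eqtl", "class_mismatches", 0, mism, 0)
    n_q = len(truth.eqtl_class)
    if n_q:
        rec = sum(1 for c in eq.values() if c == "same_anchor") / n_q
        p0 = bundle.config.p_eqtl_same_anchor
        add("eqtl", "same_anchor_rate", p0, rec, binomial_tolerance(p0, n_q))

    # repeat densities: mean fractions vs configured tile rates
    ds = pipeline_outputs["density_summary"]
    tile = bundle.config.repeat_tile
    for key, rate, attr in (
        ("mean_anchor_fraction", bundle.config.repeat_rate_anchor, "anchor"),
        ("mean_interior_fraction", bundle.config.repeat_rate_interior, "interior"),
    ):
        tiles = []
        for lp in bundle.loops:
            if lp.interior is None:
                continue
            ln = (
                lp.anchor1.length + lp.anchor2.length
                if attr == "anchor"
                else lp.interior.length
            )
            tiles.append(max(1, ln // tile))
        n = len(tiles)
        tol = 3.0 / n * float(np.sqrt(sum(rate * (1 - rate) / t for t in tiles)))
        add("repeats", key, rate, ds[key], tol)

    # replicate sharing and high-resolution co-location: exact per loop
    r2 = {c.loop_id: c.n_shared for c in pipeline_outputs["rep2_shared"]}
    mism = sum(1 for lid, n in truth.rep2_shared.items() if r2[lid] != n)
    add("pairloops", "shared_class_mismatches", 0, mism, 0)
    hr = {c.loop_id: c.n_shared for c in pipeline_outputs["highres_classes"]}
    mism = sum(1 for hid, n in truth.highres_shared.items() if hr[hid] != n)
    add("highres", "shared_class_mismatches", 0, mism, 0)

    # consensus peaks: count of support >= 2 components
    expected = sum(1 for s in truth.peak_support.values() if s >= 2)
    add("consensus", "n_consensus_peaks", expected, len(pipeline_outputs["consensus"]), 0)

    return pd.DataFrame(rows)
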