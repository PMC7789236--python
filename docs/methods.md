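# Methods

## Coordinates and interval semantics

Every record is reduced to 0-based, half-open `[start, end)` spans on
string-labelled chromosomes (`Chr`/`chr` prefixes are stripped so labels
match across files). Loop and domain tables are taken as already half-open —
they derive from binned contact-matrix callers (HICCUPS-style loops,
HiTAD-style domains) that emit BED-convention bins — so no ±1 adjustment is
applied on read. GFF3 gene models are converted from 1-based inclusive on
read and restored on write. If a coordinate dialect ever mismatches at bin
boundaries, the conversion lives in one place (`loopcoloc.io`) and the
round-trip tests pin the current choice.

Three primitives carry the whole analysis, matching bedtools behaviour:

* `overlap_length(a, b)` — shared base count; "overlap" anywhere in the
  package means `overlap_length >= min_overlap_bp` with `min_overlap_bp = 1`
  by default. The source material mixes "> 1 bp" and "at least 1 bp"
  phrasings for the same operations; we read both as ≥ 1 bp and expose the
  threshold as configuration.
* `coverage_fraction(target, features)` — fraction of target positions under
  ≥ 1 feature. Union semantics: nested/overlapping annotations never count a
  position twice (this is how `bedtools coverage` counts covered bases).
* `closest_feature(query, candidates)` — minimises the absolute signed gap;
  distance 0 exactly when the intervals share a base; negative = candidate
  left of the query. Bookended intervals (gap 0, no shared base) are
  reported at ±1 so that distance 0 always means true overlap; `bedtools
  closest -d` prints gap+1 for all non-overlapping pairs (1-based inclusive
  endpoints), so the two agree to within 1 bp off-overlap — the test suite
  cross-checks against the bedtools binary at exactly this relationship.
  Ties on |distance| break by leftmost candidate start, then identifier, so
  output is deterministic.

## Classification rules

**Zone assignment.** Many loops share one anchor, so a feature can touch an
anchor of one loop and the interior of another. Every feature is assigned
the highest-priority zone it overlaps across the whole loop set: anchor >
interior > outside. Zone counts therefore always partition the feature set.

**Replicate loop sharing.** Loop A shares *both* anchors with loop B when
A.anchor1 overlaps B.anchor1 and A.anchor2 overlaps B.anchor2 after
left-to-right ordering — no cross-matching, since both anchors stand
left-to-right on one chromosome. Counting is done in the query set's frame
(each query loop once, priority 2 > 1 > 0), and a single partner loop must
supply both matches for class 2.

**High-resolution co-location.** The ≥ 50% criterion is computed relative to
the *query* (high-resolution) anchor's length by default: Hi-C anchors are
5–25 kb bins while ChIA-PET/HiChIP anchors are typically far smaller, so a
small anchor inside a bin counts while a bin can never cover 50% of itself
inside a small anchor. `frac_of` may be set to `subject` or `either` for
sensitivity analysis, and `require_same_loop=False` relaxes class 2 to
independent per-anchor matches. Interaction zone mapping (anchor-to-anchor,
anchor-to-interior, interior-to-interior, unmapped) derives each anchor's
zone with the same priority rule; an anchor outside all loop regions makes
the interaction unmapped.

**Loop vs domain hierarchy.** The hierarchy links each level-k>0 domain to
every lower-level domain containing it (immediate parents preferred);
orphans are flagged, never dropped. A loop is attributed to the *deepest*
domain fully containing its span — per-level counts are therefore disjoint,
which is the only reading under which the per-level tables can sum to an
"overlapping" total. Within the attributed domain, an anchor is
boundary-co-located when it intersects `[b − 2000, b + 2000)` around either
edge (`boundary_rule="min_overlap_2kb"` switches to requiring ≥ 2 kb of
window overlap); two co-located anchors beat one beat embedded. Loops
contained in no domain are *inter-domain* when their anchor midpoints fall
in two distinct level-0 domains, else *no-overlap* (this bucket also absorbs
the rare loop that overlaps a domain without being contained in any; the
classes still partition the loop set). When two same-level sibling domains
both contain a span (overlapping domain calls), the first by coordinate
wins — deterministic, and unobservable with non-overlapping siblings.

**Expression and consensus peaks.** A gene is expressed when the arithmetic
mean of its four replicate TPMs is ≥ 1 — the boundary is inclusive, and the
generator plants mean-exactly-1.0 genes to pin that. Consensus peaks are
connected components of cross-replicate pairwise overlap; a component
supported by ≥ 2 distinct replicates is emitted as the union interval of its
members (the source does not state the consensus coordinate rule; the union
is the only choice under which consensus peaks can never overlap each
other). Supplying fewer replicates than `min_support` yields an empty set
rather than an error.

**Peak–gene proximity.** Distance comes from the gene's frame; the gene's
strand converts left/right into 5′/3′: right of a `+` gene is downstream,
right of a `−` gene is upstream. |distance| = 2000 exactly counts as the
"< 2 kb" class (the source mixes "<2Kbps" and "2Kbps away"; inclusive is
deterministic and the cut is configurable).

**eQTL co-location.** The expression trait is located by the associated
gene's full span (no point location is defined in the source; a TSS option
exists). Classification works in distinct-anchor space — an eQTL whose SNP
and gene share an anchor used by many loops counts once — with priority
same-anchor > cross-anchor-within-one-loop > other. Unique SNPs are
deduplicated by exact position; a SNP at an anchor's half-open end does not
overlap it.

**Anchor annotation.** Distinct anchors (exact-coordinate deduplication)
collect every overlapping gene into exactly one of eight categories:
expression status × the proximity class of the gene's *genome-wide* nearest
peak (eo/uo overlap, en3/un3 < 2 kb downstream, en5/un5 < 2 kb upstream,
ef/uf > 2 kb). Genes spanning two anchors of a loop count in each; within
one anchor a gene counts once. `mp` counts anchor-overlapping peaks; `mpfe`
those whose nearest *expressed* gene is > 2 kb away (or absent from the
chromosome). `bare` means every count is zero.

## Default thresholds

| parameter | default | meaning |
|---|---|---|
| `min_overlap_bp` | 1 | any "overlap" call |
| `min_frac` | 0.5 | high-resolution anchor co-location |
| `flank_bp` | 2000 | domain-boundary window half-width |
| `proximity_bp` | 2000 | peak–gene near/far cut (inclusive) |
| `tpm_threshold` | 1.0 | expressed-gene mean TPM (inclusive) |
| `min_support` | 2 | consensus-peak replicate support |

## Synthetic genome

The generator emulates the study's inputs at reduced scale with exact
per-record ground truth. Default conditions: five 36 Mb chromosomes; ~32
level-0 domains per chromosome (0.6–1.1 Mb) each nesting two levels of two
sub-domains with 10 kb margins; 200 loops with 5–25 kb anchors; each anchor
of an in-domain loop sits on a domain boundary with probability 0.15 (so
~72% embedded, ~26% one-boundary, ~2% two-boundary, matching the observed
per-level tables), 6% of loops bridge adjacent level-0 domains and 6% sit
outside all domains; 8 genes/Mb (1–5 kb) split 50/30/20 across
anchor/interior/outside zones; 48% expressed with mean TPM `10^U(0, 2.5)`
and multiplicative replicate noise (the expressed flag is always recomputed
from the realised mean); 240 peaks placed relative to isolated host genes
with weights 0.35 overlap / 0.27 < 2 kb / 0.38 > 2 kb, jittered ±30 bp into
three replicates (present with p = 0.85) plus 15 support-1 noise peaks per
replicate; repeats as Bernoulli 500 bp tiles at rate 0.2 in anchors and 0.6
in interiors; 400 eQTLs at 35% same-anchor / 6% cross-anchor; 240
high-resolution interactions (0.5–3 kb anchors) at 19% / 66% / 15% for
2/1/0 co-located anchors; a second loop replicate sharing both anchors for
46% of loops (anchors jittered ±2 kb) and one anchor for 31%.

Ground-truth labels are exact by construction, not merely probable:

* at most one loop per root-to-leaf chain of the domain tree, so no loop's
  anchors fall inside another loop's interior (this keeps interior repeat
  tiling pure and interior placements anchor-free);
* all "outside"/relocated placements (outside loops, relocated replicate-2
  anchors, noise peaks, unco-located eQTL SNPs and interactions) take
  disjoint segments from a reserved chromosome tail that domains, genes and
  peaks never enter;
* boundary anchors start within 2 kb of a domain edge while staying inside
  the domain, so the span stays contained and the boundary call is
  unambiguous; embedded anchors keep > 2 kb clearance.

A fixed seed yields byte-identical files (hashes recorded in
`manifest.json`). `truth_report` compares pipeline output against the
labels: exact-match stages at tolerance 0, rates at a 3σ binomial half-width
(for the repeat means, σ aggregates the per-loop tile counts).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: realistic loop/domain length distributions
(loop sizes follow the host domain), anchors shared across loops (off by
default; the `p_shared_anchor` knob exercises the prioritisation logic but
then voids per-loop domain truth), overlapping or ambiguous domain calls,
coordinate-liftover artefacts in eQTL records, unbalanced replicate quality,
and any sequence-level signal. Realised loop lengths follow the domain
geometry rather than the configured range; anchor lengths always respect it.

## Problem sizes

Unit tests run on a two-chromosome bundle (60 loops); the acceptance
recomputation and the property-based recovery checks use the full default
conditions (200 loops, 1 440 genes, 400 eQTLs) at seeds 7, 11 and 13 —
sizes chosen so every rate estimate has n ≥ 200 behind it while a full
pipeline pass stays in seconds. The supplementary-table reproduction driver
(`analysis/09_supplementary_repro.py`) runs the identical code paths on the
study's deposited tables when they are placed under `data/supplementary/`.

## Known limitations

* Consensus-peak reproduction of the study's 32,009 NF+MN count is out of
  reach without the undeposited per-replicate peak calls; the consensus
  logic is validated on synthetic replicates instead.
* Read-level processing (Hi-C mapping, loop/domain calling, peak calling,
  expression quantification) and coordinate liftover are out of scope; the
  package starts from called tables.
* Whether the study's per-level domain tables attribute by deepest
  containment is inferred from their disjoint-sum structure, not stated;
  `boundary_rule` and `frac_of` exist precisely because those readings are
  ambiguous, and both alternatives are one flag away.
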