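"""Loop sharing between replicates and co-location with high-resolution
interactions.

Counts replicate-2 loops sharing 2/1/0 anchors (>= 1 bp) with replicate 1,
then classifies the high-resolution interactions against replicate-1 loops
at the 50%-anchor-overlap criterion (the shape of the study's co-location
table) and by interior/anchor zone pairs.
"""

import json

from util import load, outdir

from loopcoloc.colocation import (
    colocate_highres_loops,
    distinct_anchors,
    map_interactions_to_zones,
    pair_loops_by_anchor_overlap,
)


def main() -> None:
    rep1 = load("loops_rep1.tsv")
    rep2 = load("loops_rep2.tsv")
    highres = load("highres.tsv")
    _cls, shared = pair_loops_by_anchor_overlap(rep2, rep1)
    hr_counts = colocate_highres_loops(highres, rep1, min_frac=0.5)
    _maps, zone_counts = map_interactions_to_zones(highres, rep1, min_frac=0.5)
    n_distinct = len(distinct_anchors(highres))
    summary = {
        "rep2_vs_rep1_shared_anchors": {str(k): shared.get(k, 0) for k in (2, 1, 0)},
        "highres_colocated_anchors_50pct": {str(k): hr_counts.get(k, 0) for k in (2, 1, 0)},
        "highres_zone_pairs": dict(zone_counts),
        "highres_distinct_anchors": n_distinct,
        "highres_total_anchor_slots": 2 * len(highres),
    }
    out = outdir() / "replicate_sharing.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    both = shared.get(2, 0)
    print(
        f"\n{both}/{len(rep2)} replicate-2 loops share both anchors with "
        f"replicate 1; {n_distinct} of {2 * len(highres)} high-resolution "
        "anchors are distinct by exact coordinates."
    )


if __name__ == "__main__":
    main()
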