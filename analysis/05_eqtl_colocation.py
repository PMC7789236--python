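"""eQTL lead-SNP / expression-trait co-location with loop anchors.

Classifies each eQTL as same-anchor, cross-anchor within one loop, or other,
and counts unique SNP positions overlapping any anchor.
"""

import json

from util import load, outdir

from loopcoloc.eqtl import colocate_eqtls


def main() -> None:
    loops = load("loops_rep1.tsv")
    genes = load("genes.gff3")
    eqtls = load("eqtls.tsv", schema="eqtl")
    _classes, summary = colocate_eqtls(eqtls, loops, genes)
    (outdir() / "eqtl_colocation.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    pct = 100 * summary["snps_on_anchors"] / summary["unique_snps"]
    print(
        f"\n{summary['same_anchor']} eQTLs have SNP and trait on one anchor; "
        f"{summary['cross_anchor']} cross anchors of one loop; "
        f"{pct:.1f}% of unique SNPs overlap anchors."
    )


if __name__ == "__main__":
    main()
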