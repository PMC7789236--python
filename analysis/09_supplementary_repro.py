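"""Reproduce the study's headline counts from its deposited tables.

Requires the supplementary loop/domain/peak (and optionally gene/expression)
tables downloaded into data/supplementary/ as: loops_rep1.tsv, loops_rep2.tsv,
domains_rep1.tsv, peaks_nf.tsv, genes.gff3, expression.tsv. Computes loop
parse counts (with/without Chr0), replicate anchor sharing, the
loop-vs-domain classification, and the anchor-annotation summaries.
"""

import json

from util import REPO, outdir

from loopcoloc.pipeline import reproduce_supplementary


def main() -> None:
    data_dir = REPO / "data" / "supplementary"
    try:
        out = reproduce_supplementary(data_dir)
    except FileNotFoundError as exc:
        raise SystemExit(f"cannot reproduce: {exc}")
    (outdir() / "supplementary_repro.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
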