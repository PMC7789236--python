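"""Generate the synthetic study inputs.

Writes a seeded synthetic genome - nested domains, two Hi-C loop replicates,
genes with expression, three ATAC-style peak replicates, repeats, eQTLs and
high-resolution interactions - to data/synthetic/, with ground-truth labels
in truth.json and file hashes in manifest.json.
"""

import argparse
import json

from util import DATA

from loopcoloc.synth import SynthConfig, generate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    bundle = generate(SynthConfig(seed=args.seed))
    manifest = bundle.write(DATA)
    print(f"wrote {len(manifest['files'])} files to {DATA} (seed {args.seed})")
    print(
        json.dumps(
            {
                "loops_rep1": len(bundle.loops),
                "loops_rep2": len(bundle.loops_rep2),
                "domains": len(bundle.domains),
                "genes": len(bundle.genes),
                "expressed_genes": sum(1 for r in bundle.expression if r.expressed),
                "consensus_truth_peaks": len(bundle.truth_peaks),
                "repeats": len(bundle.repeats),
                "eqtls": len(bundle.eqtls),
                "highres_interactions": len(bundle.highres),
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
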