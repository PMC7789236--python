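"""Shared loading for the analysis drivers: read the synthetic bundle files
written by 01_simulate.py back through the package's readers."""

from pathlib import Path

from loopcoloc import io as lio

REPO = Path(__file__).resolve().parent.parent
DATA = REPO / "data" / "synthetic"
RESULTS = REPO / "results"


def load(name: str, schema: str = None):
    path = DATA / name
    if not path.exists():
        raise SystemExit(
            f"{path} not found - run `python analysis/01_simulate.py` first"
        )
    if schema is not None:
        return lio.read_table(path, schema)
    if name.startswith("loops") or name.startswith("highres"):
        return lio.read_loops(path, id_prefix="H" if name.startswith("highres") else "L")
    if name.startswith("domains"):
        return lio.read_domains(path)
    if name.endswith(".gff3"):
        return lio.read_gene_models(path)
    raise ValueError(name)


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
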