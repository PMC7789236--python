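"""Shared fixtures: a small deterministic synthetic bundle and helpers."""

import pytest

from loopcoloc.synth import SynthConfig, generate


def small_config(seed: int = 3, **overrides) -> SynthConfig:
    """A reduced synthetic genome (2 chromosomes) for fast unit tests."""
    kwargs = dict(
        seed=seed,
        chrom_sizes={"1": 36_000_000, "2": 36_000_000},
        n_loops=60,
        n_eqtl=120,
        n_highres=80,
        n_peaks=100,
        gene_density=6.0,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def bundle():
    return generate(small_config())


@pytest.fixture(scope="session")
def bundle_outputs(bundle):
    from loopcoloc.pipeline import analyze_bundle

    return analyze_bundle(bundle)
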