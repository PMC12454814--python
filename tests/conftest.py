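"""Shared fixtures: seeded synthetic datasets at two scales.

The default-scale fixture (200 genes, 4 stages x 3 replicates, ~200 reads
per gene per sample) carries planted APA/PAL/m6A/expression effects and is
used for recovery checks; the small fixture is for fast structural tests.
All fixtures are session-scoped and fully determined by their seeds.
"""

import pytest

from tailshift import SimulationConfig, generate_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The seeded study-scale dataset with planted effects."""
    cfg = SimulationConfig(seed=1)
    genes, reads, modcalls, truth = generate_fixture(cfg)
    return cfg, genes, reads, modcalls, truth


@pytest.fixture(scope="session")
def small_fixture():
    """A light 30-gene dataset for structural/unit tests."""
    cfg = SimulationConfig(seed=11, n_genes=30, reads_per_gene_mean=60.0)
    genes, reads, modcalls, truth = generate_fixture(cfg)
    return cfg, genes, reads, modcalls, truth


def stage_samples(reads, stage):
    return sorted(reads.loc[reads["stage"] == stage, "sample_id"].unique())
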