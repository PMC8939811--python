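import numpy as np
import pytest

import rigsa
from rigsa.pipeline import PipelineConfig, run_controlled_analysis
from rigsa.simulate import default_fixture


@pytest.fixture(scope="session")
def enriched_fixture():
    """Default study conditions with one planted-enriched gene set."""
    panel, arch, ss = default_fixture(seed=1)
    return panel, arch, ss


@pytest.fixture(scope="session")
def enriched_report(enriched_fixture):
    """Full controlled analysis (baseline + RI augmentation + EPVP + IRED)."""
    panel, arch, ss = enriched_fixture
    cfg = PipelineConfig(
        panel=panel,
        genes=arch.genes,
        sumstats=ss,
        gene_sets=arch.gene_sets,
        ri_datasets={"RI": arch.regulatory_interactions},
        flank_ladder=[(10, 10)],
        set_size_range=(10, 200),
        n_perm=20,
        seed=1,
    )
    return run_controlled_analysis(cfg)


@pytest.fixture(scope="session")
def small_panel():
    """Tiny two-block panel for mapping/scoring unit tests."""
    return rigsa.simulate_reference_panel(
        200, [(5, 0.5), (5, 0.0)], [2_000_000], seed=42
    )


@pytest.fixture()
def toy_genes():
    return [
        rigsa.GeneModel("gA", 1, 100_000, 120_000, "+"),
        rigsa.GeneModel("gB", 1, 300_000, 340_000, "-"),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
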