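import pytest

from glytrome import ScenarioConfig
from glytrome import simulate as sim


@pytest.fixture(scope="session")
def default_config():
    return ScenarioConfig(seed=42)


@pytest.fixture(scope="session")
def reference(default_config):
    return sim.generate_reference(default_config)


@pytest.fixture(scope="session")
def panel(reference):
    return reference.bisulfite_panel()


@pytest.fixture(scope="session")
def small_ribo_config():
    # reduced problem size: enough footprints for offset inference
    # (>500/length class) while keeping the suite fast
    return ScenarioConfig(seed=11, n_ribo_transcripts=20,
                          footprints_per_transcript=800, n_genes=40)


@pytest.fixture(scope="session")
def cds_small(small_ribo_config):
    return sim.generate_cds(small_ribo_config)


@pytest.fixture(scope="session")
def bisulfite_matrices(default_config, panel):
    """Aligned + called methylation matrices for both genotypes."""
    from glytrome import methylation as meth
    out = {}
    for group in ("WT", "KO"):
        reads = sim.generate_bisulfite_reads(panel, default_config, group)
        out[group] = meth.methylation_matrix(reads, panel)
    return out
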