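import pytest

from circrecon import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Seeded noise-free bundle: 20 circRNAs, 30% internal-exon skip probability."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(SimConfig(seed=1, n_circ=20, skip_probability=0.3), outdir)


@pytest.fixture()
def toy_genome():
    return {"chrT": "ACGTACGTTTAACCGGATCGATCGGCTAGCTA"}
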