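import pytest

from genebirth import synthetic_data


@pytest.fixture(scope="session")
def yeast_tree():
    """11-tip yeast-shaped species tree; reference path labelled N0..N5."""
    return synthetic_data.SimConfig(seed=0).tree()


@pytest.fixture(scope="session")
def flies_tree():
    """16-tip fly-shaped tree with a multi-species terminal node."""
    return synthetic_data.SimConfig(seed=0, tree_preset="flies16-like").tree()


@pytest.fixture()
def small_cfg():
    """Downscaled simulation settings for fast unit tests."""
    return synthetic_data.SimConfig(
        seed=13,
        n_genes=60,
        codons_per_gene=100,
        n_snps=1500,
        n_intron_snps=1500,
        divergence=0.08,
        n_blocks=4,
        block_length=300,
        insertion_length=200,
    )
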