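import pytest

from pgclnc import simulate


@pytest.fixture(scope="session")
def synth():
    """Small synthetic genome with three lncRNAs per positional class."""
    return simulate.generate_genome_annotation(
        n_genes=12, n_lnc_per_class=3, seed=11, n_known=2
    )


@pytest.fixture(scope="session")
def synth_counts(synth):
    """Noise-free counts with planted correlated pairs."""
    return simulate.generate_expression(
        synth.truth, n_samples=10, r_target=0.98, noise=0.0, seed=7
    )
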