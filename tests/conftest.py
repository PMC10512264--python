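import pytest

from hybridscan import ancestry, simulate


@pytest.fixture(scope="session")
def parent_pair():
    """Small collinear parent pair at 10% divergence with a two-clade
    mitochondrial species."""
    return simulate.generate_parent_pair(
        [50_000, 40_000, 30_000, 20_000], 0.10, seed=101, n_mito_clades=(1, 2))


@pytest.fixture(scope="session")
def nuclear_index(parent_pair):
    return ancestry.build_diagnostic_index(list(parent_pair), 17)


@pytest.fixture(scope="session")
def mito_index(parent_pair):
    return ancestry.build_mito_index(list(parent_pair), 17)


@pytest.fixture(scope="session")
def balanced_sample(parent_pair):
    """Balanced euploid hybrid with reads at 20x."""
    truth = simulate.generate_hybrid(parent_pair, 0.5, sample_id="bal", seed=102)
    reads = simulate.simulate_reads(truth, parent_pair, 20.0, seed=103)
    return truth, reads
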