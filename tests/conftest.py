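import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_chain():
    """A 3-genome chain with one planted event of each type per pair."""
    from synvis.fixtures import FixtureSpec, build_truth, comparisons_from_truth
    from synvis.model import build_chain

    truth = build_truth(FixtureSpec(n_genomes=3, chroms_per_genome=2,
                                    chrom_length=50_000, seed=11))
    chain = build_chain(truth.genomes, comparisons_from_truth(truth))
    return chain, truth
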