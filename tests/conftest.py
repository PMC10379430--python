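import hypothesis
import pytest

from plastiq import synthio

hypothesis.settings.register_profile(
    "plastiq", deadline=None, derandomize=True, max_examples=50)
hypothesis.settings.load_profile("plastiq")


@pytest.fixture(scope="session")
def small_plastome():
    """A 9 kb quadripartite genome with two planted repeats and a few genes,
    shared by structure/repeat/read tests."""
    cfg = synthio.SimulationConfig(
        seed=3, lsc_len=5000, ssc_len=1000, ir_len=1500,
        n_repeats=2, n_genes=6, gene_len_range=(150, 450),
        dna_read_len_range=(500, 800), dna_depth=5, rna_depth=10)
    genome, annotations, truth = synthio.generate_plastome(cfg)
    return cfg, genome, annotations, truth
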