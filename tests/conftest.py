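import numpy as np
import pytest

from petalseq.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def big_run():
    """End-to-end run at parameter-recovery scale (shared across tests)."""
    cfg = PipelineConfig(
        n_genes=300,
        reads_per_sample=300_000,
        seed=11,
        n_de_purple=8,
        n_de_white=25,
        de_fold=3.5,
        bias3p_strength=0.5,
        kmer_list=[19, 21],
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_run():
    """20-gene smoke-scale run."""
    cfg = PipelineConfig(
        n_genes=20, reads_per_sample=5_000, seed=3, n_de_purple=2, n_de_white=3
    )
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
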