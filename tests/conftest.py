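import numpy as np
import pytest

from mitocircles.synth import SynthConfig, generate_genome, scaled_study_config


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_truth():
    """A small three-circle study genome shared across read-based tests."""
    cfg = scaled_study_config(0.05, seed=11)
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def single_circle_truth():
    cfg = SynthConfig(
        seed=3,
        n_chromosomes=1,
        chromosome_lengths=(30_000,),
        n_breaks_per_chromosome=(0,),
        cp_insert_length=0,
        read_length_mean=2_000.0,
        read_length_sd=400.0,
        fission_plan="none",
    )
    return generate_genome(cfg)
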