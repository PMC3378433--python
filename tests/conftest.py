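import numpy as np
import pytest

from est454.synthetic import SyntheticConfig
from est454 import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_transcripts=12,
        transcript_length_dist=(400, 700),
        reads_per_library=400,
        error_rate=0.0,
        seed=101,
        ssr_plant_spec=(("AG", 7, 0, 40), ("AAG", 5, 1, 80)),
    )


@pytest.fixture(scope="session")
def small_pool(small_config):
    transcripts, truth = synthetic.generate_transcriptome(small_config)
    return transcripts, truth


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
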