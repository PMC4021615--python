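import numpy as np
import pytest

from mmhg import PlantSpec, ScoredSequence, build_index, generate_planted_dataset


@pytest.fixture(scope="session")
def toy_sequences():
    """Four short ranked sequences with 'AC' common to the top two."""
    return [
        ScoredSequence("s1", "GGACGT"),
        ScoredSequence("s2", "TTACAA"),
        ScoredSequence("s3", "GGGGGG"),
        ScoredSequence("s4", "TTTTTT"),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_sequences):
    return build_index(toy_sequences)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset: 60 sequences, exact word in the top 12."""
    spec = PlantSpec(motif="ACGTAC", n_sequences=60, length=50, n_planted=12,
                     seed=7)
    ds = generate_planted_dataset(spec)
    return ds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240405)
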