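import pytest

from rigiddg.features import grouped_split
from rigiddg.synth import SyntheticSpec, gen_feature_dataset, gen_toy_structure


@pytest.fixture(scope="session")
def helix():
    return gen_toy_structure("polyala_helix", 10)


@pytest.fixture(scope="session")
def strand():
    return gen_toy_structure("extended_strand", 10)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free planted-signal dataset with its grouped split."""
    spec = SyntheticSpec(n_records=300, n_groups=60, noise_sd=0.0, seed=1)
    records, X, y = gen_feature_dataset(spec)
    split = grouped_split(records, seed=1)
    return records, X, y, split


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-noise labels (no planted weights)."""
    spec = SyntheticSpec(n_records=500, n_groups=100, planted_weights={},
                         noise_sd=1.0, seed=2)
    records, X, y = gen_feature_dataset(spec)
    split = grouped_split(records, seed=2)
    return records, X, y, split
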