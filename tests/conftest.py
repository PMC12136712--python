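import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

from phagekit.synthetic_data import dirichlet_profile, gen_proteomes
from phagekit.taxon_classifier import assemble_dataset

SEED = 37


@pytest.fixture(scope="session")
def separable_dataset():
    """Two-family tail proteomes with disjoint compositional signatures:
    family-separable by construction, 200 proteins per class."""
    profiles = [
        dirichlet_profile("FamA", "ACDEFGHIKL", seed=SEED, tail_count=5),
        dirichlet_profile("FamB", "MNPQRSTVWY", seed=SEED + 1, tail_count=5),
    ]
    records, label_map = gen_proteomes(profiles, genomes_per_family=40, seed=SEED)
    ds = assemble_dataset(records, label_map)
    return ds, records, label_map


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def random_protein(rng, length):
    from phagekit.constants import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
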