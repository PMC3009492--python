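import numpy as np
import pytest

from fxpress.classifiers import LABELS, LabeledInstance
from fxpress.features import N_FEATURES, load_codon_table
from fxpress.motifs import load_motif_table
from fxpress.scaffolds import default_scaffolds
from fxpress.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def codon_table():
    return load_codon_table()


@pytest.fixture(scope="session")
def motif_table():
    return load_motif_table()


@pytest.fixture(scope="session")
def scaffolds():
    return default_scaffolds()


@pytest.fixture(scope="session")
def dataset_726():
    """The default seeded 726-instance planted dataset (noise 0.1)."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def dataset_726_clean():
    """Noiseless variant of the planted dataset (same genes and rule)."""
    return generate_dataset(GeneratorConfig(noise_rate=0.0))


def make_blobs(n_per_class=30, spread=0.5, seed=0):
    """Well-separated 3-class toy instances in the 617-dim feature space.

    Class centers are three fixed random directions (norm 3 per feature
    scale), so no class collapses onto the origin after standardization.
    """
    dir_rng = np.random.default_rng(1234)  # centers fixed across calls
    centers = {}
    for label in LABELS:
        d = dir_rng.normal(size=N_FEATURES)
        centers[label] = 3.0 * d / np.abs(d).mean()
    rng = np.random.default_rng(seed)
    instances = []
    for label, mu in centers.items():
        for i in range(n_per_class):
            x = mu + rng.normal(0.0, spread, size=N_FEATURES)
            instances.append(
                LabeledInstance(key=(f"{label[:3]}{i}", "GST"), x=x, y=label)
            )
    return instances


@pytest.fixture(scope="session")
def blob_instances():
    return make_blobs(seed=11)
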