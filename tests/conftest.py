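import numpy as np
import pytest
from hypothesis import settings

import spikevo as sv

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def iris_like_encoder():
    """Encoder frozen on unit ranges for 4 features, L=4 (Iris geometry)."""
    return sv.EncoderConfig(n_fields=4, beta=1.5, feature_ranges=((0.0, 1.0),) * 4)


@pytest.fixture(scope="session")
def two_class_dataset():
    """Well-separated 2-class synthetic table used across the GA tests."""
    return sv.make_synthetic(
        n_per_class=15, k_classes=2, n_features=2, class_separation=4.0, noise_sd=1.0, seed=7
    )


@pytest.fixture(scope="session")
def small_trained(two_class_dataset):
    """One 30-generation fit shared by the tests that inspect results."""
    model = sv.SpikingClassifier(
        two_class_dataset.features,
        two_class_dataset.labels,
        n_hidden=6,
        ga=sv.GAConfig(max_generations=30),
    )
    return model, model.fit(seed=11)


def random_synapses(rng: np.random.Generator, n_pre: int, n_post: int) -> sv.SynapseSet:
    return sv.SynapseSet(
        weights=rng.uniform(-0.25, 1.0, size=(n_pre, n_post)),
        delays=rng.integers(1, 7, size=(n_pre, n_post)),
    )
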