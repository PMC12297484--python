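import numpy as np
import pytest

from wearssl import SynthConfig, generate_dataset, make_splits
from wearssl.losses import EmbeddingBatch


@pytest.fixture(scope="session")
def synth_dataset():
    """The default synthetic preset with subject-disjoint splits (seed 7)."""
    return make_splits(generate_dataset(SynthConfig(seed=7)), seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset for training smoke tests."""
    cfg = SynthConfig(n_classes=2, n_subjects=4, segments_per_subject=6,
                      window_s=4.0, seed=3)
    return make_splits(generate_dataset(cfg), ratios=(0.5, 0.25, 0.25), seed=3)


def random_embedding_batch(rng, n_sources=4, dim=3, n_feat=2):
    """Helper: a valid EmbeddingBatch with random unit projections."""
    z = rng.standard_normal((2 * n_sources, dim))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    d = np.repeat(rng.standard_normal((n_sources, n_feat)), 2, axis=0)
    return EmbeddingBatch(z=z, view_to_source=np.repeat(np.arange(n_sources), 2), d=d)
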