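import pytest

from nifhnet import EmbeddingConfig, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Cleanly separable two-class set, small lengths so the extractor is fast."""
    spec = SyntheticSpec(n_pos=40, n_neg=40, length_range=(60, 150),
                         motifs=("WQCDKGH",), seed=101)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_embedding_config():
    return EmbeddingConfig(M=150, L=16, n_filters=32, filter_width=15,
                           pool_size=3, epochs=5, batch_size=32)
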