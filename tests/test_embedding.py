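"""Integer tokenisation, zero padding and the embedding+convolution extractor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import LogisticRegression

from nifhnet.embedding import (EmbeddingConfig, EmbeddingExtractor, EncodingMap,
                               decode_tokens, default_encoding_map, encode_sequence,
                               extract_embedding_features, pad_sequence,
                               train_embedding_extractor)
from nifhnet.seq_io import ACCEPTED_ALPHABET, ProteinRecord

AA_TEXT = st.text(alphabet=sorted(ACCEPTED_ALPHABET), min_size=0, max_size=60)


def test_encoding_is_consistent_per_character():
    tokens = encode_sequence("ACLKIGAL")
    assert tokens[0] == tokens[6]  # both 'A'
    assert tokens[2] == tokens[7]  # both 'L'
    assert len(set(encode_sequence("AAAA"))) == 1
    assert encode_sequence("").shape == (0,)


def test_encoding_error_names_character_and_position():
    with pytest.raises(ValueError, match=r"'J' at position 2"):
        encode_sequence("ACJDE")


def test_encoding_map_reserves_token_zero():
    emap = default_encoding_map()
    assert 0 not in emap.tokens.values()
    assert len(set(emap.tokens.values())) == len(emap.tokens)
    with pytest.raises(ValueError):
        EncodingMap({"A": 0})


@pytest.mark.parametrize("n_tokens,M,n_zeros", [(125, 2000, 1875), (1750, 2000, 250),
                                                (1173, 1173, 0)])
def test_padding_arithmetic(n_tokens, M, n_zeros):
    padded = pad_sequence(np.ones(n_tokens, dtype=np.int64), M)
    assert padded.shape == (M,)
    assert int((padded == 0).sum()) == n_zeros
    assert np.all(padded[:n_tokens] == 1)


def test_padding_rejects_overlong_input():
    with pytest.raises(ValueError, match="exceeds"):
        pad_sequence(np.ones(10, dtype=np.int64), 5)


@given(AA_TEXT)
@settings(max_examples=50, deadline=None)
def test_encode_pad_decode_roundtrip(seq):
    padded = pad_sequence(encode_sequence(seq), 80)
    assert decode_tokens(padded) == seq


@pytest.fixture(scope="module")
def trained(tiny_dataset, small_embedding_config):
    return train_embedding_extractor(tiny_dataset, small_embedding_config, seed=7)


def test_extractor_output_shape(trained, small_embedding_config):
    feats = extract_embedding_features(trained, "ACDEFGHIKLMNPQRSTVWY")
    assert feats.shape == (small_embedding_config.n_filters,)
    batch = trained.transform(["ACDEF" * 5, "GHIKL" * 4])
    assert batch.shape == (2, small_embedding_config.n_filters)


def test_extractor_is_deterministic(tiny_dataset, small_embedding_config, trained):
    again = train_embedding_extractor(tiny_dataset, small_embedding_config, seed=7)
    seqs = [r.sequence for r in tiny_dataset[:6]]
    np.testing.assert_array_equal(trained.transform(seqs), again.transform(seqs))


def test_identical_sequences_get_identical_features(trained):
    a = extract_embedding_features(trained, "WQCDKGH" + "A" * 40)
    b = extract_embedding_features(trained, "WQCDKGH" + "A" * 40)
    np.testing.assert_array_equal(a, b)


def test_all_padding_input_is_a_constant_vector(trained):
    """The empty sequence encodes to all padding tokens; its features depend
    only on the trained weights (forward pass of the zero-token row)."""
    one = trained.transform([""])[0]
    with_others = trained.transform(["", "ACDEFGHIKL", "WQCDKGH" * 3])[0]
    np.testing.assert_array_equal(one, with_others)


def test_features_linearly_separate_synthetic_classes(tiny_dataset, trained):
    """Separability oracle: a linear probe on the extracted features recovers
    the planted-motif classes almost perfectly on the training set."""
    x = trained.transform([r.sequence for r in tiny_dataset])
    y = [r.label for r in tiny_dataset]
    probe = LogisticRegression(max_iter=2000).fit(x, y)
    assert probe.score(x, y) >= 0.95


def test_single_class_training_set_is_an_error(small_embedding_config):
    recs = [ProteinRecord(f"p{i}", "ACDEFGHIKL" * 3, label=1) for i in range(8)]
    with pytest.raises(ValueError, match="both classes"):
        train_embedding_extractor(recs, small_embedding_config, seed=0)


def test_sequence_longer_than_M_is_an_error(trained, small_embedding_config):
    too_long = "A" * (small_embedding_config.M + 1)
    with pytest.raises(ValueError, match="exceeds"):
        extract_embedding_features(trained, too_long)


@pytest.mark.parametrize("M,L,n_filters,width,pool", [
    (60, 8, 16, 7, 3), (100, 4, 5, 31, 2)])
def test_shape_audit_across_configs(M, L, n_filters, width, pool):
    cfg = EmbeddingConfig(M=M, L=L, n_filters=n_filters, filter_width=width,
                          pool_size=pool, epochs=1, batch_size=8)
    recs = ([ProteinRecord(f"p{i}", "WQCDKGH" + "A" * 20, 1) for i in range(8)] +
            [ProteinRecord(f"n{i}", "ILMNPQRST" * 3, 0) for i in range(8)])
    ext = train_embedding_extractor(recs, cfg, seed=1)
    # intermediate shapes: embedding (b, M, L); conv (b, M-width+1, F); pooled
    batch = ext._encode_batch(["ACDEF"])
    emb = ext.stack.layers[0].forward(batch)
    assert emb.shape == (1, M, L)
    conv = ext.stack.layers[1].forward(emb)
    assert conv.shape == (1, M - width + 1, n_filters)
    assert ext.transform(["ACDEF"]).shape == (1, n_filters)


def test_feature_matrix_csv_has_named_columns(trained, tmp_path):
    import pandas as pd
    from nifhnet.embedding import features_to_csv

    x = trained.transform(["ACDEF" * 4, "GHIKL" * 4])
    p = tmp_path / "ev.csv"
    features_to_csv(x, p, ids=["a", "b"])
    df = pd.read_csv(p)
    assert list(df.columns[:2]) == ["id", "ev_000"]
    assert df.shape == (2, 1 + trained.n_features)
    np.testing.assert_allclose(df.iloc[:, 1:].to_numpy(), x, rtol=1e-6)


def test_extractor_save_load_roundtrip(trained, tmp_path):
    trained.save(tmp_path / "ext")
    loaded = EmbeddingExtractor.load(tmp_path / "ext")
    seqs = ["WQCDKGH" * 3, "ACDEFGHIKL"]
    np.testing.assert_array_equal(trained.transform(seqs), loaded.transform(seqs))
    assert loaded.config == trained.config
    assert loaded.encoding_map == trained.encoding_map


def test_config_validation():
    with pytest.raises(ValueError):
        EmbeddingConfig(M=10, filter_width=31)
    with pytest.raises(ValueError):
        EmbeddingConfig(M=0)
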