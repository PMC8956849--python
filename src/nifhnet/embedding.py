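"""Learned embedding + convolution features (EV block).

Each sequence is integer-tokenised (one fixed token per amino-acid letter,
0 reserved for padding), right-padded with zeros to a fixed length M, and
pushed through a trainable stack

    embedding (M -> M x L) -> 1-D convolution (n_filters, width 31) -> ReLU
    -> temporal max-pool (size 3) -> global max-pool

yielding one value per filter: 128 embedding-vector (EV) features by
default.  The stack is trained end-to-end as a standalone classifier with a
small softmax head on the binary NifH labels, then truncated before the
head and frozen for feature emission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .seq_io import ACCEPTED_ALPHABET, ProteinRecord

__all__ = [
    "EncodingMap",
    "EmbeddingConfig",
    "EmbeddingExtractor",
    "default_encoding_map",
    "encode_sequence",
    "pad_sequence",
    "decode_tokens",
    "train_embedding_extractor",
    "extract_embedding_features",
    "features_to_csv",
]


@dataclass(frozen=True)
class EncodingMap:
    """Injective map from amino-acid characters to positive integer tokens.

    Token 0 is reserved for padding and never assigned to a character.
    """

    tokens: dict[str, int]

    def __post_init__(self):
        vals = list(self.tokens.values())
        if 0 in vals:
            raise ValueError("token 0 is reserved for padding")
        if len(set(vals)) != len(vals):
            raise ValueError("encoding map must be injective")

    @property
    def vocab_size(self) -> int:
        """Number of embedding rows, including the padding row."""
        return max(self.tokens.values()) + 1

    def inverse(self) -> dict[int, str]:
        return {v: k for k, v in self.tokens.items()}


def default_encoding_map() -> EncodingMap:
    """Fixed alphabetical assignment (A=1, B=2, C=3, ...) over the accepted
    alphabet; deterministic, since the particular assignment does not matter."""
    return EncodingMap({ch: i + 1 for i, ch in enumerate(sorted(ACCEPTED_ALPHABET))})


@dataclass(frozen=True)
class EmbeddingConfig:
    """Extractor hyperparameters.

    M: padded sequence length (the longest NifH sequence, 1173 aa, by default).
    L: embedding dimension per token.
    n_filters / filter_width: 1-D convolution producing one feature per filter.
    pool_size: temporal max-pool window applied before the global max-pool.
    epochs / batch_size / learning_rate: standalone training of the extractor.
    """

    M: int = 1173
    L: int = 32
    n_filters: int = 128
    filter_width: int = 31
    pool_size: int = 3
    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.filter_width > self.M:
            raise ValueError("filter_width must be <= M")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")


def encode_sequence(sequence: str, emap: Optional[EncodingMap] = None) -> np.ndarray:
    """Element-wise token lookup; identical characters get identical tokens."""
    emap = emap or default_encoding_map()
    out = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence):
        try:
            out[i] = emap.tokens[ch]
        except KeyError:
            raise ValueError(
                f"character {ch!r} at position {i} is not in the encoding map") from None
    return out


def pad_sequence(tokens: np.ndarray, M: int) -> np.ndarray:
    """Append zeros up to length M.  Longer inputs are an error — the caller
    must length-filter or truncate explicitly."""
    if len(tokens) > M:
        raise ValueError(f"sequence of {len(tokens)} tokens exceeds padded length M={M}")
    out = np.zeros(M, dtype=np.int64)
    out[: len(tokens)] = tokens
    return out


def decode_tokens(tokens: np.ndarray, emap: Optional[EncodingMap] = None) -> str:
    """Inverse of encode+pad: drops padding zeros and maps tokens back to letters."""
    emap = emap or default_encoding_map()
    inv = emap.inverse()
    return "".join(inv[int(t)] for t in tokens if t != 0)


def _build_stack(config: EmbeddingConfig, emap: EncodingMap,
                 rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([
        nn.Embedding(emap.vocab_size, config.L, rng),
        nn.Conv1D(config.L, config.n_filters, config.filter_width, rng),
        nn.ReLU(),
        nn.MaxPool1D(config.pool_size),
        nn.GlobalMaxPool1D(),
    ])


class EmbeddingExtractor:
    """Trained encoder mapping a padded integer sequence to ``n_filters`` features."""

    def __init__(self, stack: nn.Sequential, emap: EncodingMap, config: EmbeddingConfig,
                 seed: Optional[int] = None, history: Optional[dict] = None):
        self.stack = stack
        self.encoding_map = emap
        self.config = config
        self.seed = seed
        self.history = history or {}

    @property
    def n_features(self) -> int:
        return self.config.n_filters

    def _encode_batch(self, sequences: Sequence[str]) -> np.ndarray:
        return np.stack([
            pad_sequence(encode_sequence(s, self.encoding_map), self.config.M)
            for s in sequences])

    def transform(self, sequences: Sequence[str], batch_size: int = 64) -> np.ndarray:
        """Feature matrix (n_sequences, n_filters) for raw amino-acid strings."""
        out = np.empty((len(sequences), self.n_features), dtype=np.float32)
        for start in range(0, len(sequences), batch_size):
            batch = self._encode_batch(sequences[start:start + batch_size])
            out[start:start + len(batch)] = self.stack.forward(batch, training=False)
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        weights = {}
        for i, layer in enumerate(self.stack.layers):
            for name, p, _ in layer.params():
                weights[f"{i}.{name}"] = p
        np.savez(path / "weights.npz", **weights)
        meta = {
            "config": asdict(self.config),
            "encoding_map": self.encoding_map.tokens,
            "seed": self.seed,
        }
        (path / "extractor.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "EmbeddingExtractor":
        path = Path(path)
        meta = json.loads((path / "extractor.json").read_text())
        config = EmbeddingConfig(**meta["config"])
        emap = EncodingMap(dict(meta["encoding_map"]))
        stack = _build_stack(config, emap, np.random.default_rng(0))
        with np.load(path / "weights.npz") as data:
            for i, layer in enumerate(stack.layers):
                for name, p, _ in layer.params():
                    p[...] = data[f"{i}.{name}"]
        return cls(stack, emap, config, seed=meta.get("seed"))


def train_embedding_extractor(train: Sequence[ProteinRecord],
                              config: EmbeddingConfig = EmbeddingConfig(),
                              seed: int = 0,
                              emap: Optional[EncodingMap] = None) -> EmbeddingExtractor:
    """Train the embedding+convolution stack on labeled sequences and return it
    truncated before the classification head, frozen for feature emission."""
    if not train:
        raise ValueError("training set must be non-empty")
    labels = {r.label for r in train}
    if labels != {0, 1}:
        raise ValueError(
            f"training set must contain both classes (labels present: {sorted(l for l in labels if l is not None)})")

    emap = emap or default_encoding_map()
    rng = np.random.default_rng(seed)
    stack = _build_stack(config, emap, rng)
    head = nn.Dense(config.n_filters, 2, rng)
    model = nn.Sequential(stack.layers + [head, nn.Softmax()])

    x = np.stack([pad_sequence(encode_sequence(r.sequence, emap), config.M)
                  for r in train])
    y = np.zeros((len(train), 2), dtype=np.float32)
    y[np.arange(len(train)), [r.label for r in train]] = 1.0

    history = nn.fit(model, x, y, epochs=config.epochs, batch_size=config.batch_size,
                     lr=config.learning_rate, rng=rng)
    return EmbeddingExtractor(stack, emap, config, seed=seed, history=history)


def extract_embedding_features(extractor: EmbeddingExtractor, sequence: str) -> np.ndarray:
    """EV features for one sequence; deterministic given a trained extractor."""
    return extractor.transform([sequence])[0]


def features_to_csv(matrix: np.ndarray, path, ids: Optional[Sequence[str]] = None) -> None:
    """Write a feature matrix as CSV with columns ev_000..ev_NNN (plus an
    optional leading id column)."""
    import pandas as pd

    matrix = np.atleast_2d(matrix)
    df = pd.DataFrame(matrix,
                      columns=[f"ev_{i:03d}" for i in range(matrix.shape[1])])
    if ids is not None:
        df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)
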