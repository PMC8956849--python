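"""Hybrid feature assembly and the deep neural network NifH classifier.

The default feature vector has 328 values in a fixed block order:
100 5-mer presence bits, 100 7-mer presence bits, 128 EV (embedding) reals.
The classifier is a small dense network

    dense(128) -> dropout -> dense(64) -> batch-norm -> ReLU -> dropout
    -> dense(32) -> batch-norm -> ReLU -> dropout -> dense(2) -> softmax

trained with Adam (learning rate 6e-5) and 2-class cross-entropy on one-hot
labels for 40 epochs at batch size 40.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import nn
from .embedding import EmbeddingExtractor
from .kmers import GeneralKmerList, kmer_vector
from .seq_io import ProteinRecord

__all__ = [
    "FeatureLayout",
    "FeatureVector",
    "DNNConfig",
    "TrainedClassifier",
    "assemble_features",
    "featurize_records",
    "build_dnn",
    "train_dnn",
    "predict",
]


@dataclass(frozen=True)
class FeatureLayout:
    """Lengths of the named feature blocks, in fixed order kmer5 | kmer7 | ev."""

    kmer5: int = 100
    kmer7: int = 100
    ev: int = 128

    @property
    def total(self) -> int:
        return self.kmer5 + self.kmer7 + self.ev


@dataclass(frozen=True)
class FeatureVector:
    """One sequence's numeric representation plus its block layout."""

    values: np.ndarray
    layout: FeatureLayout

    def __post_init__(self):
        if len(self.values) != self.layout.total:
            raise ValueError(
                f"feature vector has {len(self.values)} values but layout totals "
                f"{self.layout.total}")


def assemble_features(kmer5: np.ndarray, kmer7: np.ndarray, ev: np.ndarray,
                      layout: Optional[FeatureLayout] = None) -> FeatureVector:
    """Concatenate the blocks in fixed order kmer5 | kmer7 | ev.

    Raises a ValueError naming the offending block on a length mismatch.
    """
    kmer5, kmer7, ev = (np.asarray(b, dtype=np.float32) for b in (kmer5, kmer7, ev))
    layout = layout or FeatureLayout(len(kmer5), len(kmer7), len(ev))
    for name, block, expect in (("kmer5", kmer5, layout.kmer5),
                                ("kmer7", kmer7, layout.kmer7),
                                ("ev", ev, layout.ev)):
        if len(block) != expect:
            raise ValueError(f"block {name!r} has length {len(block)}, expected {expect}")
    return FeatureVector(np.concatenate([kmer5, kmer7, ev]), layout)


def featurize_records(records: Sequence[ProteinRecord],
                      gls: Sequence[GeneralKmerList],
                      extractor: Optional[EmbeddingExtractor]) -> np.ndarray:
    """Feature matrix: one row per record, k-mer blocks in GL order then EV."""
    n = len(records)
    blocks = []
    for gl in gls:
        blocks.append(np.stack([kmer_vector(r.sequence, gl) for r in records])
                      if n else np.zeros((0, len(gl)), dtype=np.float32))
    if extractor is not None:
        blocks.append(extractor.transform([r.sequence for r in records]))
    if not blocks:
        raise ValueError("at least one feature block is required")
    return np.hstack(blocks).astype(np.float32)


@dataclass(frozen=True)
class DNNConfig:
    """Classifier hyperparameters; the layer stack itself is fixed."""

    input_dim: int = 328
    epochs: int = 40
    batch_size: int = 40
    learning_rate: float = 6e-5
    dropout_rates: tuple[float, float, float] = (0.3, 0.3, 0.3)
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if len(self.dropout_rates) != 3:
            raise ValueError("exactly three dropout layers in the stack")


def build_dnn(config: DNNConfig) -> nn.Sequential:
    """Untrained network with the fixed 12-layer stack (4 dense, 3 dropout,
    2 batch-norm, 3 activation); layer order and per-layer parameter counts
    follow the published architecture."""
    rng = np.random.default_rng(config.seed)
    d1, d2, d3 = config.dropout_rates
    return nn.Sequential([
        nn.Dense(config.input_dim, 128, rng),
        nn.Dropout(d1),
        nn.Dense(128, 64, rng),
        nn.BatchNorm(64),
        nn.ReLU(),
        nn.Dropout(d2),
        nn.Dense(64, 32, rng),
        nn.BatchNorm(32),
        nn.ReLU(),
        nn.Dropout(d3),
        nn.Dense(32, 2, rng),
        nn.Softmax(),
    ])


class TrainedClassifier:
    """A trained DNN plus the feature-pipeline artifacts that built its inputs."""

    def __init__(self, network: nn.Sequential, config: DNNConfig,
                 gls: Sequence[GeneralKmerList] = (),
                 extractor: Optional[EmbeddingExtractor] = None,
                 history: Optional[dict] = None):
        self.network = network
        self.config = config
        self.gls = list(gls)
        self.extractor = extractor
        self.history = history or {"loss": [], "accuracy": []}

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float32))
        return self.network.forward(features, training=False)

    def featurize(self, sequence: str) -> np.ndarray:
        if not self.gls and self.extractor is None:
            raise ValueError(
                "classifier has no GL or embedding-extractor references; "
                "pass a FeatureVector instead of a raw sequence")
        rec = ProteinRecord("query", sequence)
        return featurize_records([rec], self.gls, self.extractor)[0]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        weights = {}
        for i, layer in enumerate(self.network.layers):
            for name, p, _ in layer.params():
                weights[f"{i}.{name}"] = p
            if isinstance(layer, nn.BatchNorm):
                for name, p in layer.state().items():
                    weights[f"{i}.{name}"] = p
        np.savez(path / "dnn_weights.npz", **weights)
        meta = {"config": asdict(self.config), "history": self.history,
                "n_gls": len(self.gls), "has_extractor": self.extractor is not None}
        (path / "classifier.json").write_text(json.dumps(meta, indent=2))
        if self.history["loss"]:
            lines = ["epoch,loss,accuracy"] + [
                f"{e + 1},{l},{a}" for e, (l, a) in enumerate(
                    zip(self.history["loss"], self.history["accuracy"]))]
            (path / "training_history.csv").write_text("\n".join(lines) + "\n")
        for i, gl in enumerate(self.gls):
            gl.to_csv(path / f"general_list_{gl.k}mer_{i}.csv")
        if self.extractor is not None:
            self.extractor.save(path / "extractor")

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        path = Path(path)
        meta = json.loads((path / "classifier.json").read_text())
        cfg = meta["config"]
        cfg["dropout_rates"] = tuple(cfg["dropout_rates"])
        config = DNNConfig(**cfg)
        network = build_dnn(config)
        with np.load(path / "dnn_weights.npz") as data:
            for i, layer in enumerate(network.layers):
                for name, p, _ in layer.params():
                    p[...] = data[f"{i}.{name}"]
                if isinstance(layer, nn.BatchNorm):
                    for name, p in layer.state().items():
                        p[...] = data[f"{i}.{name}"]
        gls = [GeneralKmerList.from_csv(f)
               for f in sorted(path.glob("general_list_*.csv"))]
        extractor = (EmbeddingExtractor.load(path / "extractor")
                     if meta["has_extractor"] else None)
        return cls(network, config, gls, extractor, history=meta.get("history"))


def train_dnn(network: nn.Sequential, features: np.ndarray, labels: Sequence[int],
              config: DNNConfig,
              gls: Sequence[GeneralKmerList] = (),
              extractor: Optional[EmbeddingExtractor] = None) -> TrainedClassifier:
    """Train with 2-class cross-entropy on one-hot labels; deterministic under
    the config seed.  Zero epochs returns the untrained network with an empty
    history."""
    features = np.asarray(features, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("training labels must include both classes 0 and 1")
    if features.shape[1] != config.input_dim:
        raise ValueError(
            f"feature dimension {features.shape[1]} != config.input_dim {config.input_dim}")
    y = np.zeros((len(labels), 2), dtype=np.float32)
    y[np.arange(len(labels)), labels] = 1.0
    rng = np.random.default_rng(config.seed + 1)
    history = ({"loss": [], "accuracy": []} if config.epochs == 0 else
               nn.fit(network, features, y, epochs=config.epochs,
                      batch_size=config.batch_size, lr=config.learning_rate, rng=rng))
    return TrainedClassifier(network, config, gls, extractor, history=history)


def predict(classifier: TrainedClassifier,
            query: Union[str, FeatureVector, np.ndarray]) -> tuple[int, float]:
    """Argmax class and its probability for a raw sequence or feature vector."""
    if isinstance(query, str):
        features = classifier.featurize(query)
    elif isinstance(query, FeatureVector):
        features = query.values
    else:
        features = np.asarray(query, dtype=np.float32)
    probs = classifier.predict_proba(features)[0]
    label = int(probs.argmax())
    return label, float(probs[label])
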