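"""k-fold cross-validation over dataset methodologies and metric reporting.

A "dataset methodology" is a combination of feature blocks — k-mer presence
blocks (a k and a GL size) and/or the 128-feature EV block — evaluated by
stratified 4-fold cross-validation.  By default the general lists and the
embedding extractor are rebuilt on the training folds only, so the held-out
fold never leaks into feature construction; ``global_artifacts=True``
reproduces the simpler protocol of building them once on the full dataset.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import nn
from .classifier import DNNConfig, TrainedClassifier, build_dnn, featurize_records, train_dnn
from .embedding import EmbeddingConfig, EmbeddingExtractor, train_embedding_extractor
from .kmers import GeneralKmerList, build_general_list
from .seq_io import ProteinRecord

__all__ = [
    "FeatureBlock",
    "MethodologySpec",
    "ConfusionMatrix",
    "FoldResult",
    "CVReport",
    "kfold_split",
    "compute_metrics",
    "run_methodology",
    "compare_methodologies",
]


@dataclass(frozen=True)
class FeatureBlock:
    """One block of the feature vector: a k-mer GL block or the EV block.

    For an EV block, ``n_features=None`` defers to the embedding config's
    ``n_filters``.
    """

    kind: str  # "kmer" | "ev"
    k: Optional[int] = None
    n_features: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("kmer", "ev"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.kind == "kmer" and (self.k is None or self.k < 1):
            raise ValueError("kmer block needs k >= 1")
        if self.kind == "kmer" and (self.n_features is None or self.n_features < 1):
            raise ValueError("kmer block needs n_features >= 1")


@dataclass(frozen=True)
class MethodologySpec:
    """An ordered combination of feature blocks, e.g. 5-mers(100)+7-mers(100)+EV."""

    blocks: tuple[FeatureBlock, ...]

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("at least one feature block required")
        if sum(b.kind == "ev" for b in self.blocks) > 1:
            raise ValueError("at most one EV block")
        ks = [b.k for b in self.blocks if b.kind == "kmer"]
        if len(ks) != len(set(ks)):
            raise ValueError("k-mer blocks must have distinct k")

    @property
    def name(self) -> str:
        parts = []
        for b in self.blocks:
            parts.append("EV" if b.kind == "ev" else f"{b.k}-mers({b.n_features}f)")
        return "+".join(parts)

    @classmethod
    def parse(cls, text: str, ev_features: Optional[int] = None) -> "MethodologySpec":
        """Parse e.g. ``"5-mers(100)+7-mers(100)+ev"`` or ``"ev"``."""
        blocks = []
        for part in text.split("+"):
            part = part.strip().lower()
            if part == "ev":
                blocks.append(FeatureBlock("ev", n_features=ev_features))
                continue
            m = re.fullmatch(r"(\d+)-?mers?\s*\((\d+)\s*f?\)", part)
            if not m:
                raise ValueError(f"cannot parse methodology block {part!r}")
            blocks.append(FeatureBlock("kmer", k=int(m.group(1)),
                                       n_features=int(m.group(2))))
        return cls(tuple(blocks))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with NifH (label 1) as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix":
        yt, yp = np.asarray(y_true), np.asarray(y_pred)
        return cls(tp=int(((yt == 1) & (yp == 1)).sum()),
                   tn=int(((yt == 0) & (yp == 0)).sum()),
                   fp=int(((yt == 0) & (yp == 1)).sum()),
                   fn=int(((yt == 1) & (yp == 0)).sum()))


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity (= recall), specificity, precision and F1 on [0, 1].

    Division by zero yields NaN (undefined), never an exception.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _safe_div(cm.tp, cm.tp + cm.fp)
    recall = _safe_div(cm.tp, cm.tp + cm.fn)
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "sensitivity": recall,
        "recall": recall,
        "specificity": _safe_div(cm.tn, cm.tn + cm.fp),
        "precision": precision,
        "f1": _safe_div(2 * precision * recall, precision + recall),
    }


def kfold_split(n: int, k: int, seed: int,
                labels: Optional[Sequence[int]] = None) -> list[np.ndarray]:
    """Disjoint, covering, seed-shuffled test-fold index sets with sizes
    differing by at most one; stratified by label when labels are given."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    return [test for _, test in split]


@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    confusion: ConfusionMatrix
    metrics: dict[str, float]


@dataclass
class CVReport:
    """Per-fold confusion matrices and metrics plus the selected best classifier."""

    methodology: str
    folds: list[FoldResult]
    best_fold: int
    best_classifier: TrainedClassifier
    feature_dim: int

    def mean_metrics(self) -> dict[str, float]:
        return {key: float(np.mean([f.metrics[key] for f in self.folds]))
                for key in self.folds[0].metrics}

    def to_json(self, path=None) -> str:
        payload = {
            "methodology": self.methodology,
            "feature_dim": self.feature_dim,
            "best_fold": self.best_fold,
            "mean_metrics": self.mean_metrics(),
            "folds": [{
                "fold": f.fold,
                "test_indices": f.test_indices.tolist(),
                "confusion": {"tp": f.confusion.tp, "tn": f.confusion.tn,
                              "fp": f.confusion.fp, "fn": f.confusion.fn},
                "metrics": f.metrics,
            } for f in self.folds],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 100003 + 7919 * fold) % (2**31)


def _build_artifacts(train: Sequence[ProteinRecord], spec: MethodologySpec,
                     embedding_config: EmbeddingConfig, seed: int,
                     gl_from_all: bool):
    gls: list[GeneralKmerList] = []
    extractor: Optional[EmbeddingExtractor] = None
    for block in spec.blocks:
        if block.kind == "kmer":
            source = list(train) if gl_from_all else [r for r in train if r.label == 1]
            gls.append(build_general_list(source, block.k, block.n_features))
        else:
            cfg = embedding_config
            if block.n_features is not None and block.n_features != cfg.n_filters:
                cfg = EmbeddingConfig(**{**cfg.__dict__, "n_filters": block.n_features})
            extractor = train_embedding_extractor(train, cfg, seed=seed)
    return gls, extractor


def run_methodology(dataset: Sequence[ProteinRecord], spec: MethodologySpec,
                    k: int = 4, seed: int = 0,
                    embedding_config: EmbeddingConfig = EmbeddingConfig(),
                    dnn_config: Optional[DNNConfig] = None,
                    global_artifacts: bool = False,
                    gl_from_all: bool = False) -> CVReport:
    """Stratified k-fold cross-validation of one dataset methodology.

    For each fold the GLs and the embedding extractor are built on the
    training folds only (unless ``global_artifacts``), features are
    assembled, the DNN is trained, and the held-out fold is scored.  The
    classifier of the best fold — highest held-out accuracy, ties broken by
    lower loss — is retained in the report.
    """
    dataset = list(dataset)
    labels = [r.label for r in dataset]
    if set(labels) != {0, 1}:
        raise ValueError("dataset must contain both classes")
    test_folds = kfold_split(len(dataset), k, seed, labels=labels)

    global_gls = global_extractor = None
    if global_artifacts:
        global_gls, global_extractor = _build_artifacts(
            dataset, spec, embedding_config, seed=_fold_seed(seed, k), gl_from_all=gl_from_all)

    folds: list[FoldResult] = []
    classifiers: list[TrainedClassifier] = []
    for fold, test_idx in enumerate(test_folds):
        fold_seed = _fold_seed(seed, fold)
        test_mask = np.zeros(len(dataset), dtype=bool)
        test_mask[test_idx] = True
        train_recs = [r for r, m in zip(dataset, test_mask) if not m]
        test_recs = [dataset[i] for i in test_idx]
        try:
            if global_artifacts:
                gls, extractor = global_gls, global_extractor
            else:
                gls, extractor = _build_artifacts(
                    train_recs, spec, embedding_config, seed=fold_seed,
                    gl_from_all=gl_from_all)

            x_train = featurize_records(train_recs, gls, extractor)
            x_test = featurize_records(test_recs, gls, extractor)
            y_train = np.array([r.label for r in train_recs])
            y_test = np.array([r.label for r in test_recs])

            cfg = dnn_config or DNNConfig()
            cfg = DNNConfig(**{**cfg.__dict__, "input_dim": x_train.shape[1],
                               "seed": fold_seed})
            clf = train_dnn(build_dnn(cfg), x_train, y_train, cfg,
                            gls=gls, extractor=extractor)

            probs = clf.predict_proba(x_test)
            y_onehot = np.zeros((len(y_test), 2), dtype=np.float32)
            y_onehot[np.arange(len(y_test)), y_test] = 1.0
            loss, _ = nn.cross_entropy(probs, y_onehot)
            cm = ConfusionMatrix.from_predictions(y_test, probs.argmax(axis=1))
            metrics = compute_metrics(cm)
            metrics["loss"] = float(loss)
        except Exception as exc:
            raise RuntimeError(f"methodology {spec.name!r}, fold {fold}: {exc}") from exc
        folds.append(FoldResult(fold, test_idx, cm, metrics))
        classifiers.append(clf)

    best = min(range(k), key=lambda i: (-folds[i].metrics["accuracy"],
                                        folds[i].metrics["loss"]))
    return CVReport(methodology=spec.name, folds=folds, best_fold=best,
                    best_classifier=classifiers[best],
                    feature_dim=classifiers[best].config.input_dim)


def compare_methodologies(dataset: Sequence[ProteinRecord],
                          specs: Sequence[MethodologySpec], k: int = 4, seed: int = 0,
                          **kwargs) -> pd.DataFrame:
    """One row of fold-mean metrics per methodology, sorted by accuracy
    descending (ties keep the input order); percent scale, loss = CE x 100."""
    if not specs:
        raise ValueError("at least one methodology spec required")
    rows = []
    for spec in specs:
        report = run_methodology(dataset, spec, k=k, seed=seed, **kwargs)
        mean = report.mean_metrics()
        rows.append({
            "Methodology": spec.name,
            "Precision": 100 * mean["precision"],
            "Recall": 100 * mean["recall"],
            "F1": 100 * mean["f1"],
            "Accuracy": 100 * mean["accuracy"],
            "Loss": 100 * mean["loss"],
        })
    df = pd.DataFrame(rows)
    return df.sort_values("Accuracy", ascending=False, kind="stable").reset_index(drop=True)
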