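"""Cross-validation protocol, metric arithmetic and methodology comparison."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nifhnet.classifier import DNNConfig
from nifhnet.evaluation import (ConfusionMatrix, FeatureBlock, MethodologySpec,
                                compare_methodologies, compute_metrics, kfold_split,
                                run_methodology)


def test_kfold_even_split():
    folds = kfold_split(8, 4, seed=0)
    assert sorted(len(f) for f in folds) == [2, 2, 2, 2]
    all_idx = np.concatenate(folds)
    assert sorted(all_idx) == list(range(8))


def test_kfold_near_equal_sizes():
    folds = kfold_split(10, 4, seed=1)
    assert sorted(len(f) for f in folds) == [2, 2, 3, 3]


def test_kfold_deterministic_and_disjoint():
    a = kfold_split(30, 4, seed=5)
    b = kfold_split(30, 4, seed=5)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa, fb)
    seen = np.concatenate(a)
    assert len(seen) == len(set(seen)) == 30


def test_kfold_stratification_preserves_class_balance():
    labels = [1] * 20 + [0] * 20
    folds = kfold_split(40, 4, seed=3, labels=labels)
    for f in folds:
        assert sum(labels[i] for i in f) == 5


def test_kfold_rejects_too_few_records():
    with pytest.raises(ValueError):
        kfold_split(3, 4, seed=0)


def test_perfect_and_symmetric_confusion_matrices():
    assert all(v == 1.0 for v in compute_metrics(ConfusionMatrix(1, 1, 0, 0)).values())
    m = compute_metrics(ConfusionMatrix(25, 25, 25, 25))
    assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 0.5


def test_published_confusion_matrix_counts():
    """Counts tp=1188, tn=1132, fp=25, fn=48: expected metrics frozen from
    exact rational arithmetic."""
    m = compute_metrics(ConfusionMatrix(tp=1188, tn=1132, fp=25, fn=48))
    assert m["accuracy"] == pytest.approx(float(Fraction(2320, 2393)))
    assert m["sensitivity"] == pytest.approx(float(Fraction(1188, 1236)))
    assert m["specificity"] == pytest.approx(float(Fraction(1132, 1157)))
    assert m["precision"] == pytest.approx(float(Fraction(1188, 1213)))
    prec, rec = Fraction(1188, 1213), Fraction(1188, 1236)
    assert m["f1"] == pytest.approx(float(2 * prec * rec / (prec + rec)))


def test_division_by_zero_yields_nan_not_exception():
    m = compute_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
    assert np.isnan(m["precision"]) and np.isnan(m["sensitivity"])
    assert m["accuracy"] == 1.0


@given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
       st.integers(0, 500))
@settings(max_examples=100, deadline=None)
def test_accuracy_identity(tp, tn, fp, fn):
    """accuracy == (sens*P + spec*N)/(P+N) whenever both class totals are
    non-empty."""
    if tp + tn + fp + fn == 0:
        return
    m = compute_metrics(ConfusionMatrix(tp, tn, fp, fn))
    p, n = tp + fn, tn + fp
    if p and n:
        assert m["accuracy"] == pytest.approx(
            (m["sensitivity"] * p + m["specificity"] * n) / (p + n))


def test_methodology_spec_parsing_and_validation():
    spec = MethodologySpec.parse("5-mers(100)+7-mers(100)+ev")
    assert [b.kind for b in spec.blocks] == ["kmer", "kmer", "ev"]
    assert [b.k for b in spec.blocks] == [5, 7, None]
    # an unsized EV block defers to the embedding config's n_filters
    assert MethodologySpec.parse("ev").blocks[0].n_features is None
    assert MethodologySpec.parse("ev", ev_features=64).blocks[0].n_features == 64
    with pytest.raises(ValueError):
        MethodologySpec.parse("5-mers(100)+5-mers(200)")  # duplicate k
    with pytest.raises(ValueError):
        MethodologySpec((FeatureBlock("ev"), FeatureBlock("ev")))


@pytest.fixture(scope="module")
def quick_cv(tiny_dataset, small_embedding_config):
    # 80 records instead of the usual hundreds: train for more epochs so the
    # total number of gradient updates matches a full-scale run
    spec = MethodologySpec.parse("5-mers(20)+7-mers(20)+ev")
    return run_methodology(tiny_dataset, spec, k=4, seed=9,
                           embedding_config=small_embedding_config,
                           dnn_config=DNNConfig(epochs=200))


def test_cv_each_record_tested_exactly_once(quick_cv, tiny_dataset):
    seen = np.concatenate([f.test_indices for f in quick_cv.folds])
    assert sorted(seen) == list(range(len(tiny_dataset)))


def test_cv_feature_dimension(quick_cv, small_embedding_config):
    assert quick_cv.feature_dim == 20 + 20 + small_embedding_config.n_filters


def test_cv_separates_planted_motif_classes(quick_cv):
    assert quick_cv.mean_metrics()["accuracy"] >= 0.9


def test_best_fold_selection(quick_cv):
    accs = [(f.metrics["accuracy"], -f.metrics["loss"]) for f in quick_cv.folds]
    assert accs[quick_cv.best_fold] == max(accs)


def test_ev_only_methodology_feature_length(tiny_dataset, small_embedding_config):
    spec = MethodologySpec((FeatureBlock("ev", n_features=small_embedding_config.n_filters),))
    report = run_methodology(tiny_dataset, spec, k=4, seed=2,
                             embedding_config=small_embedding_config,
                             dnn_config=DNNConfig(epochs=5))
    assert report.feature_dim == small_embedding_config.n_filters


def test_informative_methodology_outranks_noise(tiny_dataset, small_embedding_config):
    """A 7-mer GL block that can capture the planted motif must beat a
    1-mer block (composition only, uninformative for uniform background)."""
    specs = [MethodologySpec((FeatureBlock("kmer", k=1, n_features=20),)),
             MethodologySpec((FeatureBlock("kmer", k=7, n_features=20),))]
    table = compare_methodologies(tiny_dataset, specs, k=4, seed=6,
                                  embedding_config=small_embedding_config,
                                  dnn_config=DNNConfig(epochs=40))
    assert len(table) == 2
    assert table.iloc[0]["Methodology"].startswith("7-mers")
    assert table.iloc[0]["Accuracy"] >= table.iloc[1]["Accuracy"]


def test_report_serialises_to_json(quick_cv, tmp_path):
    import json
    text = quick_cv.to_json(tmp_path / "report.json")
    payload = json.loads(text)
    assert payload["methodology"] == quick_cv.methodology
    assert len(payload["folds"]) == 4
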