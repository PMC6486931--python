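"""Lesion classifier training, LOOCV harness, leakage and fallback handling."""

import numpy as np
import pandas as pd
import pytest

import mplesion as mp
from mplesion.classification import (
    _loocv_scores,
    feature_matrix_from_table,
    incremental_evaluation,
    loocv_classification,
    train_lesion_classifier,
)
from mplesion.ranking import gini_ranking, RankingResult


def _synthetic_table(n=30, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    labels = np.array(["malignant" if i % 2 else "benign" for i in range(n)])
    sig = (labels == "malignant").astype(float)
    cols = {
        "kin_thalf": (1 - sig) * 200 + 50 + rng.normal(0, 5 if informative else 200, n),
        "noise_a": rng.normal(0, 1, n),
        "noise_b": rng.normal(0, 1, n),
        "adc_lowest_cluster": (1 - sig) * 1e-3 + 0.8e-3 + rng.normal(0, 1e-5, n),
    }
    table = pd.DataFrame(cols)
    table["label"] = labels
    table["patient_id"] = [f"p{i}" for i in range(n)]
    table["lesion_id"] = 1
    return table


def test_training_on_separable_data_reaches_f1_one():
    table = _synthetic_table()
    x, y, names = feature_matrix_from_table(table)
    clf = train_lesion_classifier(x, y, names, seed=0)
    assert clf.manifest["training_f1"] == pytest.approx(1.0)
    assert 0.0 < clf.threshold <= 1.0


def test_training_rejects_single_class():
    table = _synthetic_table()
    table["label"] = "malignant"
    x, y, names = feature_matrix_from_table(table)
    with pytest.raises(ValueError):
        train_lesion_classifier(x, y, names)


def test_seed_determinism():
    table = _synthetic_table()
    x, y, names = feature_matrix_from_table(table)
    a = train_lesion_classifier(x, y, names, seed=3)
    b = train_lesion_classifier(x, y, names, seed=3)
    assert np.array_equal(a.predict_proba(x), b.predict_proba(x))
    assert a.threshold == b.threshold


def test_loocv_single_repeat_reports_zero_sd():
    res = loocv_classification(_synthetic_table(), repeats=1, seed=0)
    assert res.auc_sd == 0.0
    assert res.n_repeats == 1
    assert 0.0 <= res.auc_mean <= 1.0


def test_loocv_no_leakage_from_held_out_label():
    """Flipping the held-out lesion's label leaves its fold untouched."""
    table = _synthetic_table(n=12)
    x, y, names = feature_matrix_from_table(table)
    p1, _ = _loocv_scores(x, y, names, n_trees=50, seed=0, ranking_method="GI", top_k=2)
    y_flipped = y.copy()
    y_flipped[0] = "benign" if y[0] == "malignant" else "malignant"
    p2, _ = _loocv_scores(x, y_flipped, names, n_trees=50, seed=0, ranking_method="GI", top_k=2)
    assert p1[0] == p2[0]


def test_incremental_curve_shape_and_plateau():
    table = _synthetic_table(n=40, seed=1)
    x, y, names = feature_matrix_from_table(table)
    ranking = gini_ranking(x, y == "malignant", names, seed=0)
    curve = incremental_evaluation(ranking, table, k_max=4, seed=0, n_trees=50)
    assert list(curve.k) == [1, 2, 3, 4]
    assert curve.auc_mean.between(0, 1).all()
    # the informative feature is top-ranked, so k = 1 is already strong
    assert curve.auc_mean.iloc[0] > 0.9


def test_incremental_single_feature_curve():
    table = _synthetic_table()
    ranking = RankingResult(names=["kin_thalf"], scores=np.array([1.0]), method="GI")
    curve = incremental_evaluation(ranking, table, seed=0, n_trees=50)
    assert len(curve) == 1


def test_classify_from_segmentation_fallback_flags(cls_cohort):
    studies = [s for s, _ in cls_cohort[1]]
    # two lesions of each class so every LOOCV fold keeps both classes
    benign = [s for s in studies if "benign" in s.lesion_labels.values()][:2]
    malignant = [s for s in studies if "malignant" in s.lesion_labels.values()][:2]
    cohort = benign + malignant
    model = mp.train_segmenter(cohort, seed=0)
    results = [mp.predict_segmentation(model, s, annotation=s.annotation) for s in cohort]
    res, table = mp.classify_from_segmentation(cohort, results, repeats=1, seed=0)
    assert set(res.fallback_flags.values()) <= {False, True}
    assert len(table) == sum(len(s.lesion_labels) for s in cohort)
    # force one undetected lesion: empty segmentation for the first study
    empty = mp.SegmentationResult(
        probability=np.zeros(cohort[0].shape),
        mask=np.zeros(cohort[0].shape, dtype=bool),
        blobs=np.zeros(cohort[0].shape, dtype=np.int32),
        threshold=0.5,
    )
    res2, table2 = mp.classify_from_segmentation(cohort, [empty] + results[1:], repeats=1, seed=0)
    n_lesions_first = len(cohort[0].lesion_labels)
    assert sum(res2.fallback_flags.values()) == n_lesions_first
    assert table2.fallback.sum() == n_lesions_first


def test_drop_groups_removes_modalities():
    table = _synthetic_table()
    x, y, names = feature_matrix_from_table(table, drop_groups={"DWI"})
    assert "adc_lowest_cluster" not in names
    assert "kin_thalf" in names
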