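"""Voxel sampling, Dice, blob post-processing and the segmentation forest."""

import numpy as np
import pytest

import mplesion as mp
from mplesion.segmentation import postprocess_blobs
from mplesion.voxel_features import voxel_feature_matrix


# -- sampling -------------------------------------------------------------

def test_sampling_counts_and_determinism(seg_cohort):
    study = seg_cohort[1][0][0]
    matrix = voxel_feature_matrix(study)
    n_lesion = int((study.annotation > 0).sum())
    rows = mp.sample_training_voxels(study, matrix, n_per_class=100, seed=1)
    lesion_rows = study.annotation[tuple(matrix.coords[rows].T)] > 0
    assert int(lesion_rows.sum()) == min(100, n_lesion)
    assert int((~lesion_rows).sum()) == 100
    rows2 = mp.sample_training_voxels(study, matrix, n_per_class=100, seed=1)
    assert np.array_equal(rows, rows2)


def test_sampling_capped_at_population(seg_cohort):
    study = seg_cohort[1][0][0]
    matrix = voxel_feature_matrix(study)
    n_lesion = int((study.annotation > 0).sum())
    rows = mp.sample_training_voxels(study, matrix, n_per_class=10**6, seed=0)
    lesion_rows = study.annotation[tuple(matrix.coords[rows].T)] > 0
    assert int(lesion_rows.sum()) == n_lesion


# -- dice -----------------------------------------------------------------

def test_dice_formula_cases():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.zeros((4, 4, 4), dtype=bool)
    a[:2], b[:2] = True, True
    assert mp.dice(a, b) == 1.0
    b[:] = False
    b[3] = True
    assert mp.dice(a, b) == 0.0
    # |a| = 4, |b| = 6, overlap 3 -> 0.6
    a[:] = False
    b[:] = False
    a.flat[:4] = True
    b.flat[1:7] = True
    assert mp.dice(a, b) == pytest.approx(0.6)
    assert mp.dice(np.zeros_like(a), np.zeros_like(b)) == 0.0


def test_dice_matches_set_arithmetic_on_random_masks():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.random((5, 5, 5)) < 0.4
        b = rng.random((5, 5, 5)) < 0.4
        sa = {tuple(i) for i in np.argwhere(a)}
        sb = {tuple(i) for i in np.argwhere(b)}
        expected = 0.0 if not (sa or sb) else 2 * len(sa & sb) / (len(sa) + len(sb))
        assert mp.dice(a, b) == pytest.approx(expected)


def test_dice_shape_mismatch():
    with pytest.raises(ValueError):
        mp.dice(np.zeros((2, 2, 2), dtype=bool), np.zeros((3, 3, 3), dtype=bool))


# -- post-processing ------------------------------------------------------

def test_six_connectivity_face_vs_corner():
    face = np.zeros((3, 3, 3), dtype=bool)
    face[1, 1, 0] = face[1, 1, 1] = True
    assert postprocess_blobs(face).max() == 1
    corner = np.zeros((3, 3, 3), dtype=bool)
    corner[0, 0, 0] = corner[1, 1, 1] = True
    assert postprocess_blobs(corner).max() == 2


def test_single_voxel_one_component():
    m = np.zeros((3, 3, 3), dtype=bool)
    m[1, 1, 1] = True
    assert postprocess_blobs(m).max() == 1


def test_annotation_overlap_filters_blobs():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[0:2, 0:2, 0:2] = True      # overlaps annotation
    mask[5:7, 5:7, 5:7] = True      # distractor
    ann = np.zeros((8, 8, 8), dtype=np.int32)
    ann[1, 1, 1] = 1
    blobs = postprocess_blobs(mask, ann)
    assert blobs.max() == 1
    assert blobs[1, 1, 1] == 1
    assert blobs[6, 6, 6] == 0


def test_postprocessing_never_decreases_dice(seg_cohort):
    """Removing annotation-disjoint blobs can only drop false positives."""
    cohort = [s for s, _ in seg_cohort[1]]
    model = mp.train_segmenter(cohort[:4], seed=0)
    study = cohort[4]
    res = mp.predict_segmentation(model, study, annotation=study.annotation)
    truth = study.annotation > 0
    assert mp.dice(res.blobs > 0, truth) >= mp.dice(res.mask, truth)


# -- training and prediction ----------------------------------------------

def test_train_predict_contract(seg_cohort):
    cohort = [s for s, _ in seg_cohort[1]]
    model = mp.train_segmenter(cohort[:3], seed=0)
    assert 0.0 <= model.threshold <= 1.0
    assert model.manifest["training_mean_dsc"] >= 0.8      # well-separated phantoms
    res = mp.predict_segmentation(model, cohort[3])
    assert res.probability.min() >= 0.0 and res.probability.max() <= 1.0
    assert np.all(res.probability[~cohort[3].breast_mask] == 0.0)
    assert not np.any(res.mask & ~cohort[3].breast_mask)


def test_single_study_training_warns(seg_cohort):
    cohort = [s for s, _ in seg_cohort[1]]
    with pytest.warns(UserWarning, match="single study"):
        mp.train_segmenter(cohort[:1], seed=0)


def test_feature_mismatch_rejected(seg_cohort):
    cohort = [s for s, _ in seg_cohort[1]]
    model = mp.train_segmenter(cohort[:3], seed=0)
    matrix = mp.feature_subset(voxel_feature_matrix(cohort[3]), {"PET"})
    with pytest.raises(ValueError, match="f_pet"):
        mp.predict_segmentation(model, cohort[3], matrix=matrix)


def test_loocv_row_count(seg_cohort):
    cohort = [s for s, _ in seg_cohort[1]][:4]
    metrics = mp.loocv_segmentation(cohort, seed=0)
    # one per-lesion row plus one per-patient aggregate row per study
    assert (metrics.lesion_id == 0).sum() == 4
    assert set(metrics.patient_id) == {s.patient_id for s in cohort}
    assert metrics.dsc.between(0, 1).all()
    assert metrics.sensitivity.between(0, 1).all()
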