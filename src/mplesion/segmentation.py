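"""Voxel-wise random-forest lesion segmentation and its evaluation.

Segmentation is treated as binary voxel classification inside the breast
mask.  A random forest is trained on up to 1000 randomly drawn voxels per
class per patient; the probability threshold is chosen on the training set
as the value maximising the mean Dice similarity coefficient (DSC), with
ties broken toward the smallest threshold.  Predicted masks are cleaned by
6-connected component analysis; in evaluation mode only components that
partially overlap the reference annotation survive, mimicking a reader
discarding obvious false positives before diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .study import MpStudy
from .voxel_features import VoxelFeatureMatrix, feature_subset, voxel_feature_matrix

__all__ = [
    "SegModel",
    "SegmentationResult",
    "sample_training_voxels",
    "train_segmenter",
    "predict_segmentation",
    "postprocess_blobs",
    "dice",
    "voxel_sensitivity",
    "loocv_segmentation",
]

N_SAMPLES_PER_CLASS = 1000
THRESHOLD_GRID = np.linspace(0.0, 1.0, 101)
SIX_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegModel:
    """Trained voxel classifier plus its operating threshold."""

    forest: RandomForestClassifier
    threshold: float
    columns: list[str]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class SegmentationResult:
    """Probability map, thresholded mask and post-processed blobs."""

    probability: np.ndarray      # in [0, 1], zero outside the breast mask
    mask: np.ndarray             # bool: probability >= threshold, inside M
    blobs: np.ndarray            # int labels after post-processing
    threshold: float


def sample_training_voxels(study: MpStudy, matrix: VoxelFeatureMatrix,
                           n_per_class: int = N_SAMPLES_PER_CLASS,
                           seed: int = 0) -> np.ndarray:
    """Row indices of up to ``n_per_class`` lesion and background voxels.

    Sampling is without replacement and reproducible under ``seed``; when a
    class has fewer voxels than requested, all of them are used.
    """
    lesion = study.annotation[tuple(matrix.coords.T)] > 0
    idx_pos = np.nonzero(lesion)[0]
    idx_neg = np.nonzero(~lesion)[0]
    if idx_pos.size == 0 or idx_neg.size == 0:
        raise ValueError("study must contain both lesion and background voxels")
    rng = np.random.default_rng(seed)
    take_pos = rng.choice(idx_pos, size=min(n_per_class, idx_pos.size), replace=False)
    take_neg = rng.choice(idx_neg, size=min(n_per_class, idx_neg.size), replace=False)
    return np.sort(np.concatenate([take_pos, take_neg]))


def _pool_training(cohort, matrices, n_per_class, seed):
    xs, ys = [], []
    for i, (study, matrix) in enumerate(zip(cohort, matrices)):
        rows = sample_training_voxels(study, matrix, n_per_class, seed=seed + i)
        xs.append(matrix.values[rows])
        ys.append(study.annotation[tuple(matrix.coords[rows].T)] > 0)
    return np.vstack(xs), np.concatenate(ys)


def train_segmenter(cohort: list[MpStudy], n_per_class: int = N_SAMPLES_PER_CLASS,
                    n_trees: int = 100, seed: int = 0,
                    drop_modalities: set[str] = frozenset(),
                    matrices: list[VoxelFeatureMatrix] | None = None,
                    feature_names: list[str] | None = None) -> SegModel:
    """Fit the voxel forest on pooled samples and pick the DSC-optimal threshold.

    ``matrices`` may carry precomputed feature matrices (same order as the
    cohort); ``feature_names`` restricts training to a named subset (used
    by feature-ranking experiments).  A single-study cohort is accepted but
    the threshold then reflects that one patient only.
    """
    if len(cohort) == 0:
        raise ValueError("empty training cohort")
    if len(cohort) == 1:
        import warnings

        warnings.warn("training on a single study: the threshold reflects one patient only")
    if matrices is None:
        matrices = [voxel_feature_matrix(s) for s in cohort]
    if drop_modalities:
        matrices = [feature_subset(m, drop_modalities) for m in matrices]
    if feature_names is not None:
        keep = [matrices[0].columns.index(c) for c in feature_names]
        matrices = [
            VoxelFeatureMatrix(m.values[:, keep], list(feature_names), m.coords, m.patient_id)
            for m in matrices
        ]
    x, y = _pool_training(cohort, matrices, n_per_class, seed)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are degenerate (one class)")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x, y)

    # threshold: maximise mean training DSC on the full probability maps
    probs, truths = [], []
    for study, matrix in zip(cohort, matrices):
        p = forest.predict_proba(matrix.values)[:, 1]
        probs.append(p)
        truths.append(study.annotation[tuple(matrix.coords.T)] > 0)
    best_thr, best_dsc = 0.0, -1.0
    for thr in THRESHOLD_GRID:
        dscs = [_dice_flat(p >= thr, t) for p, t in zip(probs, truths)]
        mean_dsc = float(np.mean(dscs))
        if mean_dsc > best_dsc + 1e-12:        # ties keep the smaller threshold
            best_thr, best_dsc = float(thr), mean_dsc
    manifest = {
        "n_patients": len(cohort),
        "n_per_class": n_per_class,
        "seed": seed,
        "training_mean_dsc": best_dsc,
        "dropped_modalities": sorted(drop_modalities),
    }
    return SegModel(forest=forest, threshold=best_thr,
                    columns=list(matrices[0].columns), manifest=manifest)


def predict_segmentation(model: SegModel, study: MpStudy,
                         matrix: VoxelFeatureMatrix | None = None,
                         annotation: np.ndarray | None = None) -> SegmentationResult:
    """Probability map and post-processed segmentation for one study.

    Voxels outside the breast mask receive probability 0.  When
    ``annotation`` is given, post-processing removes blobs with no overlap
    (evaluation mode).
    """
    if matrix is None:
        matrix = voxel_feature_matrix(study)
    missing = [c for c in model.columns if c not in matrix.columns]
    if missing:
        raise ValueError(f"study features missing columns {missing}")
    cols = [matrix.columns.index(c) for c in model.columns]
    p = model.forest.predict_proba(matrix.values[:, cols])[:, 1]
    prob = np.zeros(study.shape, dtype=float)
    prob[tuple(matrix.coords.T)] = p
    mask = (prob >= model.threshold) & study.breast_mask
    blobs = postprocess_blobs(mask, annotation)
    return SegmentationResult(probability=prob, mask=mask, blobs=blobs,
                              threshold=model.threshold)


def postprocess_blobs(mask: np.ndarray, annotation: np.ndarray | None = None) -> np.ndarray:
    """Label 6-connected components; optionally keep only annotation-overlapping ones.

    Without an annotation all components are returned (deployment mode);
    with one, components that do not partially overlap any annotated lesion
    are removed (evaluation mode).
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=SIX_CONNECTIVITY)
    if annotation is None or n == 0:
        return labels
    ann = np.asarray(annotation) > 0
    keep = np.zeros(n + 1, dtype=bool)
    overlapping = np.unique(labels[ann & (labels > 0)])
    keep[overlapping] = True
    cleaned = np.where(keep[labels], labels, 0)
    # relabel compactly
    out, _ = ndimage.label(cleaned > 0, structure=SIX_CONNECTIVITY)
    return out


def _dice_flat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 0.0     # empty-vs-empty convention
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return _dice_flat(a, b)


def voxel_sensitivity(pred: np.ndarray, truth: np.ndarray) -> float:
    """True-positive rate at voxel level; 0 when the reference is empty."""
    truth = np.asarray(truth, dtype=bool)
    n_true = int(truth.sum())
    if n_true == 0:
        return 0.0
    return int((np.asarray(pred, dtype=bool) & truth).sum()) / n_true


def loocv_segmentation(cohort: list[MpStudy], n_per_class: int = N_SAMPLES_PER_CLASS,
                       n_trees: int = 100, seed: int = 0,
                       drop_modalities: set[str] = frozenset(),
                       matrices: list[VoxelFeatureMatrix] | None = None) -> pd.DataFrame:
    """Leave-one-patient-out segmentation evaluation.

    Each patient is held out once; the forest and threshold come from the
    remaining patients.  Returns one row per held-out lesion with DSC,
    voxel sensitivity and a detection flag (>= 1 post-processed blob
    overlapping the lesion), plus per-patient rows (lesion_id = 0)
    aggregating over all annotated voxels.
    """
    if len(cohort) < 3:
        raise ValueError("LOOCV needs at least 3 studies")
    if matrices is None:
        matrices = [voxel_feature_matrix(s) for s in cohort]
    if drop_modalities:
        matrices = [feature_subset(m, drop_modalities) for m in matrices]
    records = []
    for held in range(len(cohort)):
        train_idx = [i for i in range(len(cohort)) if i != held]
        model = train_segmenter([cohort[i] for i in train_idx], n_per_class=n_per_class,
                                n_trees=n_trees, seed=seed,
                                matrices=[matrices[i] for i in train_idx])
        study = cohort[held]
        res = predict_segmentation(model, study, matrix=matrices[held],
                                   annotation=study.annotation)
        pred = res.blobs > 0
        for lesion_id in sorted(study.lesion_labels):
            truth = study.annotation == lesion_id
            records.append(
                {
                    "patient_id": study.patient_id,
                    "lesion_id": lesion_id,
                    "lesion_class": study.lesion_labels[lesion_id],
                    "dsc": dice(pred & _lesion_region(res, truth), truth),
                    "sensitivity": voxel_sensitivity(pred, truth),
                    "detected": bool((pred & truth).any()),
                }
            )
        truth_all = study.annotation > 0
        records.append(
            {
                "patient_id": study.patient_id,
                "lesion_id": 0,
                "lesion_class": "all",
                "dsc": dice(pred, truth_all),
                "sensitivity": voxel_sensitivity(pred, truth_all),
                "detected": bool((pred & truth_all).any()),
            }
        )
    return pd.DataFrame.from_records(records)


def _lesion_region(res: SegmentationResult, truth: np.ndarray) -> np.ndarray:
    """Predicted blobs touching this lesion (per-lesion DSC attribution)."""
    ids = np.unique(res.blobs[truth & (res.blobs > 0)])
    if ids.size == 0:
        return np.zeros_like(truth, dtype=bool)
    return np.isin(res.blobs, ids)
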