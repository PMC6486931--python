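"""Benign/malignant lesion classification and the LOOCV experiment harness.

A random forest is trained on lesion feature vectors; its probability
threshold is chosen on the training set as the value maximising the F1
score (harmonic mean of precision and sensitivity), ties broken toward the
smaller threshold.  Evaluation is leave-one-lesion-out cross-validation:
feature ranking (when requested) and threshold selection happen inside
each training fold so no information leaks from the held-out lesion.
Experiments are repeated with different forest seeds and reported as mean
and SD of the ROC AUC plus mean sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .lesion_features import (
    LESION_FEATURE_GROUPS,
    LESION_FEATURE_NAMES,
    lesion_feature_vector,
)
from .ranking import RankingResult, gini_ranking, mrmr_ranking, roc_auc
from .segmentation import SegmentationResult
from .study import MpStudy, standardise_study

__all__ = [
    "LesionClassifier",
    "EvalResult",
    "train_lesion_classifier",
    "loocv_classification",
    "incremental_evaluation",
    "classify_from_segmentation",
    "feature_matrix_from_table",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "malignant"
THRESHOLD_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class LesionClassifier:
    forest: RandomForestClassifier
    threshold: float
    feature_names: list[str]
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forest.predict_proba(np.asarray(x, dtype=float))[:, 1]


@dataclass
class EvalResult:
    """LOOCV classification performance over repeats."""

    auc_mean: float
    auc_sd: float
    sensitivity: float
    specificity: float
    n_lesions: int
    n_repeats: int
    per_repeat_auc: np.ndarray
    fallback_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc_mean <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _f1(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2.0 * tp / (2 * tp + fp + fn)


def train_lesion_classifier(features: np.ndarray, labels, feature_names: list[str],
                            n_trees: int = 100, seed: int = 0) -> LesionClassifier:
    """Fit the lesion forest and choose the F1-maximising threshold."""
    x = np.asarray(features, dtype=float)
    y = np.asarray([lab == POSITIVE_CLASS for lab in labels])
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x, y)
    p = forest.predict_proba(x)[:, 1]
    best_thr, best_f1 = 0.0, -1.0
    for thr in THRESHOLD_GRID:
        f1 = _f1(p >= thr, y)
        if f1 > best_f1 + 1e-12:       # ties keep the smaller threshold
            best_thr, best_f1 = float(thr), f1
    return LesionClassifier(
        forest=forest, threshold=best_thr, feature_names=list(feature_names),
        manifest={"seed": seed, "n_trees": n_trees, "training_f1": best_f1},
    )


def feature_matrix_from_table(table: pd.DataFrame,
                              drop_groups: set[str] = frozenset(),
                              feature_names: list[str] | None = None):
    """(X, y, names) from a cohort feature table, with optional group drops."""
    if feature_names is None:
        feature_names = [n for n in LESION_FEATURE_NAMES if n in table.columns]
    if drop_groups:
        group_of = dict(zip(LESION_FEATURE_NAMES, LESION_FEATURE_GROUPS))
        feature_names = [n for n in feature_names if group_of.get(n) not in drop_groups]
    x = table[feature_names].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    return x, y, feature_names


def _loocv_scores(x: np.ndarray, y: np.ndarray, names: list[str],
                  n_trees: int, seed: int,
                  ranking_method: str | None, top_k: int | None):
    """Held-out probability and threshold per lesion (one LOOCV pass)."""
    n = x.shape[0]
    probs = np.empty(n)
    preds = np.empty(n, dtype=bool)
    for held in range(n):
        tr = np.arange(n) != held
        x_tr, y_tr = x[tr], y[tr]
        cols = np.arange(x.shape[1])
        used_names = list(names)
        if ranking_method is not None:
            if ranking_method == "GI":
                ranking = gini_ranking(x_tr, y_tr == POSITIVE_CLASS, names, n_trees=n_trees, seed=seed)
            elif ranking_method == "mRMR":
                ranking = mrmr_ranking(x_tr, y_tr == POSITIVE_CLASS, names)
            else:
                raise ValueError("ranking_method must be 'GI', 'mRMR' or None")
            used_names = ranking.top(top_k or len(names))
            cols = np.array([names.index(c) for c in used_names])
        clf = train_lesion_classifier(x_tr[:, cols], y_tr, used_names,
                                      n_trees=n_trees, seed=seed)
        p = clf.predict_proba(x[held][cols][None, :])[0]
        probs[held] = p
        preds[held] = p >= clf.threshold
    return probs, preds


def loocv_classification(table: pd.DataFrame, repeats: int = 20, seed: int = 0,
                         n_trees: int = 100, drop_groups: set[str] = frozenset(),
                         ranking_method: str | None = None,
                         top_k: int | None = None) -> EvalResult:
    """Leave-one-lesion-out evaluation, repeated over forest seeds.

    ``table`` is a cohort feature table (one row per lesion with a
    ``label`` column).  ``ranking_method``/``top_k`` re-rank features
    inside every training fold and train on the top k only.  Repeats vary
    the forest seed; mean +/- SD of the pooled held-out AUC and the mean
    sensitivity/specificity at the fold thresholds are reported.
    """
    x, y, names = feature_matrix_from_table(table, drop_groups=drop_groups)
    if x.shape[0] < 3:
        raise ValueError("LOOCV needs at least 3 lesions")
    truth = y == POSITIVE_CLASS
    if truth.all() or not truth.any():
        raise ValueError("cohort must contain both classes")
    aucs, sens, spec = [], [], []
    for r in range(repeats):
        probs, preds = _loocv_scores(x, y, names, n_trees, seed + r,
                                     ranking_method, top_k)
        aucs.append(roc_auc(probs, truth))
        tp = int((preds & truth).sum())
        tn = int((~preds & ~truth).sum())
        sens.append(tp / int(truth.sum()))
        spec.append(tn / int((~truth).sum()))
    aucs = np.asarray(aucs)
    return EvalResult(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=0)),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        n_lesions=x.shape[0],
        n_repeats=repeats,
        per_repeat_auc=aucs,
    )


def incremental_evaluation(ranking: RankingResult, table: pd.DataFrame,
                           k_max: int | None = None, repeats: int = 1,
                           seed: int = 0, n_trees: int = 100) -> pd.DataFrame:
    """AUC of LOOCV models trained on the top-k ranked features, k = 1..k_max.

    Reproduces the incremental feature-contribution curve: performance as
    a function of how many top-ranked features the model may use.
    """
    if not ranking.names:
        raise ValueError("empty ranking")
    x, y, names = feature_matrix_from_table(table, feature_names=None)
    if k_max is None:
        k_max = len(ranking.names)
    truth = y == POSITIVE_CLASS
    rows = []
    for k in range(1, k_max + 1):
        subset = ranking.top(k)
        cols = np.array([names.index(c) for c in subset])
        rep_aucs = []
        for r in range(repeats):
            probs, _ = _loocv_scores(x[:, cols], y, subset, n_trees, seed + r, None, None)
            rep_aucs.append(roc_auc(probs, truth))
        rows.append({"k": k, "auc_mean": float(np.mean(rep_aucs)),
                     "auc_sd": float(np.std(rep_aucs)), "feature_added": subset[-1]})
    return pd.DataFrame(rows)


def classify_from_segmentation(cohort: list[MpStudy],
                               seg_results: list[SegmentationResult],
                               repeats: int = 20, seed: int = 0,
                               drop_groups: set[str] = frozenset()) -> tuple[EvalResult, pd.DataFrame]:
    """Classification on automatically segmented lesions.

    Each annotated lesion is matched to the union of predicted blobs
    overlapping it; undetected lesions fall back to the manual annotation
    mask and are flagged.  Returns the LOOCV result plus the feature table
    (with a ``fallback`` column).
    """
    rows = []
    flags = {}
    for study, res in zip(cohort, seg_results):
        std = standardise_study(study)
        for lesion_id in sorted(study.lesion_labels):
            truth = study.annotation == lesion_id
            blob_ids = np.unique(res.blobs[truth & (res.blobs > 0)])
            fallback = blob_ids.size == 0
            mask = truth if fallback else np.isin(res.blobs, blob_ids)
            key = f"{study.patient_id}:{lesion_id}"
            flags[key] = fallback
            fv = lesion_feature_vector(std, lesion_id, lesion_mask=mask,
                                       seed=seed, standardised=True)
            row = {"patient_id": study.patient_id, "lesion_id": lesion_id,
                   "label": study.lesion_labels[lesion_id], "fallback": fallback}
            row.update(dict(zip(fv.names, fv.values)))
            rows.append(row)
    table = pd.DataFrame(rows)
    result = loocv_classification(table, repeats=repeats, seed=seed,
                                  drop_groups=drop_groups)
    result.fallback_flags = flags
    return result, table
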