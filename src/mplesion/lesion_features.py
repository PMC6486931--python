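"""Lesion-level features for benign/malignant classification.

Per lesion the extractor assembles:

* the characteristic kinetic curve (CKC): in-lesion signal-time curves are
  fuzzy-c-means clustered and the cluster-centre curve with the highest
  contrast-enhancement rate is retained — 25 time points from contrast
  arrival plus 21 time-normalised four-frame forward differences;
* parameters of the kinetic regression model fitted to the CKC (alpha,
  tau, beta, k) and curve summaries over the 7-min window (AuC, Cmax,
  Tmax, T1/2, MDER);
* Haralick texture: spatial GLCMs of the pre-, peak- and post-contrast
  volumes plus spatio-temporal GLCMs of the (pre, peak), (pre, post) and
  (peak, post) pairs, 13 statistics each;
* the lowest ADC and highest PET fuzzy-cluster centres (5 clusters);
* shape descriptors of the lesion mask.

Every feature carries a modality group tag (DCE / DWI / PET / MORPH) so
ablation experiments can drop whole modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import cluster_extreme_intensity, fuzzy_c_means
from .kinetics import KineticFit, fit_kinetic
from .shape import SHAPE_NAMES, shape_descriptors
from .study import MpStudy, standardise_study
from .texture import HARALICK_NAMES, glcm_3d, haralick13, temporal_glcm

__all__ = [
    "CKC",
    "LesionFeatureVector",
    "LESION_FEATURE_NAMES",
    "LESION_FEATURE_GROUPS",
    "characteristic_kinetic_curve",
    "lesion_feature_vector",
    "cohort_feature_table",
]

N_CKC_POINTS = 25
N_CKC_DIFFS = N_CKC_POINTS - 4    # four-frame forward differences
CKC_CLUSTERS = 5


@dataclass
class CKC:
    """Characteristic kinetic curve of one lesion."""

    values: np.ndarray       # 25 intensities from contrast arrival
    times: np.ndarray        # acquisition times (s), same length
    fallback_mean: bool      # True when clustering was not possible

    def __post_init__(self) -> None:
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must align")

    @property
    def differences(self) -> np.ndarray:
        """Four-frame forward differences, time-normalised (21 values)."""
        v, t = self.values, self.times
        return (v[4:] - v[:-4]) / (t[4:] - t[:-4])


def _enhancement_rate(curve: np.ndarray, times: np.ndarray) -> float:
    """(max - initial) / (time-to-max - t0); the CKC selection criterion."""
    i = int(np.argmax(curve))
    dt = times[i] - times[0]
    if dt <= 0:
        return -np.inf
    return float((curve[i] - curve[0]) / dt)


def characteristic_kinetic_curve(dce: np.ndarray, times: np.ndarray,
                                 lesion_mask: np.ndarray, onset: int,
                                 c: int = CKC_CLUSTERS, seed: int = 0) -> CKC:
    """CKC of a lesion: the fastest-enhancing fuzzy-cluster-centre curve.

    Uses the 25 frames starting at contrast arrival.  Lesions with fewer
    voxels than cluster count fall back to the mean curve with a warning.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    window = slice(onset, onset + N_CKC_POINTS)
    curves = np.asarray(dce, dtype=float)[window][:, lesion_mask].T   # (n_vox, 25)
    t = np.asarray(times, dtype=float)[window]
    if curves.shape[1] != N_CKC_POINTS:
        raise ValueError(
            f"need {onset + N_CKC_POINTS} frames for onset {onset}, have {dce.shape[0]}"
        )
    if curves.shape[0] < c or np.unique(curves, axis=0).shape[0] < c:
        warnings.warn("lesion too small/homogeneous for curve clustering; using mean curve")
        return CKC(values=curves.mean(axis=0), times=t, fallback_mean=True)
    centres, _ = fuzzy_c_means(curves, c=c, seed=seed)
    rates = [_enhancement_rate(centre, t) for centre in centres]
    best = centres[int(np.argmax(rates))]
    return CKC(values=best, times=t, fallback_mean=False)


# ---------------------------------------------------------------------------

def _feature_layout() -> tuple[list[str], list[str]]:
    names, groups = [], []

    def add(block, group):
        for n in block:
            names.append(n)
            groups.append(group)

    add([f"ckc_{i:02d}" for i in range(N_CKC_POINTS)], "DCE")
    add([f"dckc_{i:02d}" for i in range(N_CKC_DIFFS)], "DCE")
    add(["kin_alpha", "kin_tau", "kin_beta", "kin_k"], "DCE")
    add(["kin_auc", "kin_cmax", "kin_tmax", "kin_thalf", "kin_mder"], "DCE")
    for block in ("tex_pre", "tex_peak", "tex_post",
                  "tex_peak_pre", "tex_post_pre", "tex_post_peak"):
        add([f"{block}_{h}" for h in HARALICK_NAMES], "DCE")
    add(["adc_lowest_cluster"], "DWI")
    add(["pet_highest_cluster"], "PET")
    add([f"shape_{s}" for s in SHAPE_NAMES], "MORPH")
    return names, groups


LESION_FEATURE_NAMES, LESION_FEATURE_GROUPS = _feature_layout()


@dataclass
class LesionFeatureVector:
    """Canonically ordered lesion feature vector with group tags."""

    values: np.ndarray
    names: list[str]
    groups: list[str]
    lesion_id: int
    patient_id: str
    label: str | None = None
    kinetic_fit: KineticFit | None = None
    flags: dict[str, bool] | None = None

    def subset(self, drop: set[str]) -> "LesionFeatureVector":
        """Drop whole modality groups (e.g. {"DWI", "PET"})."""
        known = set(self.groups)
        unknown = set(drop) - known
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        keep = [i for i, g in enumerate(self.groups) if g not in drop]
        return LesionFeatureVector(
            values=self.values[keep],
            names=[self.names[i] for i in keep],
            groups=[self.groups[i] for i in keep],
            lesion_id=self.lesion_id,
            patient_id=self.patient_id,
            label=self.label,
            kinetic_fit=self.kinetic_fit,
            flags=self.flags,
        )


def lesion_feature_vector(study: MpStudy, lesion_id: int,
                          lesion_mask: np.ndarray | None = None,
                          seed: int = 0, standardised: bool = False) -> LesionFeatureVector:
    """All lesion-level features of one lesion.

    ``lesion_mask`` overrides the annotation (used when classifying
    automatically segmented blobs); texture is computed on the
    standardised high-resolution volumes, ADC/PET on the raw maps.
    """
    if lesion_mask is None:
        lesion_mask = study.annotation == lesion_id
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise ValueError(f"lesion {lesion_id} has no voxels")
    raw = study
    if not standardised:
        study = standardise_study(study)

    flags: dict[str, bool] = {}
    ckc = characteristic_kinetic_curve(
        study.dce, study.dce_times, lesion_mask, study.enhancement_onset, seed=seed
    )
    flags["ckc_fallback_mean"] = ckc.fallback_mean

    # kinetic fit: times measured from contrast arrival, origin shifted by
    # one frame so t stays strictly positive (t**k with k < 1)
    dt = float(np.diff(ckc.times).mean())
    fit_t = ckc.times - ckc.times[0] + dt
    fit = fit_kinetic(fit_t, ckc.values, seed=seed)
    flags["kinetic_fit_failed"] = not fit.converged

    blocks = [ckc.values, ckc.differences,
              np.array([fit.params.alpha, fit.params.tau, fit.params.beta, fit.params.k]),
              np.array([fit.auc, fit.c_max, fit.t_max, fit.t_half_obs, fit.mder])]

    vols = {"pre": study.dce_pre, "peak": study.dce_peak, "post": study.dce_post}
    for key in ("pre", "peak", "post"):
        h = haralick13(glcm_3d(vols[key], lesion_mask))
        blocks.append(np.array([h[n] for n in HARALICK_NAMES]))
    for a, b in (("pre", "peak"), ("pre", "post"), ("peak", "post")):
        h = haralick13(temporal_glcm(vols[a], vols[b], lesion_mask))
        blocks.append(np.array([h[n] for n in HARALICK_NAMES]))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adc_low = cluster_extreme_intensity(raw.adc, lesion_mask, mode="lowest", seed=seed)
        pet_high = cluster_extreme_intensity(raw.pet, lesion_mask, mode="highest", seed=seed)
    blocks.append(np.array([adc_low]))
    blocks.append(np.array([pet_high]))

    morph = shape_descriptors(lesion_mask, spacing=study.voxel_size)
    blocks.append(np.array([morph[s] for s in SHAPE_NAMES]))

    values = np.concatenate(blocks)
    if values.shape[0] != len(LESION_FEATURE_NAMES):
        raise AssertionError("feature layout drifted from the canonical ordering")
    if not np.all(np.isfinite(values)):
        bad = [LESION_FEATURE_NAMES[i] for i in np.nonzero(~np.isfinite(values))[0]]
        raise ValueError(f"non-finite lesion features: {bad}")
    return LesionFeatureVector(
        values=values,
        names=list(LESION_FEATURE_NAMES),
        groups=list(LESION_FEATURE_GROUPS),
        lesion_id=lesion_id,
        patient_id=study.patient_id,
        label=study.lesion_labels.get(lesion_id),
        kinetic_fit=fit,
        flags=flags,
    )


def cohort_feature_table(cohort: list[MpStudy], seed: int = 0) -> pd.DataFrame:
    """Lesion feature table for a cohort: one row per annotated lesion."""
    rows = []
    for study in cohort:
        std = standardise_study(study)
        for lesion_id in sorted(study.lesion_labels):
            fv = lesion_feature_vector(std, lesion_id, seed=seed, standardised=True)
            row = {"patient_id": study.patient_id, "lesion_id": lesion_id,
                   "label": study.lesion_labels[lesion_id]}
            row.update(dict(zip(fv.names, fv.values)))
            rows.append(row)
    return pd.DataFrame(rows)
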