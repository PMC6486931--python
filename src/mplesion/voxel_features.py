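"""Per-voxel feature matrix for voxel-wise lesion segmentation.

For every voxel x inside the breast mask M the extractor emits 62 named
features in seven groups:

==========  =====================================================  =====
group       definition                                             count
==========  =====================================================  =====
f_dce       DCE intensities I(x, i) for j <= i <= j+25             26
f_ddce      (I(x, i+2) - I(x, i)) / (t_{i+2} - t_i), 25 windows    25
f_nsumdce   sum_{i=j}^{j+25} I(x, i), normalised by its in-mask
            maximum                                                 1
f_mri       pre-, peak-, post-contrast high-resolution values       3
f_dmri      post-pre, peak-pre, post-peak differences               3
f_dwi       b0, b850, ADC values                                    3
f_pet       FDG-PET uptake                                          1
==========  =====================================================  =====

j is the first frame with contrast enhancement.  The forward-difference
index i runs over j..j+24 (25 two-frame windows drawn from the same 26
frames as f_dce).  MRI-derived features are computed on standardised
volumes; DWI and PET are consumed raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study import MpStudy, standardise_study

__all__ = [
    "VoxelFeatureMatrix",
    "MODALITY_GROUPS",
    "detect_enhancement_start",
    "voxel_feature_matrix",
    "feature_subset",
]

N_DCE_FRAMES = 26

#: maps ablation names to the column prefixes they remove
MODALITY_GROUPS = {"DWI": ("f_dwi",), "PET": ("f_pet",)}


def _column_names() -> list[str]:
    cols = [f"f_dce_{i:02d}" for i in range(26)]
    cols += [f"f_ddce_{i:02d}" for i in range(25)]
    cols += ["f_nsumdce"]
    cols += ["f_mri_pre", "f_mri_peak", "f_mri_post"]
    cols += ["f_dmri_post_pre", "f_dmri_peak_pre", "f_dmri_post_peak"]
    cols += ["f_dwi_b0", "f_dwi_b850", "f_dwi_adc"]
    cols += ["f_pet"]
    return cols


COLUMN_NAMES = _column_names()
assert len(COLUMN_NAMES) == 62


@dataclass
class VoxelFeatureMatrix:
    """Feature rows for the in-mask voxels of one study."""

    values: np.ndarray            # (n_voxels, n_features)
    columns: list[str]
    coords: np.ndarray            # (n_voxels, 3) voxel indices (z, y, x)
    patient_id: str

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match value width")
        if self.values.shape[0] != self.coords.shape[0]:
            raise ValueError("coords do not match row count")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["z", "y", "x"])
        return pd.concat([df, pd.DataFrame(self.values, columns=self.columns)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def detect_enhancement_start(dce: np.ndarray, mask: np.ndarray,
                             n_sd: float = 2.0, min_baseline: int = 3) -> int:
    """First frame whose mean in-mask signal exceeds the running baseline.

    The baseline for candidate frame i is the mean and SD of the in-mask
    frame means over frames 0..i-1 (at least ``min_baseline`` frames);
    frame i qualifies when its mean exceeds baseline mean + ``n_sd`` *
    baseline SD (plus a small absolute guard for noise-free data) and the
    next frame confirms the excursion — enhancement is persistent, a noise
    spike is not.  Monotone: adding uniform enhancement from an earlier
    frame can only move the detection earlier.
    """
    mask = np.asarray(mask, dtype=bool)
    means = np.asarray(dce, dtype=float)[:, mask].mean(axis=1)
    n = means.shape[0]
    scale = max(abs(float(means[0])), 1.0)
    for i in range(max(min_baseline, 1), n):
        base = means[:i]
        thr = float(base.mean()) + n_sd * float(base.std()) + 1e-9 * scale
        if means[i] > thr and (i + 1 >= n or means[i + 1] > thr):
            return i
    raise ValueError("no frame exceeds the pre-injection baseline: flat series?")


def voxel_feature_matrix(study: MpStudy, onset: int | None = None,
                         standardised: bool = False) -> VoxelFeatureMatrix:
    """Compute the 62-column voxel feature matrix for one study.

    ``onset`` overrides the study's enhancement-onset frame (e.g. a value
    from :func:`detect_enhancement_start`).  Set ``standardised`` when the
    study's MRI volumes have already been standardised.
    """
    if not standardised:
        study = standardise_study(study)
    j = study.enhancement_onset if onset is None else int(onset)
    if j + N_DCE_FRAMES > study.n_frames:
        raise ValueError(
            f"need {j + N_DCE_FRAMES} DCE frames for onset {j}, study has {study.n_frames}"
        )
    mask = study.breast_mask
    coords = np.argwhere(mask)
    t = study.dce_times

    dce = study.dce[:, mask]                          # (frames, n_voxels)
    f_dce = dce[j:j + 26].T                           # (n, 26)
    # 25 two-frame forward differences; the windows need frames up to
    # j + 26, so the start index is truncated when the series ends at j + 25
    i0 = min(j, study.n_frames - 27)
    if i0 < 0:
        raise ValueError("need at least 27 DCE frames for the difference features")
    idx = np.arange(i0, i0 + 25)
    f_ddce = ((dce[idx + 2] - dce[idx]) / (t[idx + 2] - t[idx])[:, None]).T
    sumdce = f_dce.sum(axis=1)
    max_sum = float(sumdce.max())
    if max_sum <= 0:
        raise ValueError("non-positive in-mask maximum of summed enhancement")
    f_nsum = (sumdce / max_sum)[:, None]

    f_mri = np.stack([study.dce_pre[mask], study.dce_peak[mask], study.dce_post[mask]], axis=1)
    f_dmri = np.stack(
        [
            study.dce_post[mask] - study.dce_pre[mask],
            study.dce_peak[mask] - study.dce_pre[mask],
            study.dce_post[mask] - study.dce_peak[mask],
        ],
        axis=1,
    )
    f_dwi = np.stack([study.dwi_b0[mask], study.dwi_b850[mask], study.adc[mask]], axis=1)
    f_pet = study.pet[mask][:, None]

    values = np.hstack([f_dce, f_ddce, f_nsum, f_mri, f_dmri, f_dwi, f_pet])
    return VoxelFeatureMatrix(values=values, columns=list(COLUMN_NAMES),
                              coords=coords, patient_id=study.patient_id)


def feature_subset(matrix: VoxelFeatureMatrix, drop: set[str] | frozenset[str]) -> VoxelFeatureMatrix:
    """Remove whole modality groups (modality-ablation experiments).

    ``drop`` is a subset of {"DWI", "PET"}; DCE-MRI features are always
    retained.
    """
    drop = set(drop)
    unknown = drop - set(MODALITY_GROUPS)
    if unknown:
        raise ValueError(f"unknown modalities {sorted(unknown)}; choose from {sorted(MODALITY_GROUPS)}")
    prefixes = tuple(p for m in drop for p in MODALITY_GROUPS[m])
    keep = [i for i, c in enumerate(matrix.columns) if not c.startswith(prefixes)]
    return VoxelFeatureMatrix(
        values=matrix.values[:, keep],
        columns=[matrix.columns[i] for i in keep],
        coords=matrix.coords,
        patient_id=matrix.patient_id,
    )
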