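"""Multiparametric study container, NIfTI I/O and intensity preprocessing.

An :class:`MpStudy` holds one patient's co-registered volumes on a single
reference grid: the DCE-MRI time series with per-frame acquisition times,
the three high-resolution volumes (pre-, peak-, post-contrast), DWI
(b0/b850) with the derived ADC map, the FDG-PET volume, the breast mask and
the voxel-wise lesion annotation.  Axis order is (z, y, x) for volumes and
(frame, z, y, x) for the 4-D series; voxel indices are 0-based and the
NIfTI affine is respected on I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "MpStudy",
    "StudyValidationError",
    "read_study",
    "write_study",
    "resample_to_reference",
    "grow_breast_mask",
    "standardise",
    "standardise_dce",
    "standardise_study",
]

#: scalar volumes and the dtype contract of the container
_VOLUME_ROLES = ("dce_pre", "dce_peak", "dce_post", "dwi_b0", "dwi_b850", "adc", "pet")


class StudyValidationError(ValueError):
    """Raised when a study violates the co-registration / shape contract."""


@dataclass
class MpStudy:
    """One patient's co-registered multiparametric volumes.

    ``lesion_labels`` maps annotation label value -> class name
    ("benign" | "malignant"); ``enhancement_onset`` is the index of the
    first DCE frame with contrast enhancement.
    """

    patient_id: str
    dce: np.ndarray                  # (n_frames, z, y, x)
    dce_times: np.ndarray            # seconds, per frame
    dce_pre: np.ndarray
    dce_peak: np.ndarray
    dce_post: np.ndarray
    dwi_b0: np.ndarray
    dwi_b850: np.ndarray
    adc: np.ndarray
    pet: np.ndarray
    breast_mask: np.ndarray          # bool
    annotation: np.ndarray           # int labels, 0 = background
    lesion_labels: dict[int, str] = field(default_factory=dict)
    enhancement_onset: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.breast_mask = np.asarray(self.breast_mask).astype(bool)
        self.annotation = np.asarray(self.annotation).astype(np.int32)
        self.dce_times = np.asarray(self.dce_times, dtype=float)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        shape = self.dce.shape[1:]
        for role in _VOLUME_ROLES + ("breast_mask", "annotation"):
            vol = getattr(self, role)
            if vol.shape != shape:
                raise StudyValidationError(
                    f"volume '{role}' has shape {vol.shape}, expected {shape}"
                )
        if self.dce_times.shape[0] != self.dce.shape[0]:
            raise StudyValidationError("dce_times length does not match frame count")
        if np.any(np.diff(self.dce_times) <= 0):
            raise StudyValidationError("dce acquisition times must be strictly increasing")
        if self.enhancement_onset + 25 >= self.dce.shape[0]:
            raise StudyValidationError(
                f"need >= {self.enhancement_onset + 26} DCE frames for the 26-frame "
                f"feature window, got {self.dce.shape[0]}"
            )
        if np.any(self.annotation.astype(bool) & ~self.breast_mask):
            raise StudyValidationError("annotation contains voxels outside the breast mask")
        for label in np.unique(self.annotation):
            if label and int(label) not in self.lesion_labels:
                raise StudyValidationError(f"annotation label {label} has no class entry")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dce.shape[1:]

    @property
    def n_frames(self) -> int:
        return self.dce.shape[0]

    def lesion_mask(self, lesion_id: int) -> np.ndarray:
        return self.annotation == lesion_id

    def copy(self) -> "MpStudy":
        kw = {
            k: (v.copy() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        kw["lesion_labels"] = dict(self.lesion_labels)
        return MpStudy(**kw)


# -- NIfTI I/O ------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    aff = np.diag([voxel_size[2], voxel_size[1], voxel_size[0], 1.0])
    return aff


def write_study(study: MpStudy, out_dir) -> Path:
    """Write one NIfTI file per volume plus a JSON manifest; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_size)

    def save(name: str, data: np.ndarray) -> str:
        fname = f"{name}.nii.gz"
        # store as (x, y, z[, t]) per NIfTI convention
        arr = np.asarray(data)
        if arr.ndim == 4:
            arr = np.transpose(arr, (3, 2, 1, 0))
        else:
            arr = np.transpose(arr, (2, 1, 0))
        nib.save(nib.Nifti1Image(arr.astype(np.float32), aff), out / fname)
        return fname

    manifest = {
        "patient_id": study.patient_id,
        "voxel_size_mm": list(study.voxel_size),
        "dce_times_s": study.dce_times.tolist(),
        "enhancement_onset": int(study.enhancement_onset),
        "lesion_labels": {str(k): v for k, v in study.lesion_labels.items()},
        "volumes": {},
    }
    manifest["volumes"]["dce"] = save("dce", study.dce)
    for role in _VOLUME_ROLES:
        manifest["volumes"][role] = save(role, getattr(study, role))
    manifest["volumes"]["breast_mask"] = save("breast_mask", study.breast_mask.astype(np.float32))
    manifest["volumes"]["annotation"] = save("annotation", study.annotation.astype(np.float32))
    (out / "study.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_study(study_dir) -> MpStudy:
    """Read a study directory written by :func:`write_study`.

    Raises ``FileNotFoundError`` for missing volumes and
    :class:`StudyValidationError` for grid mismatches, naming the offending
    volume.
    """
    d = Path(study_dir)
    manifest_path = d / "study.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no study manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())

    def load(role: str, ndim: int) -> np.ndarray:
        fname = manifest["volumes"].get(role)
        if fname is None or not (d / fname).exists():
            raise FileNotFoundError(f"study volume '{role}' missing from {d}")
        arr = np.asarray(nib.load(d / fname).dataobj, dtype=np.float64)
        if arr.ndim != ndim:
            raise StudyValidationError(f"volume '{role}' has {arr.ndim} dims, expected {ndim}")
        if ndim == 4:
            return np.transpose(arr, (3, 2, 1, 0))
        return np.transpose(arr, (2, 1, 0))

    kwargs = dict(
        patient_id=manifest["patient_id"],
        dce=load("dce", 4),
        dce_times=np.asarray(manifest["dce_times_s"], dtype=float),
        voxel_size=tuple(manifest["voxel_size_mm"]),
        enhancement_onset=int(manifest["enhancement_onset"]),
        lesion_labels={int(k): v for k, v in manifest["lesion_labels"].items()},
    )
    for role in _VOLUME_ROLES:
        kwargs[role] = load(role, 3)
    kwargs["breast_mask"] = load("breast_mask", 3) > 0.5
    kwargs["annotation"] = np.rint(load("annotation", 3)).astype(np.int32)
    return MpStudy(**kwargs)


# -- resampling -----------------------------------------------------------

def resample_to_reference(volume, affine, reference_shape, reference_affine, order="linear"):
    """Resample a volume onto a reference grid.

    ``affine``/``reference_affine`` map voxel indices (z, y, x, 1) to
    physical millimetres.  ``order`` is "nearest" or "linear"; linear
    interpolation preserves constant volumes exactly.
    """
    if order not in ("nearest", "linear"):
        raise ValueError(f"order must be 'nearest' or 'linear', got {order!r}")
    affine = np.asarray(affine, dtype=float)
    reference_affine = np.asarray(reference_affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular source affine")
    vol = np.asarray(volume, dtype=float)
    # voxel->voxel map: src_idx = inv(A_src) @ A_ref @ ref_idx
    m = np.linalg.inv(affine) @ reference_affine
    idx = np.indices(reference_shape, dtype=float).reshape(3, -1)
    src = m[:3, :3] @ idx + m[:3, 3:4]
    out = ndimage.map_coordinates(
        vol, src, order=0 if order == "nearest" else 1, mode="nearest"
    )
    return out.reshape(reference_shape)


# -- breast mask ----------------------------------------------------------

def grow_breast_mask(pre: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Segment the breast from the pre-contrast volume by region growing.

    Intensity-based: an Otsu threshold separates tissue from background
    air, the seed is placed at the brightest voxel of the largest
    above-threshold component, and the region is grown 6-connected over
    voxels whose intensity exceeds the threshold.
    """
    pre = np.asarray(pre, dtype=float)
    if not np.all(np.isfinite(pre)):
        raise ValueError("pre-contrast volume must be finite")
    if np.ptp(pre) == 0:
        raise ValueError("constant volume: cannot derive a breast mask, supply one manually")
    thr = float(threshold_otsu(pre)) if threshold is None else float(threshold)
    above = pre > thr
    if not above.any():
        raise ValueError("no voxels above threshold: supply a manual mask")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(above, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    comp = labels == largest
    seed = np.unravel_index(np.argmax(np.where(comp, pre, -np.inf)), pre.shape)
    # growing from the seed over the above-threshold set == the seed's
    # 6-connected component of that set
    mask = labels == labels[seed]
    if not mask.any():
        raise ValueError("region growing produced an empty mask")
    return mask


# -- standardisation ------------------------------------------------------

def standardise(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Affine-map a volume to zero mean / unit SD inside the mask.

    The mean and SD are estimated from in-mask voxels only; the same affine
    map is applied to the whole volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least two voxels")
    vals = np.asarray(volume, dtype=float)[mask]
    sd = float(vals.std())
    if sd == 0:
        raise ValueError("zero variance inside mask: cannot standardise")
    return (np.asarray(volume, dtype=float) - float(vals.mean())) / sd


def standardise_dce(dce: np.ndarray, mask: np.ndarray, onset: int) -> np.ndarray:
    """Standardise a 4-D DCE series from pre-contrast statistics.

    Mean/SD are pooled over the in-mask voxels of the frames before
    ``onset`` and one shared affine map is applied to every frame, so the
    inter-frame enhancement contrast is preserved.
    """
    if onset < 1:
        raise ValueError("need at least one pre-contrast frame")
    mask = np.asarray(mask, dtype=bool)
    dce = np.asarray(dce, dtype=float)
    baseline = dce[:onset][:, mask]
    sd = float(baseline.std())
    if sd == 0:
        # noiseless baseline (e.g. an ideal phantom): centre on the baseline
        # and take the scale from the enhanced frames instead
        sd = float(dce[:, mask].std())
    if sd == 0:
        raise ValueError("zero variance in the DCE series: cannot standardise")
    return (dce - float(baseline.mean())) / sd


def standardise_study(study: MpStudy) -> MpStudy:
    """Return a copy with MRI volumes standardised from breast-area statistics.

    The DCE series uses pooled pre-contrast-frame statistics, and the three
    high-resolution volumes share the affine map derived from the
    pre-contrast volume, so peak and post keep their enhancement offset
    relative to pre.  DWI, ADC and PET are left on their native scales.
    """
    out = study.copy()
    out.dce = standardise_dce(study.dce, study.breast_mask, study.enhancement_onset)
    vals = np.asarray(study.dce_pre, dtype=float)[study.breast_mask]
    mean, sd = float(vals.mean()), float(vals.std())
    if sd == 0:
        # flat pre-contrast volume: fall back to the pooled pre/peak/post scale
        pooled = np.concatenate(
            [np.asarray(getattr(study, r), dtype=float)[study.breast_mask]
             for r in ("dce_pre", "dce_peak", "dce_post")]
        )
        sd = float(pooled.std())
    if sd == 0:
        raise ValueError("zero variance in the high-resolution volumes: cannot standardise")
    for role in ("dce_pre", "dce_peak", "dce_post"):
        setattr(out, role, (np.asarray(getattr(study, role), dtype=float) - mean) / sd)
    return out
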