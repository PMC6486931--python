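"""Synthetic multiparametric phantom cohort with known ground truth.

Each phantom patient is a breast-shaped (ellipsoidal) tissue volume on a
small isotropic grid containing one or more spherical lesions and,
optionally, tube-shaped enhancing vessels as false-positive distractors.
Lesion voxels follow a class-specific contrast-enhancement time course of
the kinetic model in :mod:`mplesion.kinetics`:

* malignant lesions — fast wash-in (small t_half, steep tau) followed by
  washout (beta < 0), reduced ADC and elevated FDG uptake;
* benign lesions — slow persistent enhancement (large t_half, beta = 0),
  mildly reduced ADC and modest uptake.

DWI b0/b850 are produced from the ADC map by the mono-exponential decay
S(b) = S0 * exp(-b * ADC).  The high-resolution pre/peak/post volumes are
frames of the same kinetic model at baseline, at the lesion enhancement
peak, and at the end of the acquisition.  Additive Gaussian noise is the
only noise source, and the cohort is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import KineticParams, SUMMARY_WINDOW_S, curve_summaries, enhancement_curve
from .study import MpStudy, write_study

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "MALIGNANT_PRIORS",
    "BENIGN_PRIORS",
    "VESSEL_KINETICS",
    "make_study",
    "make_cohort",
    "embed_vessels",
    "write_cohort",
]

# per-class priors over (G, alpha, tau, t_half, beta, k): (low, high) of a
# uniform draw.  G is relative to the tissue baseline of 100.  Chosen for
# class separability: malignant curves reach half maximum early and wash
# out; benign curves rise slowly and persist.
MALIGNANT_PRIORS: dict[str, tuple[float, float]] = {
    "G": (120.0, 180.0),
    "alpha": (0.8, 1.5),
    "tau": (8.0, 18.0),
    "t_half": (35.0, 70.0),
    "beta": (-8e-4, -3e-4),
    "k": (1.0, 1.0),
}
BENIGN_PRIORS: dict[str, tuple[float, float]] = {
    "G": (60.0, 110.0),
    "alpha": (0.8, 1.5),
    "tau": (35.0, 60.0),
    "t_half": (150.0, 230.0),
    "beta": (0.0, 0.0),
    "k": (1.0, 1.0),
}
#: vessels enhance fast (blood pool) but carry background ADC / PET.
VESSEL_KINETICS = KineticParams(G=140.0, alpha=1.0, tau=6.0, t_half=25.0, beta=-5e-4, k=1.0)

_BASELINE = 100.0          # arbitrary tissue signal units
_ADC_BACKGROUND = 1.8e-3   # mm^2/s
_PET_BACKGROUND = 0.5      # arbitrary uptake units


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, kinetics and noise of the synthetic cohort."""

    n_patients: int = 8
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)   # mm
    n_frames: int = 32
    frame_interval: float = 13.2                                # seconds
    enhancement_onset_frame: int = 6
    lesions_per_patient: int = 1
    lesion_radius_range: tuple[float, float] = (5.0, 9.0)       # mm
    class_mix: float = 0.5                                      # fraction malignant
    kinetic_priors: dict = field(
        default_factory=lambda: {"malignant": MALIGNANT_PRIORS, "benign": BENIGN_PRIORS}
    )
    adc_levels: dict = field(
        default_factory=lambda: {
            "malignant": 0.9e-3, "benign": 1.4e-3, "background": _ADC_BACKGROUND,
        }
    )
    pet_levels: dict = field(
        default_factory=lambda: {
            "malignant": 4.0, "benign": 1.2, "background": _PET_BACKGROUND,
        }
    )
    vessel_count: int = 2
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < self.enhancement_onset_frame + 26:
            raise ValueError(
                "n_frames must be >= enhancement_onset_frame + 26 so the 26-frame "
                "feature window exists"
            )
        if not 0.0 <= self.class_mix <= 1.0:
            raise ValueError("class_mix must lie in [0, 1]")
        if min(self.lesion_radius_range) <= 0:
            raise ValueError("lesion radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Known lesion geometry, class and kinetics of one phantom patient."""

    lesion_masks: np.ndarray                    # label volume, 0 = background
    lesion_classes: dict[int, str]
    kinetic_params: dict[int, KineticParams]
    breast_mask: np.ndarray
    lesion_centres: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    lesion_radii_vox: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.lesion_masks)) - {0}
        for lesion_id in self.lesion_classes:
            if lesion_id not in present:
                raise ValueError(f"lesion {lesion_id} has no voxels in the label volume")


def draw_kinetic_params(priors: dict[str, tuple[float, float]], rng: np.random.Generator) -> KineticParams:
    vals = {name: rng.uniform(lo, hi) for name, (lo, hi) in priors.items()}
    return KineticParams(**{"G": vals["G"], "alpha": vals["alpha"], "tau": vals["tau"],
                            "t_half": vals["t_half"], "beta": vals["beta"], "k": vals["k"]})


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Breast stand-in: an ellipsoid filling ~80% of each axis."""
    zz, yy, xx = np.indices(shape, dtype=float)
    c = [(s - 1) / 2.0 for s in shape]
    r = [0.42 * s for s in shape]
    d = ((zz - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + ((xx - c[2]) / r[2]) ** 2
    return d <= 1.0


def _sphere_mask(shape, centre, radius_vox) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=float)
    d2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    return d2 <= radius_vox**2


def _tube_mask(shape, p0, p1, radius_vox) -> np.ndarray:
    """Voxels within radius of the segment p0-p1 (a straight vessel)."""
    zz, yy, xx = np.indices(shape, dtype=float)
    p = np.stack([zz, yy, xx], axis=-1)
    a = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - a
    denom = float(d @ d)
    t = ((p - a) @ d) / denom if denom > 0 else np.zeros(shape)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * d
    dist2 = np.sum((p - closest) ** 2, axis=-1)
    return dist2 <= radius_vox**2


def _place_lesions(config: PhantomConfig, breast: np.ndarray, rng: np.random.Generator):
    """Non-overlapping spheres fully inside the breast; returns label volume."""
    shape = config.grid_shape
    vox = float(config.voxel_size[0])
    labels = np.zeros(shape, dtype=np.int32)
    centres = []
    geometry: dict[int, tuple[tuple[float, float, float], float]] = {}
    for lesion_id in range(1, config.lesions_per_patient + 1):
        radius_mm = rng.uniform(*config.lesion_radius_range)
        r_vox = radius_mm / vox
        if 2 * r_vox + 2 > min(shape):
            raise ValueError(
                f"grid {shape} too small for lesion radius {radius_mm:.1f} mm"
            )
        for _ in range(200):
            centre = np.array([rng.uniform(r_vox + 1, s - r_vox - 2) for s in shape])
            sphere = _sphere_mask(shape, centre, r_vox)
            inside = breast[sphere].all()
            clear = all(np.linalg.norm(centre - c) > r_vox + rp + 2 for c, rp in centres)
            if inside and clear and not (labels[sphere] > 0).any():
                labels[sphere] = lesion_id
                centres.append((centre, r_vox))
                geometry[lesion_id] = (tuple(float(c) for c in centre), float(r_vox))
                break
        else:
            raise ValueError("could not place a lesion inside the breast; grid too small")
    return labels, geometry


def make_study(config: PhantomConfig, patient_index: int, seed: int) -> tuple[MpStudy, GroundTruth]:
    """Generate one phantom patient (deterministic in (config, seed, index))."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, patient_index]))
    shape = config.grid_shape
    breast = _ellipsoid_mask(shape)
    labels, geometry = _place_lesions(config, breast, rng)

    # class assignment: deterministic round-robin against class_mix keeps the
    # cohort composition at the configured fraction
    lesion_ids = sorted(set(np.unique(labels)) - {0})
    classes: dict[int, str] = {}
    params: dict[int, KineticParams] = {}
    for lesion_id in lesion_ids:
        malignant = rng.random() < config.class_mix
        cls = "malignant" if malignant else "benign"
        classes[lesion_id] = cls
        params[lesion_id] = draw_kinetic_params(config.kinetic_priors[cls], rng)

    times = config.frame_times
    onset_t = times[config.enhancement_onset_frame]

    # DCE series: tissue baseline plus per-lesion enhancement after onset
    dce = np.full((config.n_frames,) + shape, 0.0)
    dce += np.where(breast, _BASELINE, 0.0)
    enh_t = np.clip(times - onset_t, 0.0, None)
    for lesion_id in lesion_ids:
        curve = enhancement_curve(params[lesion_id], enh_t)
        curve[times < onset_t] = 0.0
        mask = labels == lesion_id
        dce[:, mask] += curve[:, None]

    # high-resolution frames: baseline, per-lesion peak, end of acquisition
    dce_pre = np.where(breast, _BASELINE, 0.0)
    dce_peak = dce_pre.copy()
    dce_post = dce_pre.copy()
    t_end = float(enh_t[-1])
    for lesion_id in lesion_ids:
        s = curve_summaries(params[lesion_id], window=min(SUMMARY_WINDOW_S, t_end))
        mask = labels == lesion_id
        dce_peak[mask] += float(s["Cmax"])
        dce_post[mask] += float(enhancement_curve(params[lesion_id], [t_end])[0])

    # ADC and PET: class-dependent plateaus inside lesions
    adc = np.where(breast, config.adc_levels["background"], 0.0)
    pet = np.where(breast, config.pet_levels["background"], 0.0)
    for lesion_id in lesion_ids:
        mask = labels == lesion_id
        adc[mask] = config.adc_levels[classes[lesion_id]]
        pet[mask] = config.pet_levels[classes[lesion_id]]

    # DWI from ADC by mono-exponential decay
    s0 = np.where(breast, _BASELINE, 0.0)
    dwi_b0 = s0.copy()
    dwi_b850 = s0 * np.exp(-850.0 * adc)

    study = MpStudy(
        patient_id=f"phantom-{patient_index:03d}",
        dce=dce,
        dce_times=times,
        dce_pre=dce_pre,
        dce_peak=dce_peak,
        dce_post=dce_post,
        dwi_b0=dwi_b0,
        dwi_b850=dwi_b850,
        adc=adc,
        pet=pet,
        breast_mask=breast,
        annotation=labels,
        lesion_labels=classes,
        enhancement_onset=config.enhancement_onset_frame,
        voxel_size=config.voxel_size,
    )
    truth = GroundTruth(
        lesion_masks=labels.copy(),
        lesion_classes=dict(classes),
        kinetic_params=dict(params),
        breast_mask=breast.copy(),
        lesion_centres={k: v[0] for k, v in geometry.items()},
        lesion_radii_vox={k: v[1] for k, v in geometry.items()},
    )
    if config.vessel_count > 0:
        study = embed_vessels(study, config, rng)
    if config.noise_sd > 0:
        study = _add_noise(study, config.noise_sd, rng)
    return study, truth


def embed_vessels(study: MpStudy, config: PhantomConfig,
                  rng: np.random.Generator | None = None) -> MpStudy:
    """Add tube-shaped enhancing distractors inside the breast mask.

    Vessels enhance in the DCE series (blood-pool kinetics) but keep
    background-level ADC and PET, and are excluded from the annotation —
    they exist to exercise false-positive post-processing.
    """
    if config.vessel_count == 0:
        return study
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = study.copy()
    shape = out.shape
    times = out.dce_times
    onset_t = times[out.enhancement_onset]
    enh_t = np.clip(times - onset_t, 0.0, None)
    curve = enhancement_curve(VESSEL_KINETICS, enh_t)
    curve[times < onset_t] = 0.0
    t_end = float(enh_t[-1])
    s = curve_summaries(VESSEL_KINETICS, window=min(SUMMARY_WINDOW_S, t_end))

    lesion_dilated = _dilate(out.annotation > 0, 2)
    placed = 0
    attempts = 0
    vessel_all = np.zeros(shape, dtype=bool)
    while placed < config.vessel_count and attempts < 500:
        attempts += 1
        axis = rng.integers(0, 3)
        p0 = np.array([rng.uniform(4, s_ - 5) for s_ in shape], dtype=float)
        p1 = p0.copy()
        p1[axis] = shape[axis] - 5.0
        p0[axis] = 4.0
        tube = _tube_mask(shape, p0, p1, radius_vox=1.2) & out.breast_mask
        if tube.any():
            # clipping at the breast edge can shear off diagonal fragments;
            # keep the main 6-connected piece only
            from scipy import ndimage

            lab, nlab = ndimage.label(tube, structure=ndimage.generate_binary_structure(3, 1))
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
            tube = lab == (int(np.argmax(sizes)) + 1)
        if tube.sum() < 15:
            continue
        if (tube & (lesion_dilated | _dilate(vessel_all, 1))).any():
            continue
        out.dce[:, tube] += curve[:, None]
        out.dce_peak[tube] += float(s["Cmax"])
        out.dce_post[tube] += float(enhancement_curve(VESSEL_KINETICS, [t_end])[0])
        vessel_all |= tube
        placed += 1
    if placed < config.vessel_count:
        raise ValueError("could not place the requested number of vessels")
    return out


def _dilate(mask: np.ndarray, it: int) -> np.ndarray:
    from scipy import ndimage

    if not mask.any():
        return mask.copy()
    return ndimage.binary_dilation(mask, iterations=it)


def _add_noise(study: MpStudy, sd: float, rng: np.random.Generator) -> MpStudy:
    out = study.copy()
    for role in ("dce_pre", "dce_peak", "dce_post", "dwi_b0", "dwi_b850", "pet"):
        vol = getattr(out, role)
        scale = sd if role not in ("pet",) else sd * _PET_BACKGROUND / _BASELINE
        setattr(out, role, vol + rng.normal(0.0, scale, vol.shape))
    out.dce = out.dce + rng.normal(0.0, sd, out.dce.shape)
    out.adc = out.adc + rng.normal(0.0, sd * _ADC_BACKGROUND / _BASELINE, out.adc.shape)
    return out


def make_cohort(config: PhantomConfig) -> list[tuple[MpStudy, GroundTruth]]:
    """Generate the full phantom cohort; bit-identical under (config, seed)."""
    return [make_study(config, i, config.seed) for i in range(config.n_patients)]


def write_cohort(cohort, out_dir) -> list[Path]:
    """Write each study as NIfTI volumes plus a JSON ground-truth sidecar."""
    import json

    out = Path(out_dir)
    paths = []
    for study, truth in cohort:
        d = write_study(study, out / study.patient_id)
        sidecar = {
            "lesion_classes": {str(k): v for k, v in truth.lesion_classes.items()},
            "kinetic_params": {
                str(k): dict(zip(("G", "alpha", "tau", "t_half", "beta", "k"),
                                 p.as_array().tolist()))
                for k, p in truth.kinetic_params.items()
            },
        }
        (d / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
        paths.append(d)
    return paths
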