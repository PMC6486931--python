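"""Study container, NIfTI round-trips, resampling, mask growing, standardisation."""

import numpy as np
import pytest

import mplesion as mp
from mplesion.study import StudyValidationError

from conftest import toy_study


def test_write_read_roundtrip(clean_study, tmp_path):
    _, study, _ = clean_study
    mp.write_study(study, tmp_path / "p0")
    back = mp.read_study(tmp_path / "p0")
    assert back.patient_id == study.patient_id
    assert np.allclose(back.dce, study.dce, atol=1e-4)
    assert np.allclose(back.adc, study.adc, atol=1e-7)
    assert np.array_equal(back.breast_mask, study.breast_mask)
    assert np.array_equal(back.annotation, study.annotation)
    assert back.lesion_labels == study.lesion_labels
    assert np.allclose(back.dce_times, study.dce_times)


def test_missing_volume_reported(clean_study, tmp_path):
    _, study, _ = clean_study
    d = mp.write_study(study, tmp_path / "p1")
    (d / "adc.nii.gz").unlink()
    with pytest.raises(FileNotFoundError, match="adc"):
        mp.read_study(d)


def test_nonincreasing_times_rejected():
    study = toy_study()
    times = study.dce_times.copy()
    times[5] = times[4]
    with pytest.raises(StudyValidationError, match="increasing"):
        mp.MpStudy(**{**study.__dict__, "dce_times": times})


def test_shape_mismatch_names_volume():
    study = toy_study()
    with pytest.raises(StudyValidationError, match="pet"):
        mp.MpStudy(**{**study.__dict__, "pet": np.zeros((3, 3, 3))})


def test_annotation_outside_mask_rejected():
    study = toy_study()
    mask = study.breast_mask.copy()
    mask[2:4, 2:4, 2:4] = False   # annotation voxels now outside
    with pytest.raises(StudyValidationError, match="outside"):
        mp.MpStudy(**{**study.__dict__, "breast_mask": mask})


# -- resampling -----------------------------------------------------------

def _affine(spacing):
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def test_resample_constant_preserved():
    vol = np.full((8, 8, 8), 3.7)
    out = mp.resample_to_reference(vol, _affine((1, 1, 1)), (5, 5, 5), _affine((1.3, 1.3, 1.3)))
    assert np.allclose(out, 3.7)


def test_resample_identity():
    rng = np.random.default_rng(1)
    vol = rng.random((6, 7, 8))
    out = mp.resample_to_reference(vol, _affine((1, 1, 1)), vol.shape, _affine((1, 1, 1)))
    assert np.allclose(out, vol)


def test_resample_downsampled_ramp():
    """Linear resampling of a linear ramp returns the ramp at new centres."""
    z = np.arange(16, dtype=float)
    vol = np.broadcast_to(z[:, None, None], (16, 4, 4)).copy()
    out = mp.resample_to_reference(vol, _affine((1, 1, 1)), (8, 4, 4), _affine((2, 1, 1)))
    # reference voxel i sits at physical z = 2 i -> value 2 i
    expected = 2.0 * np.arange(8, dtype=float)
    assert np.allclose(out[:, 0, 0], expected)


def test_resample_rejects_singular_affine():
    with pytest.raises(ValueError, match="singular"):
        mp.resample_to_reference(np.zeros((4, 4, 4)), np.zeros((4, 4)), (4, 4, 4), np.eye(4))


# -- breast mask ----------------------------------------------------------

def test_grow_breast_mask_recovers_phantom(clean_study):
    _, study, truth = clean_study
    mask = mp.grow_breast_mask(study.dce_pre)
    assert np.array_equal(mask, truth.breast_mask)


def test_grow_breast_mask_rejects_flat_volume():
    with pytest.raises(ValueError):
        mp.grow_breast_mask(np.zeros((8, 8, 8)))


def test_grow_breast_mask_is_six_connected():
    # two bright cubes touching only at a corner: the seed's component wins
    vol = np.zeros((8, 8, 8))
    vol[1:4, 1:4, 1:4] = 10.0
    vol[4:7, 4:7, 4:7] = 5.0
    mask = mp.grow_breast_mask(vol, threshold=1.0)
    assert mask[2, 2, 2] and not mask[5, 5, 5]


# -- standardisation ------------------------------------------------------

def test_standardise_mean_zero_unit_sd():
    rng = np.random.default_rng(2)
    vol = rng.normal(50, 7, (10, 10, 10))
    mask = np.zeros(vol.shape, dtype=bool)
    mask[2:8, 2:8, 2:8] = True
    out = mp.standardise(vol, mask)
    assert abs(out[mask].mean()) < 1e-9
    assert abs(out[mask].std() - 1) < 1e-9


def test_standardise_idempotent_and_affine_invariant():
    rng = np.random.default_rng(3)
    vol = rng.normal(0, 1, (6, 6, 6))
    mask = np.ones(vol.shape, dtype=bool)
    once = mp.standardise(vol, mask)
    assert np.allclose(mp.standardise(once, mask), once)
    assert np.allclose(mp.standardise(10.0 * vol + 3.0, mask), once)


def test_standardise_rejects_constant():
    with pytest.raises(ValueError):
        mp.standardise(np.ones((4, 4, 4)), np.ones((4, 4, 4), dtype=bool))


def test_dce_standardisation_preserves_interframe_contrast(seg_cohort):
    """One shared affine map: frame differences are only rescaled."""
    study = seg_cohort[1][0][0]
    out = mp.standardise_dce(study.dce, study.breast_mask, study.enhancement_onset)
    raw_diff = study.dce[20] - study.dce[10]
    std_diff = out[20] - out[10]
    nz = np.abs(raw_diff) > 1e-12
    ratios = std_diff[nz] / raw_diff[nz]
    assert np.allclose(ratios, ratios.flat[0])
    # pre-contrast frames are centred at zero
    base = out[: study.enhancement_onset][:, study.breast_mask]
    assert abs(base.mean()) < 1e-9
    assert abs(base.std() - 1) < 1e-9
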