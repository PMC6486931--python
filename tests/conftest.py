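"""Shared phantom fixtures (generated once per session, fully seeded)."""

import numpy as np
import pytest

import mplesion as mp


@pytest.fixture(scope="session")
def clean_study():
    """One noise-free, vessel-free phantom patient with a malignant lesion."""
    cfg = mp.PhantomConfig(n_patients=1, noise_sd=0.0, vessel_count=0, class_mix=1.0, seed=3)
    study, truth = mp.make_cohort(cfg)[0]
    return cfg, study, truth


@pytest.fixture(scope="session")
def seg_cohort():
    """Eight-patient high-contrast cohort for segmentation experiments."""
    cfg = mp.PhantomConfig(n_patients=8, seed=7)
    return cfg, mp.make_cohort(cfg)


@pytest.fixture(scope="session")
def cls_cohort():
    """Thirty single-lesion patients with a balanced class mix."""
    cfg = mp.PhantomConfig(n_patients=30, vessel_count=0, seed=11)
    return cfg, mp.make_cohort(cfg)


@pytest.fixture(scope="session")
def cls_table(cls_cohort):
    _, cohort = cls_cohort
    return mp.cohort_feature_table([s for s, _ in cohort], seed=0)


def toy_study(shape=(6, 6, 6), n_frames=33, onset=3, dt=13.2, baseline=10.0):
    """Hand-built minimal study: constant tissue, one 2-voxel-radius lesion."""
    mask = np.ones(shape, dtype=bool)
    ann = np.zeros(shape, dtype=np.int32)
    ann[2:4, 2:4, 2:4] = 1
    times = np.arange(n_frames) * dt
    rng = np.random.default_rng(0)
    # spatial structure but no temporal change: every frame is the same map
    vol = baseline + rng.normal(0, 1.0, shape)
    dce = np.broadcast_to(vol, (n_frames,) + shape).copy()
    return mp.MpStudy(
        patient_id="toy",
        dce=dce,
        dce_times=times,
        dce_pre=vol + rng.normal(0, 0.1, shape),
        dce_peak=vol + rng.normal(0, 0.1, shape),
        dce_post=vol + rng.normal(0, 0.1, shape),
        dwi_b0=vol.copy(),
        dwi_b850=vol * 0.5,
        adc=np.full(shape, 1.5e-3),
        pet=np.full(shape, 0.7),
        breast_mask=mask,
        annotation=ann,
        lesion_labels={1: "benign"},
        enhancement_onset=onset,
        voxel_size=(1.0, 1.0, 1.0),
    )
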