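"""GLCM construction and Haralick statistics against brute-force oracles."""

import numpy as np
import pytest

from mplesion.texture import HARALICK_NAMES, glcm_3d, haralick13, temporal_glcm
from mplesion.texture import CoocMatrix


# -- independent oracles --------------------------------------------------

def brute_spatial_glcm(volume, mask, bins):
    """Exhaustive 26-neighbour pair enumeration (the slow reference)."""
    vals = volume[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        q = np.zeros_like(volume, dtype=int)
    else:
        q = np.clip(((volume - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    counts = np.zeros((bins, bins))
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    shape = volume.shape
    for idx in np.argwhere(mask):
        for off in offsets:
            nb = idx + off
            if np.all(nb >= 0) and np.all(nb < shape) and mask[tuple(nb)]:
                counts[q[tuple(idx)], q[tuple(nb)]] += 1
    return counts


def brute_haralick(p):
    """Textbook loop-based recomputation of the 13 statistics."""
    n = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    energy = contrast = corr = var = homog = ent = 0.0
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            energy += v * v
            contrast += (i - j) ** 2 * v
            var += (i - mu_x) ** 2 * v
            homog += v / (1 + (i - j) ** 2)
            if v > 0:
                ent -= v * np.log(v)
            if sd_x > 0 and sd_y > 0:
                corr += (i - mu_x) * (j - mu_y) * v / (sd_x * sd_y)
            p_sum[i + j] += v
            p_diff[abs(i - j)] += v
    sum_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    sum_ent = -sum(v * np.log(v) for v in p_sum if v > 0)
    d_mean = sum(k * p_diff[k] for k in range(n))
    d_var = sum((k - d_mean) ** 2 * p_diff[k] for k in range(n))
    d_ent = -sum(v * np.log(v) for v in p_diff if v > 0)
    hx = -sum(v * np.log(v) for v in px if v > 0)
    hy = -sum(v * np.log(v) for v in py if v > 0)
    hxy1 = hxy2 = 0.0
    for i in range(n):
        for j in range(n):
            q = px[i] * py[j]
            if q > 0:
                hxy2 -= q * np.log(q)
                if p[i, j] > 0:
                    hxy1 -= p[i, j] * np.log(q)
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(1 - np.exp(-2 * (hxy2 - ent)), 0.0)) if denom > 0 else 0.0
    return dict(zip(HARALICK_NAMES, [energy, contrast, corr, var, homog, sum_avg,
                                     sum_var, sum_ent, ent, d_var, d_ent, imc1, imc2]))


# -- GLCM construction ----------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_spatial_glcm_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, 6, size=3))
    vol = rng.random(shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask[0, 0, 0] = True
    g = glcm_3d(vol, mask, bins=8)
    brute = brute_spatial_glcm(vol, mask, 8)
    if brute.sum() > 0:
        assert np.allclose(g.p, brute / brute.sum())
        assert g.n_pairs == int(brute.sum())


def test_glcm_constant_volume_single_entry():
    vol = np.full((4, 4, 4), 2.5)
    mask = np.ones((4, 4, 4), dtype=bool)
    g = glcm_3d(vol, mask)
    assert np.count_nonzero(g.p) == 1
    assert g.p.sum() == pytest.approx(1.0)


def test_glcm_two_level_toy_counts():
    """3x3x1 checkerboard-ish volume: counts equal manual pair enumeration."""
    vol = np.zeros((3, 3, 1))
    vol[1, 1, 0] = 1.0
    mask = np.ones((3, 3, 1), dtype=bool)
    g = glcm_3d(vol, mask, bins=2)
    brute = brute_spatial_glcm(vol, mask, 2)
    assert np.allclose(g.p * g.n_pairs, brute)


def test_glcm_symmetric_and_normalised(seg_cohort):
    study = seg_cohort[1][0][0]
    lesion = study.annotation == 1
    g = glcm_3d(study.dce_peak, lesion)
    assert g.p.shape == (128, 128)
    assert np.allclose(g.p, g.p.T)
    assert g.p.sum() == pytest.approx(1.0)
    assert np.all(g.p >= 0)


def test_glcm_empty_mask_rejected():
    with pytest.raises(ValueError):
        glcm_3d(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), dtype=bool))


# -- temporal GLCM --------------------------------------------------------

def test_temporal_glcm_identical_volumes_diagonal():
    rng = np.random.default_rng(0)
    vol = rng.random((4, 4, 4))
    mask = np.ones((4, 4, 4), dtype=bool)
    g = temporal_glcm(vol, vol, mask, bins=16)
    off_diag = g.p - np.diag(np.diag(g.p))
    assert np.allclose(off_diag, 0.0)


def test_temporal_glcm_pair_count_is_mask_size():
    rng = np.random.default_rng(1)
    mask = rng.random((5, 5, 5)) < 0.5
    mask[0, 0, 0] = True
    g = temporal_glcm(rng.random((5, 5, 5)), rng.random((5, 5, 5)), mask, bins=8)
    assert g.n_pairs == int(mask.sum())


def test_temporal_glcm_matches_bruteforce():
    rng = np.random.default_rng(2)
    a, b = rng.random((4, 3, 2)), rng.random((4, 3, 2))
    mask = rng.random((4, 3, 2)) < 0.7
    mask[0, 0, 0] = True
    bins = 6
    g = temporal_glcm(a, b, mask, bins=bins)
    pooled = np.concatenate([a[mask], b[mask]])
    lo, hi = pooled.min(), pooled.max()
    counts = np.zeros((bins, bins))
    for av, bv in zip(a[mask], b[mask]):
        qa = min(int((av - lo) / (hi - lo) * bins), bins - 1)
        qb = min(int((bv - lo) / (hi - lo) * bins), bins - 1)
        counts[qa, qb] += 1
        counts[qb, qa] += 1
    assert np.allclose(g.p, counts / counts.sum())


def test_uniform_uptake_has_higher_temporal_energy():
    """Homogeneous enhancement concentrates the pair distribution."""
    rng = np.random.default_rng(3)
    mask = np.ones((6, 6, 6), dtype=bool)
    pre = np.full((6, 6, 6), 1.0)
    uniform_post = np.full((6, 6, 6), 2.0)
    hetero_post = 2.0 + rng.random((6, 6, 6)) * 2.0
    e_uniform = haralick13(temporal_glcm(pre, uniform_post, mask))["energy"]
    e_hetero = haralick13(temporal_glcm(pre, hetero_post, mask))["energy"]
    assert e_uniform > e_hetero


# -- Haralick statistics --------------------------------------------------

def _cooc_from(p):
    return CoocMatrix(p=p, bin_edges=np.linspace(0, 1, p.shape[0] + 1), n_pairs=1)


def test_haralick_single_entry():
    p = np.zeros((8, 8))
    p[3, 3] = 1.0
    h = haralick13(_cooc_from(p))
    assert h["energy"] == pytest.approx(1.0)
    assert h["entropy"] == pytest.approx(0.0)


def test_haralick_uniform_closed_form():
    k = 5
    p = np.full((k, k), 1.0 / k**2)
    h = haralick13(_cooc_from(p))
    assert h["energy"] == pytest.approx(1.0 / k**2)
    assert h["entropy"] == pytest.approx(np.log(k**2))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_haralick_matches_textbook_recomputation(seed):
    rng = np.random.default_rng(seed)
    raw = rng.random((7, 7))
    p = raw + raw.T
    p /= p.sum()
    ours = haralick13(_cooc_from(p))
    ref = brute_haralick(p)
    for name in HARALICK_NAMES:
        assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name


def test_haralick_invariant_to_affine_rescaling(seg_cohort):
    """Quantisation over the in-mask range makes texture scale-free."""
    study = seg_cohort[1][2][0]
    lesion = study.annotation == 1
    h1 = haralick13(glcm_3d(study.dce_peak, lesion))
    h2 = haralick13(glcm_3d(7.3 * study.dce_peak - 11.0, lesion))
    for name in HARALICK_NAMES:
        assert h1[name] == pytest.approx(h2[name], rel=1e-9, abs=1e-12)
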