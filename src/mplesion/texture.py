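"""Volumetric grey-level co-occurrence texture analysis.

Spatial GLCMs accumulate co-occurrences over all 26 three-dimensional
unit-offset neighbours with both voxels inside the lesion mask, after
quantising the in-mask intensities to 128 equal-width bins over the
in-mask range.  Spatio-temporal GLCMs pair each voxel's quantised value in
two volumes of the enhancement sequence (same spatial position, different
time point), with a quantisation shared over the pooled in-mask range of
both volumes.  Matrices are symmetrised and normalised to sum 1, and are
summarised by Haralick's 13 second-order statistics.  Because the bins are
derived from the in-mask range, the statistics are invariant to any
affine rescaling of the input intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoocMatrix",
    "HARALICK_NAMES",
    "glcm_3d",
    "temporal_glcm",
    "haralick13",
]

N_BINS = 128

#: the 26 neighbour offsets = all nonzero (dz, dy, dx) in {-1, 0, 1}^3;
#: only the 13 "positive" half need scanning, the transpose adds the rest.
_HALF_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)


@dataclass
class CoocMatrix:
    """Normalised, symmetric grey-level co-occurrence matrix."""

    p: np.ndarray                 # (bins, bins), sums to 1
    bin_edges: np.ndarray
    n_pairs: int                  # raw (directed) pair count before normalisation

    def __post_init__(self) -> None:
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if not np.allclose(self.p, self.p.T):
            raise ValueError("co-occurrence matrix must be symmetric")
        total = float(self.p.sum())
        if not np.isclose(total, 1.0):
            raise ValueError(f"co-occurrence matrix must sum to 1, sums to {total}")


def _quantise(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    """Equal-width binning of [lo, hi] into ``bins`` levels (0-based)."""
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(q, 0, bins - 1)


def glcm_3d(volume: np.ndarray, mask: np.ndarray, bins: int = N_BINS) -> CoocMatrix:
    """Spatial GLCM over the 26-neighbourhood within the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vol = np.asarray(volume, dtype=float)
    if not np.all(np.isfinite(vol[mask])):
        raise ValueError("volume contains non-finite in-mask values")
    vals = vol[mask]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.where(mask, _quantise(vol, lo, hi, bins), -1)

    counts = np.zeros((bins, bins), dtype=np.int64)
    for off in _HALF_OFFSETS:
        a, b = _shifted_pairs(q, mask, off)
        np.add.at(counts, (a, b), 1)
    counts = counts + counts.T        # symmetrise: adds the 13 mirror offsets
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        # single isolated voxel: fall back to the self-pair so the matrix
        # remains a valid distribution
        counts[q[mask][0], q[mask][0]] = 1
        n_pairs = 1
    edges = np.linspace(lo, hi, bins + 1)
    return CoocMatrix(p=counts / n_pairs, bin_edges=edges, n_pairs=n_pairs)


def _shifted_pairs(q: np.ndarray, mask: np.ndarray, off):
    """Quantised value pairs (q[x], q[x+off]) with both endpoints in-mask."""
    sl_a, sl_b = [], []
    for o, n in zip(off, q.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return q[sl_a][valid], q[sl_b][valid]


def temporal_glcm(vol_a: np.ndarray, vol_b: np.ndarray, mask: np.ndarray,
                  bins: int = N_BINS) -> CoocMatrix:
    """Spatio-temporal GLCM: one pair per voxel, (bin(a[x]), bin(b[x])).

    Both volumes are quantised over their pooled in-mask range so the two
    axes share bins; the matrix is symmetrised and normalised.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    a = np.asarray(vol_a, dtype=float)[mask]
    b = np.asarray(vol_b, dtype=float)[mask]
    if a.shape != b.shape:
        raise ValueError("volumes must share the grid")
    pooled = np.concatenate([a, b])
    lo, hi = float(pooled.min()), float(pooled.max())
    qa = _quantise(a, lo, hi, bins)
    qb = _quantise(b, lo, hi, bins)
    counts = np.zeros((bins, bins), dtype=np.int64)
    np.add.at(counts, (qa, qb), 1)
    counts = counts + counts.T
    edges = np.linspace(lo, hi, bins + 1)
    return CoocMatrix(p=counts / counts.sum(), bin_edges=edges, n_pairs=int(mask.sum()))


def haralick13(glcm: CoocMatrix) -> dict[str, float]:
    """Haralick's 13 second-order statistics of a normalised GLCM.

    Correlation-type statistics (correlation, imc1, imc2) are defined as 0
    when a marginal is degenerate (zero variance / entropy).
    """
    p = glcm.p
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0

    energy = float(np.sum(p**2))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if sd_x > 0 and sd_y > 0:
        correlation = float(np.sum((ii - mu_x) * (jj - mu_y) * p) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(np.sum((ii - mu_x) ** 2 * p))
    homogeneity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))   # inverse difference moment
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))

    # p_{x+y}(k), k = 0..2n-2 ; p_{x-y}(k), k = 0..n-1
    k_sum = (ii + jj).astype(int)
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * n - 1)
    k_diff = np.abs(ii - jj).astype(int)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=n)

    ks = np.arange(2 * n - 1, dtype=float)
    sum_average = float(ks @ p_sum)
    sum_variance = float(((ks - sum_average) ** 2) @ p_sum)
    nz_s = p_sum > 0
    sum_entropy = float(-np.sum(p_sum[nz_s] * np.log(p_sum[nz_s])))

    kd = np.arange(n, dtype=float)
    diff_mean = float(kd @ p_diff)
    difference_variance = float(((kd - diff_mean) ** 2) @ p_diff)
    nz_d = p_diff > 0
    difference_entropy = float(-np.sum(p_diff[nz_d] * np.log(p_diff[nz_d])))

    # information measures of correlation
    hx = float(-np.sum(px[px > 0] * np.log(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log(py[py > 0])))
    pxy = np.outer(px, py)
    valid = nz & (pxy > 0)
    hxy1 = float(-np.sum(p[valid] * np.log(pxy[valid])))
    v2 = pxy > 0
    hxy2 = float(-np.sum(pxy[v2] * np.log(pxy[v2])))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(arg, 0.0))) if denom > 0 else 0.0

    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "homogeneity": homogeneity,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }
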