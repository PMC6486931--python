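"""Fuzzy c-means clustering and cluster-extreme intensity features."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["fuzzy_c_means", "cluster_extreme_intensity"]


def fuzzy_c_means(samples: np.ndarray, c: int, m: float = 2.0, seed: int = 0,
                  max_iter: int = 300, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Standard fuzzy c-means (Bezdek) with seeded initialisation.

    ``samples`` is (n, d); returns (centres (c, d), memberships (n, c)).
    Memberships row-sum to 1.  Iterates the alternating centre/membership
    updates with fuzziness exponent ``m`` until the maximum membership
    change falls below ``tol``.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[0] < c:
        raise ValueError(f"need at least {c} samples, got {x.shape[0]}")
    if c < 2:
        raise ValueError("cluster count must be >= 2")
    if m <= 1:
        raise ValueError("fuzziness exponent must exceed 1")
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)          # (n, c), rows sum to 1

    for _ in range(max_iter):
        um = u**m
        centres = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        # samples coincident with a centre get a crisp membership
        hit = d2 < 1e-250
        rows = hit.any(axis=1)
        if rows.any():
            u_new[rows] = hit[rows] / hit[rows].sum(axis=1, keepdims=True)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    um = u**m
    centres = (um.T @ x) / um.sum(axis=0)[:, None]
    return centres, u


def cluster_extreme_intensity(volume: np.ndarray, mask: np.ndarray, c: int = 5,
                              mode: str = "lowest", seed: int = 0) -> float:
    """Extreme fuzzy-cluster centre of the in-mask intensity distribution.

    The in-mask scalar intensities are partitioned into ``c`` fuzzy
    clusters; the lowest centre summarises restricted diffusion on ADC
    maps, the highest summarises focal FDG uptake on PET.  Lesions with
    fewer than ``c`` voxels fall back to the in-mask min/max with a
    warning.
    """
    if mode not in ("lowest", "highest"):
        raise ValueError("mode must be 'lowest' or 'highest'")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(volume, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    if vals.size < c or np.unique(vals).size < c:
        warnings.warn("too few distinct voxels for clustering; using in-mask extreme")
        return float(vals.min() if mode == "lowest" else vals.max())
    centres, _ = fuzzy_c_means(vals[:, None], c=c, seed=seed)
    centres = centres.ravel()
    return float(centres.min() if mode == "lowest" else centres.max())
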