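"""Vein segmentation: Hessian vesselness, 3-class Otsu, hysteresis mask.

The probability map comes from a multiscale Frangi-type tubularity filter
for bright structures (veins are bright on susceptibility volumes); an
externally computed probability map is accepted anywhere one is expected.
Binarization follows the two-threshold hysteresis rule: a mid-band voxel
belongs to a vessel only if it is connected (26-neighbourhood, through
voxels above the lower threshold) to a voxel above the upper threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.filters import frangi

from .core_io import Volume

__all__ = [
    "ThresholdPair",
    "vesselness_probability",
    "otsu_thresholds_3class",
    "hysteresis_binarize",
]


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper probability thresholds plus 3-class Otsu statistics."""

    lower: float
    upper: float
    class_probs: tuple[float, float, float]
    class_means: tuple[float, float, float]
    between_class_variance: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got {self.lower}, {self.upper}")


def vesselness_probability(volume: Volume, scales_mm=(0.5, 1.0)) -> Volume:
    """Multiscale bright-tubular-structure response rescaled to [0, 1].

    Per-scale Frangi responses are combined by voxelwise maximum.  A
    constant input yields an all-zero map with a warning.
    """
    scales_mm = tuple(scales_mm)
    if not scales_mm:
        raise ValueError("need at least one scale")
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        data = np.nan_to_num(data, nan=0.0)
    if np.ptp(data) == 0:
        warnings.warn("constant input volume: vesselness map is all zeros")
        return volume.with_data(np.zeros_like(data))
    # frangi works in voxel units; convert mm scales using the mean spacing
    voxel_mm = float(np.mean(volume.spacing))
    sigmas = [max(s / voxel_mm, 0.5) for s in scales_mm]
    response = np.zeros_like(data)
    for sigma in sigmas:
        r = frangi(data, sigmas=[sigma], black_ridges=False)
        np.maximum(response, r, out=response)
    lo, hi = response.min(), response.max()
    if hi > lo:
        response = (response - lo) / (hi - lo)
    return volume.with_data(response)


def otsu_thresholds_3class(values, n_bins: int = 256) -> ThresholdPair:
    """Two thresholds maximizing 3-class between-class variance.

    Exhaustive search over all bin-boundary pairs of an ``n_bins``
    histogram; ties broken by the smallest (lower, then upper) pair.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if np.unique(values).size < 3:
        raise ValueError("need >= 3 distinct values to form 3 classes")

    counts, edges = np.histogram(values, bins=n_bins)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    # cumulative class probability and first moment up to each bin
    cw = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * centers)])
    mu_T = cm[-1]

    # classes: [0, i), [i, j), [j, n) over bin indices, 1 <= i < j <= n-1
    i = np.arange(1, n_bins)[:, None]
    j = np.arange(1, n_bins)[None, :]
    w0 = cw[i]
    w1 = cw[j] - cw[i]
    w2 = 1.0 - cw[j]
    m0 = cm[i]
    m1 = cm[j] - cm[i]
    m2 = mu_T - cm[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        sb = (
            np.where(w0 > 0, m0**2 / w0, 0.0)
            + np.where(w1 > 0, m1**2 / w1, 0.0)
            + np.where(w2 > 0, m2**2 / w2, 0.0)
            - mu_T**2
        )
    sb = np.where(j > i, sb, -np.inf)

    best = np.max(sb)
    # smallest (lower, upper) among ties: first index pair in row-major order
    ii, jj = np.argwhere(np.isclose(sb, best, rtol=0, atol=1e-15))[0]
    bi, bj = ii + 1, jj + 1  # back to bin-boundary indices

    lower, upper = float(edges[bi]), float(edges[bj])
    w = (float(cw[bi]), float(cw[bj] - cw[bi]), float(1.0 - cw[bj]))
    m = tuple(
        float(num / den) if den > 0 else float("nan")
        for num, den in zip(
            (cm[bi], cm[bj] - cm[bi], mu_T - cm[bj]), w
        )
    )
    return ThresholdPair(
        lower=lower,
        upper=upper,
        class_probs=w,
        class_means=m,
        between_class_variance=float(best),
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def hysteresis_binarize(
    prob: Volume, thresholds: ThresholdPair, connectivity: int = 26
) -> Volume:
    """Two-threshold hysteresis binarization of a probability map.

    mask = {p > upper} plus every voxel with lower < p <= upper that is
    connected, through voxels with p > lower, to some voxel with p > upper.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    p = np.asarray(prob.data)
    strong = p > thresholds.upper
    weak = p > thresholds.lower
    labels, n = ndimage.label(weak, structure=_STRUCTURES[connectivity])
    if n == 0 or not strong.any():
        if not strong.any():
            warnings.warn("hysteresis: no voxel above the upper threshold; empty mask")
        return prob.with_data(np.zeros_like(p))
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    mask = keep[labels]
    return prob.with_data(mask.astype(float))
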