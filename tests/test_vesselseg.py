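from collections import deque

import numpy as np
import pytest

from venalamina.core_io import Volume
from venalamina.vesselseg import (
    ThresholdPair,
    hysteresis_binarize,
    otsu_thresholds_3class,
    vesselness_probability,
)


def brute_force_otsu(values, n_bins):
    """Independent oracle: direct triple-sum over all threshold pairs."""
    counts, edges = np.histogram(values, bins=n_bins)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu_T = (p * centers).sum()
    best = (-np.inf, None, None)
    for i in range(1, n_bins):
        for j in range(i + 1, n_bins):
            sb = 0.0
            for cls in (slice(0, i), slice(i, j), slice(j, n_bins)):
                w = p[cls].sum()
                if w > 0:
                    mu = (p[cls] * centers[cls]).sum() / w
                    sb += w * (mu - mu_T) ** 2
            if sb > best[0] + 1e-15:
                best = (sb, edges[i], edges[j])
    return best


def bfs_hysteresis(prob, lower, upper):
    """Independent oracle: flood fill from strong seeds over 26-neighbours."""
    strong = prob > upper
    weak = prob > lower
    mask = np.zeros_like(weak)
    queue = deque(zip(*np.nonzero(strong)))
    mask[strong] = True
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    shape = prob.shape
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                if weak[nx, ny, nz] and not mask[nx, ny, nz]:
                    mask[nx, ny, nz] = True
                    queue.append((nx, ny, nz))
    return mask


def _cylinder(shape=(32, 32, 32), radius=2.0, value=1.0):
    data = np.zeros(shape)
    cx, cy = shape[0] / 2, shape[1] / 2
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    data[disc, :] = value
    return data


class TestVesselness:
    def test_cylinder_axis_in_top_percentile(self):
        vol = Volume(_cylinder(radius=2.0), spacing=(1.0, 1.0, 1.0))
        prob = vesselness_probability(vol, scales_mm=[1.0]).data
        axis_vals = prob[16, 16, 8:-8]
        assert np.all(axis_vals >= np.percentile(prob, 99))

    def test_constant_volume_all_zero_with_warning(self):
        vol = Volume(np.full((8, 8, 8), 3.0), spacing=(1, 1, 1))
        with pytest.warns(UserWarning, match="constant"):
            prob = vesselness_probability(vol, scales_mm=[1.0])
        assert not prob.data.any()

    def test_cylinder_beats_sphere(self):
        shape = (32, 32, 32)
        xx, yy, zz = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        sphere = (((xx - 16) ** 2 + (yy - 16) ** 2 + (zz - 16) ** 2) <= 4).astype(float)
        cyl = _cylinder(shape, radius=2.0)
        r_cyl = vesselness_probability(Volume(cyl, (1, 1, 1)), [1.0]).data[16, 16, 16]
        r_sph = vesselness_probability(Volume(sphere, (1, 1, 1)), [1.0]).data[16, 16, 16]
        assert r_cyl > r_sph

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        vol = Volume(rng.random((16, 16, 16)), (1, 1, 1))
        prob = vesselness_probability(vol, [1.0]).data
        assert prob.min() >= 0 and prob.max() <= 1

    def test_requires_scales(self):
        with pytest.raises(ValueError):
            vesselness_probability(Volume(np.zeros((4, 4, 4))), [])


class TestOtsu3Class:
    def test_separated_point_masses(self):
        values = np.concatenate(
            [np.full(800, 0.1), np.full(150, 0.5), np.full(50, 0.9)]
        )
        tp = otsu_thresholds_3class(values, n_bins=64)
        assert 0.1 < tp.lower < 0.5
        assert 0.5 < tp.upper < 0.9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [
                rng.normal(0.2, 0.05, 300),
                rng.normal(0.5, 0.05, rng.integers(20, 200)),
                rng.normal(0.8, 0.05, rng.integers(20, 200)),
            ]
        )
        n_bins = int(rng.integers(16, 64))
        tp = otsu_thresholds_3class(values, n_bins=n_bins)
        sb, lo, up = brute_force_otsu(values, n_bins)
        assert tp.between_class_variance == pytest.approx(sb, rel=1e-10)
        assert tp.lower == pytest.approx(lo)
        assert tp.upper == pytest.approx(up)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(3)
        values = rng.random(1000)
        a = otsu_thresholds_3class(values, 64)
        b = otsu_thresholds_3class(values * 0.5, 64)
        assert b.lower == pytest.approx(a.lower * 0.5, rel=1e-9)
        assert b.upper == pytest.approx(a.upper * 0.5, rel=1e-9)

    def test_too_few_distinct_values_fatal(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_thresholds_3class(np.array([0.1, 0.9] * 50))

    def test_class_probs_sum_to_one(self):
        rng = np.random.default_rng(4)
        tp = otsu_thresholds_3class(rng.random(500), 32)
        assert sum(tp.class_probs) == pytest.approx(1.0)


class TestHysteresis:
    def _pair(self, lower, upper):
        return ThresholdPair(lower, upper, (1 / 3,) * 3, (0.1, 0.5, 0.9), 1.0)

    def test_isolated_midband_voxel_is_background(self):
        data = np.zeros((7, 7, 7))
        data[1, 1, 1] = 0.95
        data[5, 5, 5] = 0.6
        mask = hysteresis_binarize(
            Volume(data, (1, 1, 1)), self._pair(0.5, 0.9)
        ).data
        assert mask[1, 1, 1] == 1
        assert mask[5, 5, 5] == 0
        assert mask.sum() == 1

    def test_connected_chain_included(self):
        data = np.zeros((7, 7, 7))
        data[2, 2, 2] = 0.95
        data[2, 2, 3] = 0.7
        data[2, 2, 4] = 0.6
        mask = hysteresis_binarize(
            Volume(data, (1, 1, 1)), self._pair(0.5, 0.9)
        ).data
        assert mask[2, 2, 2] == mask[2, 2, 3] == mask[2, 2, 4] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prob = rng.random((12, 12, 12))
        vol = Volume(prob, (1, 1, 1))
        mask = hysteresis_binarize(vol, self._pair(0.6, 0.92)).data > 0
        oracle = bfs_hysteresis(prob, 0.6, 0.92)
        np.testing.assert_array_equal(mask, oracle)

    @pytest.mark.parametrize("seed", range(5))
    def test_sandwich_property(self, seed):
        rng = np.random.default_rng(100 + seed)
        prob = rng.random((10, 10, 10))
        vol = Volume(prob, (1, 1, 1))
        mask = hysteresis_binarize(vol, self._pair(0.4, 0.85)).data > 0
        assert np.all(mask[prob > 0.85])
        assert not np.any(mask & ~(prob > 0.4))

    def test_empty_mask_allowed_with_warning(self):
        data = np.full((5, 5, 5), 0.1)
        with pytest.warns(UserWarning, match="empty"):
            mask = hysteresis_binarize(
                Volume(data, (1, 1, 1)), self._pair(0.5, 0.9)
            ).data
        assert not mask.any()


def test_phantom_dice_against_truth(subject, config):
    """Detection property: segmentation recovers truth veins in the ribbon."""
    from scipy import ndimage

    prob = vesselness_probability(subject.qsm_volume, config.vesselness_scales_mm)
    ribbon = (subject.inner_signed_distance.data > 0) & (
        subject.outer_signed_distance.data > 0
    )
    region = ndimage.binary_dilation(ribbon, iterations=4)
    tp = otsu_thresholds_3class(prob.data[region], 256)
    mask = hysteresis_binarize(prob, tp).data > 0
    truth = subject.vein_mask_truth.data > 0
    inter = (mask & truth & ribbon).sum()
    dice = 2 * inter / ((mask & ribbon).sum() + (truth & ribbon).sum())
    assert dice >= 0.6
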