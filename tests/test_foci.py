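"""3D foci segmentation, volume cutoff, statistics, and the t-test."""

import numpy as np
import pytest
from scipy import stats as sps

from rai2ctbp import foci, synthetic
from rai2ctbp.synthetic import VolumetricImage


def _flood_fill_oracle(binary, connectivity):
    """Brute-force connected components by BFS (independent of skimage)."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(binary.shape, dtype=int)
    nxt = 0
    for idx in zip(*np.nonzero(binary)):
        if labels[idx]:
            continue
        nxt += 1
        stack = [idx]
        labels[idx] = nxt
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if all(0 <= q[k] < binary.shape[k] for k in range(3)):
                    if binary[q] and not labels[q]:
                        labels[q] = nxt
                        stack.append(q)
    return nxt, labels


class TestBackground:
    def test_zero_background_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 10, (4, 5, 6))
        out = foci.subtract_background(img, foci.FociConfig(background=0.0))
        assert np.array_equal(out, img)

    def test_constant_image_goes_to_zero(self):
        img = np.full((3, 3, 3), 50.0)
        out = foci.subtract_background(img, foci.FociConfig(background=50.0))
        assert np.all(out == 0.0)

    def test_clipping_at_zero(self):
        img = np.array([[[10.0, 60.0]]])
        out = foci.subtract_background(img, foci.FociConfig(background=50.0))
        assert np.array_equal(out, [[[0.0, 10.0]]])

    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            foci.subtract_background(np.zeros((2, 2, 2)), foci.FociConfig(background=-1.0))

    def test_auto_mode_estimates_dominant_background(self):
        rng = np.random.default_rng(1)
        img = np.full((10, 20, 20), 10.0) + rng.normal(0, 0.1, (10, 20, 20))
        img[5, 10, 10] = 200.0
        out = foci.subtract_background(img, foci.FociConfig(background="auto"))
        assert np.median(out) < 1.0
        assert out[5, 10, 10] > 150.0


class TestSegmentation:
    def test_empty_image_no_objects(self):
        img = VolumetricImage(np.zeros((4, 4, 4)), (0.1, 0.1, 0.1))
        objs = foci.segment_foci(
            img, np.ones((4, 4, 4), int), foci.FociConfig(threshold=0.5)
        )
        assert objs == []

    def test_diagonal_adjacency_by_connectivity(self):
        vox = np.zeros((3, 3, 3))
        vox[0, 0, 0] = vox[1, 1, 1] = 10.0
        img = VolumetricImage(vox, (0.1, 0.1, 0.1))
        mask = np.ones((3, 3, 3), int)
        one = foci.segment_foci(img, mask, foci.FociConfig(threshold=5.0, connectivity=26))
        two = foci.segment_foci(img, mask, foci.FociConfig(threshold=5.0, connectivity=6))
        assert len(one) == 1
        assert len(two) == 2

    def test_sphere_volume_recovered(self):
        spec = synthetic.ImageSpec(
            shape=(24, 24, 24),
            voxel_size=(0.1, 0.1, 0.1),
            n_cells=1,
            foci_per_cell=1,
            focus_radius=0.4,
            background=0.0,
            noise_sd=0.0,
        )
        img, truth, mask = synthetic.gen_foci_image(spec, seed=2)
        objs = foci.segment_foci(img, mask, foci.FociConfig(threshold=50.0))
        assert len(objs) == 1
        assert abs(objs[0].volume - 0.268) / 0.268 < 0.15

    def test_shape_mismatch_rejected(self):
        img = VolumetricImage(np.zeros((4, 4, 4)), (0.1, 0.1, 0.1))
        with pytest.raises(ValueError, match="shape"):
            foci.segment_foci(img, np.ones((5, 4, 4), int), foci.FociConfig(threshold=1))

    def test_agrees_with_flood_fill_oracle(self):
        rng = np.random.default_rng(3)
        vox = (rng.random((8, 8, 8)) < 0.2).astype(float) * 10
        img = VolumetricImage(vox, (0.1, 0.1, 0.1))
        mask = np.ones(vox.shape, int)
        for conn in (6, 18, 26):
            objs = foci.segment_foci(
                img, mask, foci.FociConfig(threshold=5.0, connectivity=conn)
            )
            n_oracle, labels = _flood_fill_oracle(vox > 5.0, conn)
            assert len(objs) == n_oracle
            ours = sorted(o.voxel_count for o in objs)
            oracle = sorted(np.bincount(labels.ravel())[1:])
            assert ours == oracle


class TestVolumeFilter:
    def _obj(self, volume):
        return foci.FocusObject(
            voxel_count=1, volume=volume, centroid=(0, 0, 0), cell_id=1,
            mean_intensity=1.0,
        )

    def test_small_object_removed(self):
        assert foci.filter_foci([self._obj(0.002)]) == []

    def test_boundary_inclusive(self):
        objs = [self._obj(0.1)]
        assert foci.filter_foci(objs) == objs

    def test_zero_cutoff_identity(self):
        objs = [self._obj(0.002), self._obj(5.0)]
        assert foci.filter_foci(objs, foci.FociConfig(min_volume=0.0)) == objs


class TestStats:
    def test_counts_include_empty_cells(self):
        mask = np.zeros((2, 4, 4), int)
        mask[:, :, :2] = 1
        mask[:, :, 2:] = 2
        objs = [
            foci.FocusObject(1, 0.5, (0, 0, 0), cell_id=1, mean_intensity=1.0)
            for _ in range(5)
        ]
        st = foci.foci_stats(objs, mask)
        assert st["counts_per_cell"] == {1: 5, 2: 0}

    def test_median_of_four_volumes(self):
        objs = [
            foci.FocusObject(1, v, (0, 0, 0), cell_id=1, mean_intensity=1.0)
            for v in (1.0, 2.0, 3.0, 4.0)
        ]
        st = foci.foci_stats(objs, np.ones((1, 1, 1), int))
        assert st["volume_summary"]["median"] == pytest.approx(2.5)


class TestTTest:
    def test_identical_samples(self):
        res = foci.unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        a, b = np.array([0.0, 0.0, 1.0, 1.0]), np.array([2.0, 2.0, 3.0, 3.0])
        res = foci.unpaired_t_test(a, b)
        # textbook pooled-variance computation
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_hand = 2 * sps.t.sf(abs(t_hand), len(a) + len(b) - 2)
        assert res.t == pytest.approx(t_hand)
        assert res.df == len(a) + len(b) - 2
        assert res.p_two_sided == pytest.approx(p_hand)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = foci.unpaired_t_test([1.0, 1.0], [2.0, 2.0])
        assert res.p_two_sided == 0.0

    def test_sample_size_validated(self):
        with pytest.raises(ValueError):
            foci.unpaired_t_test([1.0], [1.0, 2.0])


class TestGroundTruthRecovery:
    def test_detection_and_centroids_on_synthetic_image(self, small_foci_image):
        img, truth, mask, spec = small_foci_image
        cfg = foci.FociConfig(min_volume=0.1)
        objs = foci.filter_foci(
            foci.segment_foci(foci.subtract_background(img, cfg), mask, cfg), cfg
        )
        assert len(objs) == len(truth)
        got = np.array(sorted(o.centroid for o in objs))
        want = np.array(sorted(zip(truth.z_um, truth.y_um, truth.x_um)))
        assert np.all(np.abs(got - want) < np.array(spec.voxel_size))

    def test_scaling_invariance_with_otsu(self, small_foci_image):
        img, truth, mask, _ = small_foci_image
        cfg = foci.FociConfig(background=0.0)
        a = foci.segment_foci(img, mask, cfg)
        scaled = VolumetricImage(img.voxels * 13.0, img.voxel_size)
        b = foci.segment_foci(scaled, mask, cfg)
        assert sorted(o.voxel_count for o in a) == sorted(o.voxel_count for o in b)
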