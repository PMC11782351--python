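"""Segmentation and morphometrics: analytic shapes, oracles, invariants."""

import numpy as np
import pytest

from vstain.imgen import SceneSpec, generate_scene
from vstain.morph import (WatershedConfig, agreement, marker_watershed,
                          measure_cells, otsu_threshold, segment_particles)


def disk_mask(radius, pad=28):
    n = 2 * (radius + pad)
    yy, xx = np.mgrid[0:n, 0:n]
    return (((yy - n / 2) ** 2 + (xx - n / 2) ** 2) <= radius ** 2).astype(np.int32)


class TestOtsu:
    def test_two_delta_histogram(self):
        img = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)])
        thr = otsu_threshold(img)
        assert 0.2 < thr < 0.8

    def test_matches_exhaustive_between_class_variance_search(self):
        # independent oracle: argmax over all 256 cut points by direct loops
        rng = np.random.default_rng(0)
        for _ in range(20):
            img = np.concatenate([rng.normal(0.3, 0.05, 200),
                                  rng.normal(0.7, rng.uniform(0.02, 0.1), 300)])
            counts, edges = np.histogram(img, bins=256, range=(img.min(), img.max()))
            p = counts / counts.sum()
            centers = (edges[:-1] + edges[1:]) / 2
            best_k, best_v = -1, -1.0
            for k in range(256):
                w0 = p[:k + 1].sum()
                w1 = 1 - w0
                if w0 == 0 or w1 == 0:
                    continue
                mu0 = (p[:k + 1] * centers[:k + 1]).sum() / w0
                mu1 = (p[k + 1:] * centers[k + 1:]).sum() / w1
                v = w0 * w1 * (mu0 - mu1) ** 2
                if v > best_v + 1e-15:
                    best_v, best_k = v, k
            assert otsu_threshold(img) == pytest.approx(edges[best_k + 1], abs=1e-12)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((8, 8), 0.5))


class TestSegmentParticles:
    def test_two_disjoint_blobs(self):
        mask = np.zeros((64, 64), bool)
        mask[10:25, 10:25] = True
        mask[40:55, 40:55] = True
        labels = segment_particles(mask, WatershedConfig(min_area_px=10))
        assert labels.max() == 2

    def test_small_blob_removed(self):
        mask = np.zeros((64, 64), bool)
        mask[30:33, 30:33] = True  # 9 px < 50
        assert segment_particles(mask, WatershedConfig(min_area_px=50)).max() == 0

    def test_border_blob_removed_iff_excluded(self):
        mask = np.zeros((64, 64), bool)
        mask[0:15, 20:35] = True
        assert segment_particles(mask, WatershedConfig(exclude_border=True)).max() == 0
        assert segment_particles(mask, WatershedConfig(exclude_border=False)).max() == 1


class TestMarkerWatershed:
    def basin_image(self, depth=0.5):
        """Two basins separated by a ridge of the given depth."""
        img = np.zeros((64, 64))
        img[:, 31:33] = depth
        return img

    def test_tolerance_below_ridge_depth_keeps_two_regions(self):
        labels = marker_watershed(self.basin_image(0.5), WatershedConfig(tolerance=0.1))
        assert len(np.unique(labels)) == 2
        assert (labels > 0).all()  # partition, no line label

    def test_tolerance_above_ridge_depth_merges(self):
        with pytest.warns(UserWarning, match="single-region"):
            labels = marker_watershed(self.basin_image(0.5), WatershedConfig(tolerance=0.9))
        assert len(np.unique(labels)) == 1

    def test_region_count_non_increasing_in_tolerance(self):
        counts = []
        for tol in (0.01, 0.05, 0.2):
            per_scene = []
            for seed in range(10):
                sc = generate_scene(SceneSpec(width_px=128, height_px=128, n_cells=6,
                                              shape_model="pavement", seed=seed))
                labels = marker_watershed(sc.channels["membrane"],
                                          WatershedConfig(tolerance=tol))
                per_scene.append(labels.max())
            counts.append(per_scene)
        for lo, hi in zip(counts[1:], counts[:-1]):
            assert all(a <= b for a, b in zip(lo, hi))

    def test_partition_every_pixel_labeled_once(self):
        sc = generate_scene(SceneSpec(width_px=128, height_px=128, n_cells=8,
                                      shape_model="pavement", seed=3))
        labels = marker_watershed(sc.channels["membrane"], WatershedConfig(tolerance=0.2))
        assert (labels > 0).all()


class TestMeasureCells:
    def test_disk_circularity_near_one(self):
        rec = measure_cells(disk_mask(100), 1.0)[0]
        assert rec.circularity == pytest.approx(1.0, abs=0.05)
        assert rec.area_um2 == pytest.approx(np.pi * 100 ** 2, rel=0.01)

    def test_rectangle_solidity_and_aspect(self):
        img = np.zeros((200, 200), np.int32)
        img[50:100, 40:140] = 1  # 50 x 100
        rec = measure_cells(img, 1.0)[0]
        assert rec.solidity == pytest.approx(1.0, abs=1e-6)
        assert rec.aspect_ratio == pytest.approx(2.0, abs=0.02)

    def test_square_circularity_closed_form(self):
        img = np.zeros((100, 100), np.int32)
        img[20:70, 20:70] = 1
        rec = measure_cells(img, 1.0)[0]
        assert rec.circularity == pytest.approx(np.pi / 4, abs=0.02)

    def test_pixel_size_scales_area_and_centroid(self):
        img = np.zeros((100, 100), np.int32)
        img[10:30, 50:90] = 1
        r1 = measure_cells(img, 1.0)[0]
        r2 = measure_cells(img, 0.5)[0]
        assert r2.area_um2 == pytest.approx(r1.area_um2 / 4)
        assert r2.centroid[0] == pytest.approx(r1.centroid[0] / 2)

    def test_solidity_never_exceeds_one(self):
        for seed in range(5):
            sc = generate_scene(SceneSpec(n_cells=8, seed=seed, shape_model="pavement",
                                          lobe_amplitude=6.0))
            for rec in measure_cells(sc.labels, 1.0):
                assert 0 < rec.solidity <= 1.0 + 1e-9
                assert 0 < rec.circularity <= 1.05
                assert rec.aspect_ratio >= 1.0

    def test_empty_labels_give_empty_list(self):
        assert measure_cells(np.zeros((32, 32), np.int32), 1.0) == []


class TestAgreement:
    def test_identical_sources_r2_one(self):
        vals = [1.0, 2.0, 3.5, 7.0]
        assert agreement(vals, vals).r2 == pytest.approx(1.0)

    def test_constant_source_raises(self):
        with pytest.raises(ValueError, match="variance"):
            agreement([1, 2, 3], [5, 5, 5])

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            agreement([1, 2], [1, 2])

    def test_known_signal_noise_ratio(self):
        # y = 2x + eps: population R^2 = var(2x) / (var(2x) + sigma^2)
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 1, 50)
        sigma = 0.3
        y = 2 * x + rng.normal(0, sigma, 50)
        expected = (4 * x.var()) / (4 * x.var() + sigma ** 2)
        assert agreement(x, y).r2 == pytest.approx(expected, abs=0.12)
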