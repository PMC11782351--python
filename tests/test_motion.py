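"""Centroid extraction, track linking, speed recovery."""

import numpy as np
import pytest

from vstain.imgen import SceneSpec, SpeedModel, generate_scene, generate_timelapse
from vstain.motion import LinkConfig, extract_centroids, link_tracks, speed_agreement


def disk_frame(centers, radius=6, size=128):
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for cx, cy in centers:
        img = np.maximum(img, ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2) * 1.0)
    return img * 0.8 + 0.05


class TestExtractCentroids:
    def test_single_disk_centroid_subpixel(self):
        dets = extract_centroids(disk_frame([(40.0, 70.0)]))
        assert len(dets) == 1
        assert dets[0][0] == pytest.approx(40.0, abs=0.5)
        assert dets[0][1] == pytest.approx(70.0, abs=0.5)

    def test_two_disks(self):
        dets = extract_centroids(disk_frame([(30, 30), (90, 90)]))
        assert len(dets) == 2

    def test_constant_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            assert extract_centroids(np.full((64, 64), 0.5)) == []

    def test_generator_frame_agreement(self):
        sc = generate_scene(SceneSpec(width_px=256, height_px=256, n_cells=9,
                                      shape_model="chloroplast_field",
                                      pixel_size_um=0.28, seed=11))
        dets = extract_centroids(sc.channels["chloroplast"])
        assert len(dets) == 9
        for t in sc.truth:
            tx, ty = t["centroid_px"]
            d = min(np.hypot(x - tx, y - ty) for x, y in dets)
            assert d <= 1.0


class TestLinkTracks:
    def test_two_wellseparated_objects_recovered_exactly(self):
        frames = [[(20.0 + 2 * k, 30.0), (80.0, 90.0 + 2 * k)] for k in range(5)]
        tracks = link_tracks(frames, LinkConfig(max_disp_px=10, dt_s=0.5,
                                                pixel_size_um=0.28))
        assert len(tracks) == 2
        for t in tracks:
            assert len(t.points) == 5

    def test_speed_arithmetic_on_printed_calibration(self):
        # 1 px/frame at 0.28 um/px and 0.5 s -> 0.56 um/s
        frames = [[(10.0 + k, 10.0)] for k in range(4)]
        tracks = link_tracks(frames, LinkConfig(max_disp_px=5, dt_s=0.5,
                                                pixel_size_um=0.28))
        assert tracks[0].speeds_um_s == pytest.approx([0.56, 0.56, 0.56])

    def test_jump_beyond_gate_starts_new_track(self):
        frames = [[(10.0, 10.0)], [(11.0, 10.0)], [(60.0, 60.0)]]
        tracks = link_tracks(frames, LinkConfig(max_disp_px=5, dt_s=0.5,
                                                pixel_size_um=0.28))
        assert len(tracks) == 2
        assert [len(t.points) for t in tracks] == [2, 1]

    def test_linking_exact_when_spacing_exceeds_twice_displacement(self):
        # exhaustive configurations: grids of objects, displacement 3 px,
        # spacing > 6 px -> assignment must equal ground truth
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = rng.integers(3, 8)
            base = rng.uniform(20, 200, size=(n, 2))
            # enforce spacing > 2 * max displacement
            keep = []
            for p in base:
                if all(np.hypot(*(p - q)) > 14 for q in keep):
                    keep.append(p)
            steps = rng.uniform(-3, 3, size=(len(keep), 2))
            steps *= 3.0 / np.maximum(np.hypot(steps[:, 0], steps[:, 1]), 3.0)[:, None]
            frames = [[tuple(p) for p in keep],
                      [tuple(p + s) for p, s in zip(keep, steps)]]
            tracks = link_tracks(frames, LinkConfig(max_disp_px=7, dt_s=0.5,
                                                    pixel_size_um=0.28))
            assert len(tracks) == len(keep)
            for t, p, s in zip(tracks, keep, steps):
                assert len(t.points) == 2
                assert t.points[1][1:] == pytest.approx(tuple(p + s))

    def test_speeds_invariant_under_global_translation(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(30, 100, size=(4, 2))
        frames_a = [[tuple(p + k * np.array([1.5, -0.5])) for p in pts] for k in range(4)]
        frames_b = [[(x + 200.0, y + 111.0) for x, y in f] for f in frames_a]
        cfg = LinkConfig(max_disp_px=8, dt_s=0.5, pixel_size_um=0.28)
        sa = sorted(tuple(t.speeds_um_s) for t in link_tracks(frames_a, cfg))
        sb = sorted(tuple(t.speeds_um_s) for t in link_tracks(frames_b, cfg))
        assert sa == pytest.approx(sb)

    def test_empty_frames_raise(self):
        with pytest.raises(ValueError):
            link_tracks([])


class TestSpeedAgreement:
    def timelapse(self, n=50, seed=13):
        spec = SceneSpec(width_px=512, height_px=512, n_cells=n,
                         shape_model="chloroplast_field", pixel_size_um=0.28, seed=seed)
        return generate_timelapse(spec, 10, SpeedModel(1.5, 0.5, 0.8), dt_s=0.5)

    def test_perfect_detections_give_r2_one(self):
        tl = self.timelapse(n=10)
        frames = [[tuple(t["centroid_px"]) for t in f.truth] for f in tl.frames]
        tracks = link_tracks(frames, LinkConfig(max_disp_px=15, dt_s=0.5,
                                                pixel_size_um=0.28))
        rep = speed_agreement(tl, tracks)
        assert rep.r2 == pytest.approx(1.0, abs=1e-9)

    def test_centroid_jitter_degrades_r2_as_noise_propagation_predicts(self):
        # with iid jitter of sd j on each centroid, the per-interval speed
        # error has sd ~ sqrt(2)*j*pixel/dt, so R^2 ~ var_s / (var_s + var_err)
        tl = self.timelapse(n=50)
        jitter = 0.3
        rng = np.random.default_rng(2)
        frames = [[(x + rng.normal(0, jitter), y + rng.normal(0, jitter))
                   for x, y in (t["centroid_px"] for t in f.truth)] for f in tl.frames]
        tracks = link_tracks(frames, LinkConfig(max_disp_px=15, dt_s=0.5,
                                                pixel_size_um=0.28))
        rep = speed_agreement(tl, tracks)
        assert rep.n >= 50 * 9 * 0.9
        truth_var = np.concatenate(tl.speeds_um_s).var()
        err_var = 2 * (jitter * 0.28 / 0.5) ** 2
        expected = truth_var / (truth_var + err_var)
        assert rep.r2 == pytest.approx(expected, abs=0.08)
        assert rep.r2 >= 0.8

    def test_shuffled_pairing_destroys_agreement(self):
        tl = self.timelapse(n=30)
        rng = np.random.default_rng(3)
        frames = [[tuple(t["centroid_px"]) for t in f.truth] for f in tl.frames]
        tracks = link_tracks(frames, LinkConfig(max_disp_px=15, dt_s=0.5,
                                                pixel_size_um=0.28))
        # shuffle which truth object each track is scored against
        shuffled_speeds = list(tl.speeds_um_s)
        rng.shuffle(shuffled_speeds)
        import dataclasses
        broken = dataclasses.replace(tl, speeds_um_s=tuple(shuffled_speeds))
        rep = speed_agreement(broken, tracks)
        assert rep.r2 < 0.2
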