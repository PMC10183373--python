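"""Instance metrics (volumetric best JI, bbox detection) and tracking."""

import numpy as np
import pytest

from actimesh import (
    Volume,
    best_ji_map,
    bbox_ji,
    cell_counts,
    detection_match,
    make_icosphere,
    track_bboxes,
    velocity_distribution,
)


def label_volume(shape, cubes, spacing=(1.0, 1.0, 1.0)):
    """Integer labels from (label, corner, size) cube specs."""
    data = np.zeros(shape, dtype=np.uint16)
    for lab, corner, size in cubes:
        z, y, x = corner
        data[z:z + size, y:y + size, x:x + size] = lab
    return Volume(data, spacing)


def brute_force_best_ji(gt, pred):
    g, p = np.asarray(gt.data), np.asarray(pred.data)
    out = {}
    for gl in np.unique(g[g > 0]):
        best, arg = 0.0, None
        for pl in np.unique(p[p > 0]):
            t, q = g == gl, p == pl
            ji = (t & q).sum() / (t | q).sum()
            if ji > best:
                best, arg = ji, int(pl)
        out[int(gl)] = (best, arg)
    return out


class TestBestJiMap:
    def test_identity(self):
        v = label_volume((16, 16, 16), [(1, (2, 2, 2), 4), (2, (9, 9, 9), 5)])
        res = best_ji_map(v, v)
        assert all(m.best_ji == 1.0 and m.delta_cm == 0.0 for m in res.matches)

    def test_shifted_cube_exact(self):
        gt = label_volume((10, 10, 10), [(1, (4, 4, 4), 2)])
        pred = label_volume((10, 10, 10), [(1, (4, 4, 5), 2)])
        res = best_ji_map(gt, pred)
        assert res.matches[0].best_ji == pytest.approx(1 / 3)
        assert res.matches[0].delta_cm == pytest.approx(1.0)

    def test_shifted_cube_physical_units(self):
        gt = label_volume((10, 10, 10), [(1, (4, 4, 4), 2)], spacing=(1, 1, 0.5))
        pred = label_volume((10, 10, 10), [(1, (4, 4, 5), 2)], spacing=(1, 1, 0.5))
        res = best_ji_map(gt, pred)
        assert res.matches[0].delta_cm == pytest.approx(0.5)

    def test_empty_prediction(self):
        gt = label_volume((8, 8, 8), [(1, (2, 2, 2), 3)])
        pred = Volume(np.zeros((8, 8, 8), np.uint16), (1, 1, 1))
        res = best_ji_map(gt, pred)
        assert res.matches[0].best_ji == 0.0
        assert res.matches[0].matched_pred_label is None
        assert res.matches[0].delta_cm is None

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            best_ji_map(Volume(np.zeros((4, 4, 4)), (1, 1, 1)),
                        Volume(np.zeros((4, 4, 5)), (1, 1, 1)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 5, size=(12, 12, 12)).astype(np.uint16)
        p = rng.integers(0, 5, size=(12, 12, 12)).astype(np.uint16)
        gt, pred = Volume(g, (1, 1, 1)), Volume(p, (1, 1, 1))
        res = best_ji_map(gt, pred)
        ref = brute_force_best_ji(gt, pred)
        for m in res.matches:
            assert m.best_ji == pytest.approx(ref[m.gt_label][0])


def box(corner, size):
    c = np.asarray(corner, dtype=float)
    return (c, c + np.asarray(size, dtype=float))


class TestDetectionMatch:
    def test_identical_sets(self):
        boxes = [box((0, 0, 0), (2, 2, 2)), box((5, 5, 5), (3, 3, 3))]
        assert detection_match(boxes, boxes) == (2, 0, 0)

    def test_two_preds_one_gt(self):
        gt = [box((0, 0, 0), (4, 4, 4))]
        pred = [box((0, 0, 0), (3, 3, 3)), box((1, 1, 1), (3, 3, 3))]
        assert detection_match(gt, pred) == (0, 2, 1)

    def test_disjoint_sets(self):
        gt = [box((0, 0, 0), (2, 2, 2)), box((4, 4, 4), (2, 2, 2))]
        pred = [box((10, 10, 10), (2, 2, 2))]
        assert detection_match(gt, pred) == (0, 0, 2)

    def test_one_to_one_offset(self):
        gt = [box((0, 0, 0), (4, 4, 4))]
        pred = [box((1, 1, 1), (4, 4, 4))]
        assert detection_match(gt, pred) == (1, 0, 0)

    def test_two_gts_one_pred(self):
        gt = [box((0, 0, 0), (2, 2, 2)), box((2, 2, 2), (2, 2, 2))]
        pred = [box((0, 0, 0), (4, 4, 4))]
        assert detection_match(gt, pred) == (0, 0, 2)

    def test_empty_predictions(self):
        gt = [box((0, 0, 0), (2, 2, 2))]
        assert detection_match(gt, []) == (0, 0, 1)

    def test_empty_ground_truth(self):
        pred = [box((0, 0, 0), (2, 2, 2))]
        assert detection_match([], pred) == (0, 0, 0)

    def test_mixed_configuration(self):
        gt = [box((0, 0, 0), (4, 4, 4)), box((10, 0, 0), (4, 4, 4)),
              box((20, 0, 0), (4, 4, 4))]
        pred = [box((0.5, 0, 0), (4, 4, 4)), box((10.5, 0, 0), (4, 4, 4))]
        assert detection_match(gt, pred) == (2, 0, 1)

    def test_non_mutual_pair_is_fn(self):
        # pred maps to gt0, but gt0's best pred is another one
        gt = [box((0, 0, 0), (4, 4, 4))]
        pred = [box((3, 3, 3), (4, 4, 4)), box((0.2, 0.2, 0.2), (4, 4, 4))]
        tp, fp, fn = detection_match(gt, pred)
        assert fp == 2 and tp == 0 and fn == 1  # both preds map to the one gt

    def test_permutation_invariance(self, rng):
        boxes_gt = [box(rng.uniform(0, 20, 3), rng.uniform(2, 4, 3)) for _ in range(6)]
        boxes_pr = [box(rng.uniform(0, 20, 3), rng.uniform(2, 4, 3)) for _ in range(6)]
        ref = detection_match(boxes_gt, boxes_pr)
        perm = rng.permutation(6)
        shuffled = detection_match([boxes_gt[i] for i in perm],
                                   [boxes_pr[i] for i in perm[::-1]])
        assert ref == shuffled

    def test_tp_bounded(self, rng):
        for _ in range(10):
            n_g, n_p = rng.integers(1, 6), rng.integers(1, 6)
            gs = [box(rng.uniform(0, 15, 3), rng.uniform(1, 5, 3)) for _ in range(n_g)]
            ps = [box(rng.uniform(0, 15, 3), rng.uniform(1, 5, 3)) for _ in range(n_p)]
            tp, fp, fn = detection_match(gs, ps)
            assert tp <= min(n_g, n_p)
            assert tp + fn == n_g


class TestBboxJi:
    def test_identical(self):
        b = box((0, 0, 0), (2, 2, 2))
        assert bbox_ji(b, b) == pytest.approx(1.0)

    def test_disjoint(self):
        assert bbox_ji(box((0, 0, 0), (1, 1, 1)), box((5, 5, 5), (1, 1, 1))) == 0.0

    def test_half_overlap(self):
        a = box((0, 0, 0), (2, 2, 2))
        b = box((1, 0, 0), (2, 2, 2))
        assert bbox_ji(a, b) == pytest.approx(8 / 24)


def static_meshes(n_frames, centers, radius=2.0):
    frames = []
    for t in range(n_frames):
        frames.append([make_icosphere(c, radius, 1, frame_index=t, instance_id=i + 1)
                       for i, c in enumerate(centers)])
    return frames


class TestTracking:
    def test_static_scene(self):
        frames = static_meshes(5, [(5.0, 5.0, 5.0), (15.0, 15.0, 15.0)])
        tracks = track_bboxes(frames)
        assert len(tracks) == 2
        assert all(len(t.frames) == 5 for t in tracks)
        assert all(len(set(t.instance_ids)) == 1 for t in tracks)

    def test_drifting_meshes_no_switch(self):
        frames = []
        for t in range(8):
            frames.append([
                make_icosphere((5.0 + 0.5 * t, 5.0, 5.0), 2.0, 1, t, 1),
                make_icosphere((15.0, 15.0 + 0.5 * t, 15.0), 2.0, 1, t, 2),
            ])
        tracks = track_bboxes(frames)
        assert len(tracks) == 2
        for tr in tracks:
            assert len(set(tr.instance_ids)) == 1

    def test_division_fixture(self):
        """A mesh replaced by two small meshes inside its old box."""
        frames = [[make_icosphere((10.0, 10.0, 10.0), 4.0, 1, 0, 1)],
                  [make_icosphere((10.0, 10.0, 8.5), 1.5, 1, 1, 2),
                   make_icosphere((10.0, 10.0, 11.5), 1.5, 1, 1, 3)]]
        tracks = track_bboxes(frames)
        assert len(tracks) == 3
        parent = tracks[0]
        children = [t for t in tracks if t.parent_track_id == parent.track_id]
        assert len(children) == 2

    def test_needs_frames(self):
        with pytest.raises(ValueError):
            track_bboxes([])


class TestQuantifications:
    def test_cell_counts_constant(self):
        frames = static_meshes(4, [(5.0, 5.0, 5.0), (15.0, 15.0, 15.0)])
        counts = cell_counts(track_bboxes(frames), 4)
        assert counts.tolist() == [2, 2, 2, 2]

    def test_cell_counts_division_step(self):
        frames = [[make_icosphere((10.0, 10.0, 10.0), 4.0, 1, t, 1)] for t in range(3)]
        frames += [[make_icosphere((10.0, 10.0, 8.5), 1.5, 1, t, 2),
                    make_icosphere((10.0, 10.0, 11.5), 1.5, 1, t, 3)] for t in range(3, 6)]
        counts = cell_counts(track_bboxes(frames), 6)
        assert counts.tolist() == [1, 1, 1, 2, 2, 2]

    def test_cell_counts_empty(self):
        assert cell_counts([], 3).tolist() == [0, 0, 0]

    def test_velocity_static(self):
        tracks = track_bboxes(static_meshes(4, [(5.0, 5.0, 5.0)]))
        assert np.allclose(velocity_distribution(tracks, 1.0), 0.0)

    def test_velocity_uniform_drift(self):
        frames = [[make_icosphere((5.0, 5.0, 5.0 + 0.8 * t), 2.0, 1, t, 1)]
                  for t in range(5)]
        speeds = velocity_distribution(track_bboxes(frames), frame_interval_minutes=2.0)
        assert np.allclose(speeds, 0.4)

    def test_velocity_hand_computed(self):
        frames = [[make_icosphere((20.0, 20.0, 20.0), 8.0, 1, 0, 1)],
                  [make_icosphere((20.0, 23.0, 24.0), 8.0, 1, 1, 1)],
                  [make_icosphere((20.0, 23.0, 36.0), 8.0, 1, 2, 1)]]
        speeds = velocity_distribution(track_bboxes(frames), 1.0)
        # steps of length 5 then 12
        assert sorted(np.round(speeds, 6).tolist()) == [5.0, 12.0]
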