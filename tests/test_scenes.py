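"""Synthetic scene generator: determinism, truth consistency, coder model."""

import numpy as np
import pytest

from fidtrack.analytics import segment_bouts, series_from_values
from fidtrack.detector import detect_markers
from fidtrack.scenes import (Pose, SceneSpec, TrackSegment, expected_kappa,
                             failure_fixtures, generate_scene, latent_series,
                             simulate_coder)


def _spec(dictionary, **kw):
    base = dict(frame_shape=(200, 200), n_frames=3, rois=[])
    base.update(kw)
    base.setdefault("tracks", {4: [TrackSegment(0, base["n_frames"],
                                                Pose((100, 100), 48))]})
    return SceneSpec(**base)


class TestGenerateScene:
    def test_same_seed_bit_identical(self, dictionary):
        s = _spec(dictionary, noise_sigma=0.02, seed=9)
        f1, _ = generate_scene(s, dictionary)
        f2, _ = generate_scene(_spec(dictionary, noise_sigma=0.02, seed=9),
                               dictionary)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
        f3, _ = generate_scene(_spec(dictionary, noise_sigma=0.02, seed=10),
                               dictionary)
        assert not all(np.array_equal(a, b) for a, b in zip(f1, f3))

    def test_static_marker_full_recall(self, dictionary):
        frames, truth = generate_scene(_spec(dictionary, n_frames=5), dictionary)
        for f in frames:
            dets = detect_markers(f, dictionary)
            assert [d.id for d in dets] == [4]

    def test_truth_pixels_consistent(self, dictionary):
        """Noise-free frames agree with the declared geometry: sampling the
        frame at each true data-cell center reproduces the code bits."""
        frames, truth = generate_scene(_spec(dictionary, n_frames=1), dictionary)
        frame = frames[0].astype(float) / 255
        row = truth.frames.iloc[0]
        quad = row[["x0", "y0", "x1", "y1", "x2", "y2",
                    "x3", "y3"]].values.reshape(4, 2).astype(float)
        code = dictionary[int(row["id"])]
        # bilinear cell centers inside the border: cells (1..4) of the 6-cell
        # border square, via the bilinear map of the quad
        def at(u, v):
            top = quad[0] + u * (quad[1] - quad[0])
            bot = quad[3] + u * (quad[2] - quad[3])
            p = top + v * (bot - top)
            return frame[int(round(p[1])), int(round(p[0]))]

        for r in range(4):
            for c in range(4):
                u = (c + 1.5) / 6
                v = (r + 1.5) / 6
                assert (at(u, v) > 0.5) == bool(code.bits[r, c])

    def test_occlusion_suppresses_detection(self, dictionary):
        s = _spec(dictionary, n_frames=2,
                  tracks={4: [TrackSegment(0, 2, Pose((100, 100), 48),
                                           occluded_frac=0.5)]})
        frames, _ = generate_scene(s, dictionary)
        assert all(detect_markers(f, dictionary) == [] for f in frames)

    def test_infeasible_pose_raises(self, dictionary):
        s = _spec(dictionary,
                  tracks={4: [TrackSegment(0, 3, Pose((100, 100), 500))]})
        with pytest.raises(ValueError, match="larger than frame"):
            generate_scene(s, dictionary)

    def test_marker_absent_when_no_segment(self, dictionary):
        s = _spec(dictionary, n_frames=6,
                  tracks={4: [TrackSegment(2, 4, Pose((100, 100), 48))]})
        frames, truth = generate_scene(s, dictionary)
        assert truth.visible_ids(0) == [] and truth.visible_ids(3) == [4]
        assert detect_markers(frames[0], dictionary) == []
        assert [d.id for d in detect_markers(frames[2], dictionary)] == [4]


class TestSimulateCoder:
    def test_zero_error_identity(self):
        truth = np.array([0, 1, 1, 0, 1], np.uint8)
        assert np.array_equal(simulate_coder(truth, seed=0), truth)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        truth = (rng.random(500) < 0.3).astype(np.uint8)
        a = simulate_coder(truth, 0.1, 0.02, 2, seed=5)
        b = simulate_coder(truth, 0.1, 0.02, 2, seed=5)
        assert np.array_equal(a, b)

    def test_jitter_preserves_bout_count(self):
        truth = np.zeros(400, np.uint8)
        truth[50:90] = 1
        truth[250:300] = 1
        coded = simulate_coder(truth, boundary_jitter=3, seed=1)
        b_t = segment_bouts(series_from_values(truth, resolution="second"),
                            gap_threshold=60)
        b_c = segment_bouts(series_from_values(coded, resolution="second"),
                            gap_threshold=60)
        assert len(b_t) == len(b_c) == 2
        assert not np.array_equal(truth, coded)  # durations perturbed

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_coder(np.zeros(5), miss_rate=1.5)

    def test_expected_kappa_extremes(self):
        assert expected_kappa(0.3, 0.0, 0.0) == pytest.approx(1.0)
        assert expected_kappa(0.5, 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def fixtures(dictionary):
    return failure_fixtures(dictionary, seed=0)


class TestFailureFixtures:
    def test_adjacent_rois_double_membership(self, fixtures, dictionary):
        from fidtrack.roi import assign_rois

        spec, frames, truth = fixtures["adjacent_rois"]
        hits = [assign_rois(d, spec.rois)
                for f in frames for d in detect_markers(f, dictionary)]
        assert hits and all(len(h) == 2 for h in hits)

    def test_separated_rois_single_membership(self, fixtures, dictionary):
        from fidtrack.roi import assign_rois

        spec, frames, truth = fixtures["separated_rois"]
        hits = [assign_rois(d, spec.rois)
                for f in frames for d in detect_markers(f, dictionary)]
        assert hits and all(len(h) == 1 for h in hits)

    def test_drifting_resource_changes_roi(self, fixtures, dictionary):
        from fidtrack.roi import assign_rois

        spec, frames, truth = fixtures["drifting_resource"]
        first = assign_rois(detect_markers(frames[0], dictionary)[0], spec.rois)
        last = assign_rois(detect_markers(frames[-1], dictionary)[0], spec.rois)
        assert first == [0] and last == [1]

    def test_presence_without_use_depresses_kappa(self, fixtures, dictionary):
        from fidtrack.agreement import cohen_kappa

        spec, frames, truth = fixtures["presence_without_use"]
        n = spec.n_frames
        present = latent_series(truth, 0, n, state="present")
        using = latent_series(truth, 0, n, state="using")
        assert present.all() and not using.all()
        k = cohen_kappa(present, using)
        assert not k.defined or k.estimate < 1.0

    def test_fur_occlusion_detection_gap(self, fixtures, dictionary):
        spec, frames, truth = fixtures["fur_occlusion"]
        per_frame = [len(detect_markers(f, dictionary)) for f in frames]
        assert per_frame[:10] == [1] * 10
        assert per_frame[10:20] == [0] * 10
        assert per_frame[20:] == [1] * 10
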