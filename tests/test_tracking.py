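"""Tests for blob linking, body-length estimation and BLPS."""

import numpy as np
import pytest

from wormtriage.errors import (
    DivisionGuardError,
    InputStructureError,
    NoDataError,
    ZeroBodyLengthError,
)
from wormtriage.imaging import Blob, label_components
from wormtriage.simulate import WormSimParams, simulate_worm_video
from wormtriage.tracking import (
    MotilitySummary,
    WormTrack,
    body_length,
    compute_track_metrics,
    link_tracks,
    summarize_plate,
    track_speed_blps,
    track_stack,
)


def point_blob(r, c, frame=0):
    coords = np.array([[int(round(r)), int(round(c))]])
    return Blob(frame, (float(r), float(c)), 1, 0.0, coords, (int(r), int(c), int(r) + 1, int(c) + 1))


def frames_from_positions(positions_per_frame):
    return [
        [point_blob(r, c, frame=t) for r, c in frame_positions]
        for t, frame_positions in enumerate(positions_per_frame)
    ]


class TestLinking:
    def test_single_translating_blob_gives_one_track(self):
        frames = frames_from_positions([[(10, 10 + 3 * t)] for t in range(50)])
        tracks = link_tracks(frames, max_displacement_px=10)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 50

    def test_two_distant_worms_never_swap(self):
        frames = frames_from_positions(
            [[(10, 10 + 3 * t), (110, 10 + 3 * t)] for t in range(30)]
        )
        tracks = link_tracks(frames, max_displacement_px=10)
        assert len(tracks) == 2
        rows = {round(tr.points[0][1]): tr for tr in tracks}
        assert all(p[1] == 10 for p in rows[10].points)
        assert all(p[1] == 110 for p in rows[110].points)

    def test_jump_beyond_gate_splits_track(self):
        positions = [[(10, 10 + 3 * t)] for t in range(10)]
        positions += [[(10, 37 + 20 + 3 * t)] for t in range(10)]
        tracks = link_tracks(frames_from_positions(positions), max_displacement_px=10)
        assert sorted(tr.n_frames for tr in tracks) == [10, 10]

    def test_min_track_frames_filters(self):
        frames = frames_from_positions([[(5, 5 + t)] for t in range(8)])
        assert link_tracks(frames, 5, min_track_frames=9) == []
        assert len(link_tracks(frames, 5, min_track_frames=8)) == 1

    def test_permutation_invariance_within_frames(self):
        rng = np.random.default_rng(11)
        base = [
            [(10.0, 10 + 2.0 * t), (40.0, 10 + 2.0 * t), (70.0, 10 + 2.0 * t)]
            for t in range(20)
        ]
        ref = link_tracks(frames_from_positions(base), 8)
        shuffled = [list(f) for f in base]
        for f in shuffled:
            rng.shuffle(f)
        got = link_tracks(frames_from_positions(shuffled), 8)
        key = lambda tr: tr.points[0][1:]
        assert sorted([tr.points for tr in ref], key=lambda p: p[0]) == sorted(
            [tr.points for tr in got], key=lambda p: p[0]
        )

    def test_equidistant_conflict_goes_to_lower_track_id(self):
        # two tracks converge symmetrically on one blob
        frames = frames_from_positions([[(10, 10), (20, 10)], [(15, 10)]])
        tracks = link_tracks(frames, max_displacement_px=10)
        winner = [tr for tr in tracks if tr.n_frames == 2]
        assert len(winner) == 1
        assert winner[0].points[0][1] == 10  # the earlier-seeded (lower-id) track

    def test_non_consecutive_dict_grouping_rejected(self):
        frames = {0: [point_blob(1, 1)], 2: [point_blob(1, 2)]}
        with pytest.raises(InputStructureError):
            link_tracks(frames, 5)


class TestBodyLengthAndSpeed:
    def test_rigid_line_body_length(self):
        mask = np.zeros((5, 44), dtype=bool)
        mask[2, 2:42] = True
        blob = label_components(mask)[0]
        track = WormTrack(0, [(0, *blob.centroid)], [blob])
        assert body_length(track, 1.0) == pytest.approx(39.0)

    def test_single_pixel_blobs_raise(self):
        track = WormTrack(0, [(0, 1.0, 1.0)], [point_blob(1, 1)])
        with pytest.raises(ZeroBodyLengthError):
            body_length(track, 1.0)

    def test_blps_arithmetic(self):
        track = WormTrack(0, [(0, 0, 0), (1, 0, 1)], [])
        track.body_length_um = 1000.0
        track.path_length_um = 2000.0
        track.duration_s = 10.0
        assert track_speed_blps(track) == pytest.approx(0.2)

    def test_stationary_worm_zero_blps(self):
        mask = np.zeros((5, 30), dtype=bool)
        mask[2, 2:28] = True
        blob = label_components(mask)[0]
        track = WormTrack(0, [(t, *blob.centroid) for t in range(10)], [blob] * 10)
        out = compute_track_metrics(track, 1.0, 0.2)
        assert out.blps == 0.0

    def test_zero_duration_guard(self):
        track = WormTrack(0, [(0, 0, 0)], [])
        track.body_length_um = 100.0
        track.path_length_um = 0.0
        track.duration_s = 0.0
        with pytest.raises(DivisionGuardError):
            track_speed_blps(track)

    def test_blps_invariant_to_pixel_size(self):
        """Pixel size cancels: path and body length scale together."""
        mask = np.zeros((6, 30), dtype=bool)
        mask[2:4, 2:28] = True
        blob = label_components(mask)[0]
        points = [(t, blob.centroid[0], blob.centroid[1] + 2.0 * t) for t in range(10)]
        for px in (1.0, 7.5):
            track = WormTrack(0, list(points), [blob] * 10)
            compute_track_metrics(track, px, 0.2)
            if px == 1.0:
                ref = track.blps
        assert track.blps == pytest.approx(ref)


class TestSummaries:
    def test_mean_sem_closed_form(self):
        s = summarize_plate([0.1, 0.2, 0.3], "g")
        assert s.mean_blps == pytest.approx(0.2)
        assert s.sem_blps == pytest.approx(0.1 / np.sqrt(3))

    def test_percent_of_control(self):
        control = MotilitySummary("EV", 10, 0.20, 0.01)
        s = summarize_plate([0.12], "gene", control=control)
        assert s.pct_of_control == pytest.approx(60.0)

    def test_control_vs_itself_is_100(self):
        control = summarize_plate([0.2, 0.2, 0.2], "EV")
        s = summarize_plate([0.2, 0.2, 0.2], "EV", control=control)
        assert s.pct_of_control == pytest.approx(100.0)

    def test_empty_group_raises(self):
        with pytest.raises(NoDataError):
            summarize_plate([], "g")


class TestEndToEnd:
    def test_stationary_worm_tracked_at_near_zero_blps(self):
        params = WormSimParams(n_worms=1, speed_blps=0.0, duration_s=10.0)
        stack, truth = simulate_worm_video(params, seed=5)
        assert np.allclose(truth["centroids_px"][0, 0], truth["centroids_px"][0, -1])
        tracks = track_stack(stack, body_length_stride=5)
        assert len(tracks) == 1
        # undulating in place still wobbles the centroid a little; the
        # measured speed must sit well below the slowest crawling speed
        assert tracks[0].blps < 0.02

    def test_moving_worm_speed_recovered_within_5pct(self):
        params = WormSimParams(n_worms=1, speed_blps=0.15, duration_s=20.0)
        stack, _ = simulate_worm_video(params, seed=6)
        tracks = track_stack(stack, body_length_stride=5)
        assert len(tracks) == 1
        assert tracks[0].blps == pytest.approx(0.15, rel=0.05)

    def test_undulating_body_length_within_10pct(self):
        params = WormSimParams(n_worms=1, speed_blps=0.1, duration_s=10.0)
        stack, truth = simulate_worm_video(params, seed=7)
        tracks = track_stack(stack, body_length_stride=5)
        assert tracks[0].body_length_um == pytest.approx(
            truth["body_length_um"], rel=0.10
        )

    def test_track_count_matches_worm_count(self):
        params = WormSimParams(n_worms=3, speed_blps=0.12, duration_s=15.0)
        stack, _ = simulate_worm_video(params, seed=8)
        tracks = track_stack(stack, body_length_stride=5)
        assert len(tracks) == 3
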