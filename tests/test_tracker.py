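"""Tracking demo: synthetic renderer determinism and ground truth,
background model, subtraction, arc-search accuracy, writer formats, and the
fault-tolerance behaviour of the assembled fleet."""

from __future__ import annotations

import math

import numpy as np
import pytest

import fleetkit as fk
from fleetkit import data as fdata
from fleetkit.errors import SpecificationError
from fleetkit.tracker import (BinaryFrameWriter, LarvaSceneParams, TextRecordWriter,
                              TrackerConfig, build_demo_fleet, estimate_amplitude,
                              freeze_background, read_binary_frames,
                              read_text_records, render_frame, subtract, track_tail)
from fleetkit.tracker.pipeline import ForegroundFrame, TailTrackResult
from fleetkit.tracker.synthetic import render_background, truth_tail_angles


PARAMS = LarvaSceneParams()


class TestRenderer:
    def test_same_seed_identical_pixels(self):
        a = render_frame(PARAMS, 7, seed=3)
        b = render_frame(PARAMS, 7, seed=3)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.truth_angles == b.truth_angles

    def test_zero_amplitude_straight_tail(self):
        params = LarvaSceneParams(amplitude=0.0, noise_sigma=0.0)
        frame = render_frame(params, 5)
        assert all(a == params.heading for a in frame.truth_angles)

    def test_truth_angles_periodic(self):
        period = int(PARAMS.frame_rate / PARAMS.frequency)  # 50 frames
        a = truth_tail_angles(PARAMS, 3)
        b = truth_tail_angles(PARAMS, 3 + period)
        assert a == pytest.approx(b)

    def test_out_of_bounds_larva_rejected(self):
        params = LarvaSceneParams(head=(150.0, 60.0))
        with pytest.raises(SpecificationError, match="outside"):
            render_frame(params, 0)

    def test_geometry_invariants(self):
        frame = render_frame(PARAMS, 0)
        assert frame.pixels.shape == (PARAMS.height, PARAMS.width)
        assert len(frame.truth_angles) == PARAMS.segment_count


class TestBackground:
    def test_identical_frames_model_equals_frame(self):
        frames = [render_frame(LarvaSceneParams(noise_sigma=0.0), 0) for _ in range(5)]
        model = freeze_background(frames)
        assert np.array_equal(model.reference, frames[0].pixels.astype(float))
        assert model.frames_absorbed == 5

    def test_single_frame_model(self):
        frame = render_frame(PARAMS, 0)
        model = freeze_background([frame])
        assert np.array_equal(model.reference, frame.pixels.astype(float))

    def test_moving_tail_median_recovers_static_background(self):
        frames = [render_frame(PARAMS, t, seed=2) for t in range(50)]
        model = freeze_background(frames)
        clean = render_background(PARAMS, 2)
        # away from the static head/body, the median converges on the texture
        mask = np.ones_like(clean, dtype=bool)
        hx, hy = PARAMS.head
        reach = PARAMS.segment_count * PARAMS.segment_length + PARAMS.head_radius + 4
        yy, xx = np.mgrid[0:PARAMS.height, 0:PARAMS.width]
        mask &= ((xx - hx) ** 2 + (yy - hy) ** 2) > reach**2
        assert np.abs(model.reference - clean)[mask].mean() < 3.0

    def test_geometry_mismatch_rejected(self):
        f1 = render_frame(PARAMS, 0)
        f2 = render_frame(LarvaSceneParams(width=80, height=60, head=(20, 30),
                                           segment_length=6.0), 0)
        with pytest.raises(SpecificationError):
            freeze_background([f1, f2])


class TestSubtract:
    def test_frame_equals_model_all_zero(self):
        frame = render_frame(LarvaSceneParams(noise_sigma=0.0), 0)
        model = freeze_background([frame])
        fg = subtract(model, frame)
        assert not fg.pixels.any()

    def test_threshold_255_blanks_everything(self):
        frame = render_frame(PARAMS, 0)
        model = freeze_background([render_frame(PARAMS, 25)])
        assert not subtract(model, frame, threshold=255).pixels.any()

    def test_foreground_confined_to_larva_neighborhood(self):
        params = LarvaSceneParams(noise_sigma=0.0)
        clean = render_background(params, 0)
        bg_frame = render_frame(params, 0)
        model_ref = clean
        from fleetkit.tracker.pipeline import BackgroundModel
        model = BackgroundModel(model_ref.copy(), 1)
        frame = render_frame(params, 12)
        fg = subtract(model, frame, threshold=10)
        ys, xs = np.nonzero(fg.pixels)
        from fleetkit.tracker.synthetic import tail_points
        pts = np.array(tail_points(params, frame.truth_angles))
        # every foreground pixel lies near the larva skeleton (dilation slack)
        for x, y in zip(xs, ys):
            d = np.min(np.hypot(pts[:, 0] - x, pts[:, 1] - y))
            assert d < params.segment_length + params.head_radius + 3


class TestTrackTail:
    def _clean_foreground(self, params, t):
        from fleetkit.tracker.pipeline import BackgroundModel
        model = BackgroundModel(render_background(params, 0).copy(), 1)
        return subtract(model, render_frame(params, t), threshold=10)

    def test_straight_tail_recovered_within_tolerance(self):
        params = LarvaSceneParams(amplitude=0.0, noise_sigma=0.0)
        fg = self._clean_foreground(params, 0)
        cfg = TrackerConfig(head=params.head, heading=params.heading,
                            segment_length=params.segment_length,
                            segment_count=params.segment_count)
        result = track_tail(fg, cfg)
        assert result.success
        assert len(result.segment_points) == params.segment_count + 1
        for est, true in zip(result.segment_angles, (params.heading,) * 5):
            assert abs(est - true) < 0.05

    def test_blank_foreground_fails_gracefully(self):
        fg = ForegroundFrame(160, 120, np.zeros((120, 160), dtype=np.uint8), 0)
        result = track_tail(fg, TrackerConfig())
        assert not result.success

    def test_oscillating_tail_mean_error_below_tolerance(self):
        params = LarvaSceneParams(noise_sigma=0.0)
        cfg = TrackerConfig(head=params.head, heading=params.heading,
                            segment_length=params.segment_length,
                            segment_count=params.segment_count)
        period = int(params.frame_rate / params.frequency)
        errors = []
        for t in range(period):
            fg = self._clean_foreground(params, t)
            result = track_tail(fg, cfg)
            assert result.success
            truth = truth_tail_angles(params, t)
            errors.append(np.mean(np.abs(np.array(result.segment_angles) - truth)))
        assert float(np.mean(errors)) < 0.1

    def test_head_outside_frame_rejected(self):
        fg = ForegroundFrame(160, 120, np.zeros((120, 160), dtype=np.uint8), 0)
        with pytest.raises(SpecificationError):
            track_tail(fg, TrackerConfig(head=(500.0, 60.0)))


class TestWriters:
    def _result(self, idx):
        return TailTrackResult(idx, ((0.0, 0.0),), (0.1, -0.2), True)

    def test_text_lines_one_per_frame(self, tmp_path):
        writer = TextRecordWriter(tmp_path / "track.txt")
        for i in range(10):
            writer.write_result(self._result(i))
        writer.close()
        records = read_text_records(tmp_path / "track.txt")
        assert len(records) == 10
        assert records[3] == (3, (0.1, -0.2))

    def test_binary_size_arithmetic(self, tmp_path):
        params = LarvaSceneParams()
        writer = BinaryFrameWriter(tmp_path / "frames.bin")
        for t in range(10):
            writer.write_frame(render_frame(params, t))
        writer.close()
        size = (tmp_path / "frames.bin").stat().st_size
        assert size == 10 * (16 + params.width * params.height)
        frames = read_binary_frames(tmp_path / "frames.bin")
        assert [i for i, _ in frames] == list(range(10))
        assert np.array_equal(frames[0][1], render_frame(params, 0).pixels)


class TestDemoFleet:
    def _run(self, tmp_path, n_frames=120, kill_at=None):
        params = LarvaSceneParams()
        fleet = build_demo_fleet(tmp_path, params, n_frames=n_frames, seed=4,
                                 model_frames=30)
        fleet.launch(threaded=False)
        meta = fleet.vessels["ExperimentMetadata"]
        meta.execute_call(lambda m: (m.set_info(experiment_name="t"),
                                     m.export({"segment_count": params.segment_count,
                                               "subtraction_threshold": 10.0})))
        fleet.vessels["BinaryWriter"].reload()
        fleet.vessels["OutputWriter"].reload()
        fleet.vessels["MockCamera"].reload()
        camera = fleet.vessels["MockCamera"]
        frame_no = 0
        while fdata.generate_data(camera) > 0:
            frame_no += 1
            if kill_at is not None and frame_no == kill_at:
                fleet.vessels["TrackingAlgorithm"].execute_call(lambda c: 1 / 0)
            fleet.pump()
        fleet.pump()
        paths = meta.component.current
        counters = {
            "binary": fleet.vessels["BinaryWriter"].component.frames_written,
            "display_frames": fleet.vessels["Display"].component.frames_shown,
        }
        fleet.shutdown()
        return fleet, paths, counters

    def test_metadata_file_records_parameters(self, tmp_path):
        _, paths, _ = self._run(tmp_path, n_frames=40)
        text = paths.metadata_file.read_text()
        assert "segment_count = 5" in text
        assert "subtraction_threshold = 10.0" in text

    def test_end_to_end_recovery_and_recording(self, tmp_path):
        params = LarvaSceneParams()
        _, paths, counters = self._run(tmp_path, n_frames=150)
        records = read_text_records(paths.text_path)
        assert len(records) == 150 - 30  # warmup frames build the background
        assert counters["binary"] == 150
        terminal = np.array([angles[-1] for _, angles in records])
        assert estimate_amplitude(terminal) == pytest.approx(params.amplitude, rel=0.1)

    def test_killing_tracker_spares_camera_and_binary_writer(self, tmp_path):
        _, paths, counters = self._run(tmp_path, n_frames=120, kill_at=80)
        records = read_text_records(paths.text_path)
        assert counters["binary"] == 120  # binary stream kept growing
        # text output froze when the tracker died (80 frames in, 30 warmup,
        # minus the one in flight)
        assert len(records) < 120 - 30
        assert len(records) >= 80 - 30 - 1

    def test_one_output_folder_per_export(self, tmp_path):
        self._run(tmp_path, n_frames=40)
        folders = [p for p in tmp_path.iterdir() if p.is_dir()]
        assert len(folders) == 1
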