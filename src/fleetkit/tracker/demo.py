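"""Assembly and scripted operation of the demo tracking fleet.

Topology (link dependencies in parentheses):

* ``MockCamera`` — synthetic movie source emitting frames
* ``BGSubtractor`` — transformer: frame -> foreground (median background)
* ``TrackingAlgorithm`` — transformer: foreground -> tail track result
* ``Display`` — stub sink counting frames and results
* ``ExperimentMetadata`` — export manager establishing recording paths
* ``BinaryWriter`` (dep: ExperimentMetadata) — sink recording raw frames
* ``OutputWriter`` (dep: ExperimentMetadata) — sink recording tail metrics

The writers read their output paths from the metadata component when they
build, so they stay offline until an export has established the paths; the
scripted protocol (configure, export, reload writers, re-arm the camera)
mirrors how the interactive application is operated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .. import data as _data
from ..fleet import Fleet
from .io import (BinaryFrameWriter, ExperimentMetadataManager, TextRecordWriter,
                 read_text_records)
from .pipeline import (BackgroundSubtractor, DisplayStub, ForegroundFrame,
                       TailTracker, TailTrackResult, TrackerConfig)
from .synthetic import LarvaSceneParams, SyntheticFrame, SyntheticMovieCamera


def build_demo_fleet(out_dir: str | Path, params: Optional[LarvaSceneParams] = None,
                     n_frames: int = 500, seed: int = 0,
                     model_frames: int = 50, threshold: float = 10.0,
                     tracker_config: Optional[TrackerConfig] = None,
                     settings_path: str | Path | None = None) -> Fleet:
    params = params or LarvaSceneParams()
    tracker_config = tracker_config or TrackerConfig(
        head=params.head, heading=params.heading,
        segment_length=params.segment_length, segment_count=params.segment_count)
    fleet = Fleet("tracker-demo", settings_path=settings_path)

    camera = fleet.freight(
        "MockCamera", lambda: SyntheticMovieCamera(params, n_frames, seed),
        queue_capacity=8, source_rate=params.frame_rate)
    # one frame per generate-data tick: the movie is paced by the poller,
    # not drained as a burst
    _data.add_source(camera, lambda cam: (cam.grab(), False),
                     output_type=SyntheticFrame, name="camera_frames")

    subtractor = fleet.freight(
        "BGSubtractor", lambda: BackgroundSubtractor(model_frames, threshold),
        queue_capacity=256)
    _data.add_transformer(subtractor, lambda comp, frame, md: comp.feed(frame),
                          input_type=SyntheticFrame, output_type=ForegroundFrame,
                          name="subtract")

    tracker = fleet.freight("TrackingAlgorithm", lambda: TailTracker(tracker_config),
                            queue_capacity=256)
    _data.add_transformer(tracker, lambda comp, fg, md: comp.track(fg),
                          input_type=ForegroundFrame, output_type=TailTrackResult,
                          name="track")

    display = fleet.freight("Display", DisplayStub, queue_capacity=256)

    def _show_frame(comp, frame, md):
        comp.frames_shown += 1

    def _show_result(comp, result, md):
        comp.results_shown += 1

    _data.add_sink(display, _show_frame, input_type=SyntheticFrame, name="show_frames")
    _data.add_sink(display, _show_result, input_type=TailTrackResult, name="show_results")

    metadata = fleet.freight("ExperimentMetadata",
                             lambda: ExperimentMetadataManager(out_dir))

    binary_writer = fleet.freight(
        "BinaryWriter", lambda meta: BinaryFrameWriter(meta.binary_path),
        invalidator=lambda meta, writer: writer.close(),
        dependencies=[metadata], queue_capacity=512)
    _data.add_sink(binary_writer, lambda comp, frame, md: comp.write_frame(frame),
                   input_type=SyntheticFrame, name="record_frames")

    output_writer = fleet.freight(
        "OutputWriter", lambda meta: TextRecordWriter(meta.text_path),
        invalidator=lambda meta, writer: writer.close(),
        dependencies=[metadata], queue_capacity=512)
    _data.add_sink(output_writer, lambda comp, result, md: comp.write_result(result),
                   input_type=TailTrackResult, name="record_metrics")

    return fleet


def estimate_amplitude(terminal_angles: np.ndarray, discard: int = 0) -> float:
    """Half the peak-to-peak excursion of the terminal-segment angle."""
    a = np.asarray(terminal_angles, dtype=float)
    if discard:
        a = a[discard:]
    return float((a.max() - a.min()) / 2.0)


@dataclass(frozen=True)
class DemoRunSummary:
    frames_emitted: int
    results_recorded: int
    frames_recorded: int
    amplitude_estimate: float
    mean_abs_angle_error: float
    out_folder: Path
    metadata_file: Path


def run_demo(out_dir: str | Path, params: Optional[LarvaSceneParams] = None,
             n_frames: int = 500, seed: int = 0, model_frames: int = 50,
             threshold: float = 10.0,
             experiment_name: str = "demo", animal_id: str = "synthetic-01"
             ) -> DemoRunSummary:
    """Run the scripted user protocol end to end (deterministic, unthreaded):
    launch, configure, export metadata, reload the camera and writers, then
    drive the movie through the fleet and summarize tracking accuracy
    against the renderer's hidden ground truth."""
    params = params or LarvaSceneParams()
    fleet = build_demo_fleet(out_dir, params, n_frames, seed,
                             model_frames=model_frames, threshold=threshold)
    fleet.launch(threaded=False)
    try:
        meta_vessel = fleet.vessels["ExperimentMetadata"]
        acquisition = {
            "segment_count": params.segment_count,
            "segment_length_px": params.segment_length,
            "background_model_frames": model_frames,
            "subtraction_threshold": threshold,
            "frame_rate_hz": params.frame_rate,
        }
        meta_vessel.execute_call(
            lambda m: (m.set_info(experiment_name=experiment_name, animal_id=animal_id),
                       m.export(acquisition)))
        # writers can only open their files once the export set the paths
        fleet.vessels["BinaryWriter"].reload()
        fleet.vessels["OutputWriter"].reload()
        fleet.vessels["MockCamera"].reload()  # restart the movie for recording

        camera = fleet.vessels["MockCamera"]
        emitted = 0
        while True:
            n = _data.generate_data(camera)
            if n == 0:
                break
            emitted += n
            fleet.pump()
        fleet.pump()

        meta = meta_vessel.component
        paths = meta.current
        records = read_text_records(paths.text_path)
        truth = {t: fleet_truth for t, fleet_truth in _truth_by_frame(params, n_frames)}
        terminal = np.array([angles[-1] for _, angles in records]) if records else np.array([0.0])
        errors = [np.mean(np.abs(np.array(angles) - np.array(truth[idx])))
                  for idx, angles in records if idx in truth and angles]
        binary_count = fleet.vessels["BinaryWriter"].component.frames_written
        return DemoRunSummary(
            frames_emitted=emitted,
            results_recorded=len(records),
            frames_recorded=binary_count,
            amplitude_estimate=estimate_amplitude(terminal),
            mean_abs_angle_error=float(np.mean(errors)) if errors else float("nan"),
            out_folder=paths.folder,
            metadata_file=paths.metadata_file,
        )
    finally:
        fleet.shutdown()


def _truth_by_frame(params: LarvaSceneParams, n_frames: int):
    from .synthetic import truth_tail_angles

    for t in range(n_frames):
        yield t, truth_tail_angles(params, t)
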