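"""Background subtraction and sequential arc-search tail tracking.

The background model is the per-pixel median of the first K frames: with a
beating tail, each tail pixel is occupied for well under half the frames, so
the median converges to the static background. Subtraction keeps the
absolute difference above a threshold, leaving the larva as the only bright
structure.

The tracker is the classical sequential arc search used for larval
zebrafish: starting at the (known, head-fixed) head position and resting
heading, candidate directions are sampled over an arc around the current
heading; the foreground intensity along each candidate segment is summed,
and the next segment angle is the intensity-weighted circular mean of the
candidates (weights raised to a sharpening power). The walk repeats for the
configured number of segments; if the arc carries almost no intensity at
any step, the frame is marked a tracking failure rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ..errors import SpecificationError
from .synthetic import SyntheticFrame


@dataclass(frozen=True)
class BackgroundModel:
    reference: np.ndarray  # float, shape (height, width); immutable after freeze
    frames_absorbed: int

    def __post_init__(self):
        self.reference.setflags(write=False)


@dataclass(frozen=True)
class ForegroundFrame:
    width: int
    height: int
    pixels: np.ndarray  # uint8 foreground (0 where background)
    frame_index: int


@dataclass(frozen=True)
class TailTrackResult:
    frame_index: int
    segment_points: tuple[tuple[float, float], ...]  # joints, head first
    segment_angles: tuple[float, ...]  # absolute angle per segment, radians
    success: bool


def freeze_background(frames: Sequence[SyntheticFrame]) -> BackgroundModel:
    """Per-pixel median over the given frames (K >= 1, uniform geometry)."""
    if not frames:
        raise SpecificationError("background model needs at least one frame")
    shape = frames[0].pixels.shape
    if any(f.pixels.shape != shape for f in frames):
        raise SpecificationError("frames have mismatched geometry")
    stack = np.stack([f.pixels.astype(np.float64) for f in frames])
    return BackgroundModel(np.median(stack, axis=0), len(frames))


def subtract(model: BackgroundModel, frame: SyntheticFrame,
             threshold: float = 10.0) -> ForegroundFrame:
    """Saturating absolute difference, zeroed at or below the threshold."""
    if frame.pixels.shape != model.reference.shape:
        raise SpecificationError("frame geometry does not match background model")
    diff = np.abs(frame.pixels.astype(np.float64) - model.reference)
    fg = np.where(diff > threshold, np.clip(diff, 0, 255), 0.0).astype(np.uint8)
    return ForegroundFrame(frame.width, frame.height, fg, frame.frame_index)


@dataclass(frozen=True)
class TrackerConfig:
    head: tuple[float, float] = (40.0, 60.0)
    heading: float = 0.0  # initial search direction, radians
    segment_length: float = 14.0  # pixels
    segment_count: int = 5
    half_angle: float = 0.7  # arc search half-width, radians
    arc_samples: int = 31  # candidate directions per segment
    radii: tuple[float, ...] = (0.5, 0.75, 1.0)  # sample radii, fractions of length
    weight_power: float = 2.0  # sharpening of the intensity weighting
    intensity_floor: float = 60.0  # minimum summed arc intensity per step


def _arc_step(fg: np.ndarray, x: float, y: float, heading: float,
              cfg: TrackerConfig) -> tuple[Optional[float], float]:
    """One arc search step: returns (estimated angle, total arc intensity)."""
    offsets = np.linspace(-cfg.half_angle, cfg.half_angle, cfg.arc_samples)
    angles = heading + offsets
    scores = np.zeros_like(angles)
    for frac in cfg.radii:
        r = frac * cfg.segment_length
        xs = x + r * np.cos(angles)
        ys = y + r * np.sin(angles)
        scores += ndimage.map_coordinates(fg, [ys, xs], order=1, mode="constant")
    total = float(scores.sum())
    if total < cfg.intensity_floor:
        return None, total
    w = scores ** cfg.weight_power
    est = heading + float((w * offsets).sum() / w.sum())
    return est, total


def track_tail(foreground: ForegroundFrame, config: TrackerConfig) -> TailTrackResult:
    """Sequential arc search from the head. Failure (insufficient intensity
    at any step, e.g. a blank foreground) is encoded in the result, never
    raised."""
    h, w = foreground.pixels.shape
    x, y = config.head
    if not (0 <= x < w and 0 <= y < h):
        raise SpecificationError(f"head point ({x}, {y}) outside the frame")
    fg = foreground.pixels.astype(np.float64)
    heading = config.heading
    points: list[tuple[float, float]] = [(x, y)]
    angles: list[float] = []
    for _ in range(config.segment_count):
        est, _total = _arc_step(fg, x, y, heading, config)
        if est is None:
            return TailTrackResult(foreground.frame_index, tuple(points),
                                   tuple(angles), success=False)
        x += config.segment_length * math.cos(est)
        y += config.segment_length * math.sin(est)
        points.append((x, y))
        angles.append(est)
        heading = est
    return TailTrackResult(foreground.frame_index, tuple(points), tuple(angles), True)


# ----------------------------------------------------------------------
# stateful components for the demo fleet


class BackgroundSubtractor:
    """Absorbs the first ``model_frames`` frames into a median background,
    then emits thresholded foregrounds for every later frame."""

    def __init__(self, model_frames: int = 50, threshold: float = 10.0):
        self.model_frames = model_frames
        self.threshold = threshold
        self._warmup: list[SyntheticFrame] = []
        self.model: Optional[BackgroundModel] = None

    def feed(self, frame: SyntheticFrame) -> Optional[ForegroundFrame]:
        if self.model is None:
            self._warmup.append(frame)
            if len(self._warmup) >= self.model_frames:
                self.model = freeze_background(self._warmup)
                self._warmup.clear()
            return None
        return subtract(self.model, frame, self.threshold)


class TailTracker:
    """Stateful wrapper holding the tracker configuration."""

    def __init__(self, config: Optional[TrackerConfig] = None):
        self.config = config or TrackerConfig()
        self.frames_tracked = 0

    def track(self, foreground: ForegroundFrame) -> TailTrackResult:
        result = track_tail(foreground, self.config)
        self.frames_tracked += 1
        return result

    # exposed as readable acquisition parameters for metadata collection
    @property
    def segment_count(self) -> int:
        return self.config.segment_count

    @property
    def segment_length(self) -> float:
        return self.config.segment_length


class DisplayStub:
    """Counts rendered messages in place of a window, preserving the data
    graph topology of the interactive application."""

    def __init__(self):
        self.frames_shown = 0
        self.results_shown = 0
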