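"""Synthetic larva movie generator with ground-truth tail kinematics.

Each frame shows a bright larva on a static textured background: a fixed
head blob and a tail of connected straight segments whose absolute angles
follow a travelling sine wave,

    theta_k(t) = heading + A * sin(2*pi*f*t/frame_rate + k*phi),

where ``A`` is the beat amplitude (radians), ``f`` the beat frequency (Hz),
``phi`` the phase lag per segment, and ``k`` the segment index. The
generating angles are recorded with every frame (hidden from the pipeline),
so tracking accuracy can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from ..errors import SpecificationError


@dataclass(frozen=True)
class LarvaSceneParams:
    """Geometry and kinematics of the synthetic scene.

    Defaults give a 160x120 movie at 100 frames/s of a 5-segment tail
    beating at 2 Hz with 0.5 rad amplitude — a scaled-down but
    kinematically faithful stand-in for a head-fixed larva recording.
    """

    width: int = 160
    height: int = 120
    head: tuple[float, float] = (40.0, 60.0)  # (x, y) pixels
    heading: float = 0.0  # resting tail direction, radians (+x axis)
    segment_length: float = 14.0  # pixels
    segment_count: int = 5
    amplitude: float = 0.5  # A, radians
    frequency: float = 2.0  # f, Hz (tail beats)
    frame_rate: float = 100.0  # frames per second
    phase_lag: float = 0.4  # phi, radians per segment
    noise_sigma: float = 3.0  # additive Gaussian pixel noise (gray levels)
    head_radius: float = 5.0
    tail_radius: tuple[float, float] = (3.0, 1.2)  # taper base -> tip
    larva_intensity: float = 215.0
    margin: float = 4.0  # required clearance from the frame border


@dataclass(frozen=True)
class SyntheticFrame:
    width: int
    height: int
    pixels: np.ndarray  # uint8, shape (height, width), row-major, origin top-left
    frame_index: int
    truth_angles: tuple[float, ...]  # ground truth, hidden from the pipeline

    def __post_init__(self):
        if self.pixels.shape != (self.height, self.width):
            raise SpecificationError("pixel array does not match declared geometry")


def truth_tail_angles(params: LarvaSceneParams, t: int) -> tuple[float, ...]:
    omega = 2 * math.pi * params.frequency * t / params.frame_rate
    return tuple(params.heading + params.amplitude * math.sin(omega + k * params.phase_lag)
                 for k in range(params.segment_count))


def tail_points(params: LarvaSceneParams, angles) -> list[tuple[float, float]]:
    """Joint coordinates (segment_count + 1 points) for a set of segment angles."""
    points = [params.head]
    x, y = params.head
    for theta in angles:
        x += params.segment_length * math.cos(theta)
        y += params.segment_length * math.sin(theta)
        points.append((x, y))
    return points


_background_cache: dict[tuple, np.ndarray] = {}


def render_background(params: LarvaSceneParams, seed: int) -> np.ndarray:
    """Static smooth random texture, deterministic per (geometry, seed)."""
    key = (params.width, params.height, seed)
    if key not in _background_cache:
        rng = np.random.default_rng(seed)
        coarse = rng.uniform(20.0, 55.0, size=(params.height // 8 + 2, params.width // 8 + 2))
        fine = np.kron(coarse, np.ones((8, 8)))[: params.height, : params.width]
        _background_cache[key] = ndimage.gaussian_filter(fine, sigma=4.0)
    return _background_cache[key]


def _stamp_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    h, w = img.shape
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    patch = img[y0:y1, x0:x1]
    patch[mask] = np.maximum(patch[mask], value)


def render_frame(params: LarvaSceneParams, t: int, seed: int = 0) -> SyntheticFrame:
    """Render frame ``t``: deterministic given (params, t, seed)."""
    angles = truth_tail_angles(params, t)
    points = tail_points(params, angles)
    m = params.margin
    for x, y in points:
        if not (m <= x < params.width - m and m <= y < params.height - m):
            raise SpecificationError(
                f"larva point ({x:.1f}, {y:.1f}) outside frame at t={t}")
    img = render_background(params, seed).copy()
    r_base, r_tip = params.tail_radius
    total = params.segment_count
    for k in range(total):
        (x0, y0), (x1, y1) = points[k], points[k + 1]
        steps = max(2, int(3 * params.segment_length))
        for s in range(steps + 1):
            u = s / steps
            frac = (k + u) / total
            radius = r_base + (r_tip - r_base) * frac
            _stamp_disk(img, x0 + u * (x1 - x0), y0 + u * (y1 - y0),
                        radius, params.larva_intensity)
    _stamp_disk(img, *params.head, params.head_radius, params.larva_intensity + 20)
    if params.noise_sigma > 0:
        noise_rng = np.random.default_rng([seed, 1_000_003 + t])
        img = img + noise_rng.normal(0.0, params.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticFrame(params.width, params.height, pixels, t, angles)


class SyntheticMovieCamera:
    """Mock camera: grabs successive synthetic frames until the movie ends."""

    def __init__(self, params: Optional[LarvaSceneParams] = None,
                 n_frames: int = 500, seed: int = 0):
        self.params = params or LarvaSceneParams()
        self.n_frames = n_frames
        self.seed = seed
        self._cursor = 0
        self.frame_rate = self.params.frame_rate

    def grab(self) -> Optional[SyntheticFrame]:
        if self._cursor >= self.n_frames:
            return None
        frame = render_frame(self.params, self._cursor, self.seed)
        self._cursor += 1
        return frame

    @property
    def frames_remaining(self) -> int:
        return self.n_frames - self._cursor
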