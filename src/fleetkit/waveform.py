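"""Waveform sequencing for synchronous hardware control.

Waveform synthesizers render parametric shapes into sample arrays; a
pattern block aligns one such track per physical channel (plus software
instructions scheduled at sample positions on virtual channels); the
sequencer concatenates a schedule of blocks, with repeats, into the full
per-channel output arrays and an absolute-indexed virtual-instruction
timeline. A simulated sample clock then fires the virtual instructions in
order, which is how software actions stay aligned with hardware output
without a real device.

Sample indices are 0-based; virtual-event positions within a block live in
the half-open range [0, length). Digital tracks are stored as 0/1 samples so
all tracks share one array representation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, SpecificationError


class ChannelKind(Enum):
    ANALOG = "analog"
    DIGITAL = "digital"
    VIRTUAL = "virtual"


@dataclass(frozen=True)
class Channel:
    name: str
    kind: ChannelKind = ChannelKind.ANALOG
    value_range: Optional[tuple[float, float]] = None  # volts, ANALOG only


class Shape(Enum):
    CONSTANT = "constant"
    SQUARE = "square"
    RAMP = "ramp"
    SINE = "sine"
    SAMPLES = "samples"


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric waveform. For SINE, sample i is
    ``offset + amplitude * sin(2*pi*frequency*i/sample_rate + phase)``;
    SQUARE is high (offset + amplitude) for the first ``duty`` fraction of
    each period and at ``offset`` otherwise; RAMP rises linearly from
    ``offset`` to ``offset + amplitude`` (per period when a frequency is
    given, across the whole duration otherwise); CONSTANT holds ``offset``.
    SAMPLES passes an explicit sample list through unchanged."""

    shape: Shape
    amplitude: float = 1.0
    offset: float = 0.0
    frequency: Optional[float] = None  # Hz
    duty: float = 0.5
    phase: float = 0.0  # radians
    samples: Optional[tuple[float, ...]] = None

    @classmethod
    def constant(cls, value: float) -> "WaveformSpec":
        return cls(Shape.CONSTANT, offset=value)

    @classmethod
    def from_samples(cls, samples: Sequence[float]) -> "WaveformSpec":
        return cls(Shape.SAMPLES, samples=tuple(float(s) for s in samples))


def synthesize(spec: WaveformSpec, sample_rate: float, duration: float) -> np.ndarray:
    """Render ``round(sample_rate * duration)`` samples (at least one)."""
    if sample_rate <= 0:
        raise ConfigurationError(f"sample_rate must be positive, got {sample_rate}")
    if duration <= 0:
        raise ConfigurationError(f"duration must be positive, got {duration}")
    n = int(round(sample_rate * duration))
    if n < 1:
        raise ConfigurationError(
            f"duration {duration} s at {sample_rate} Hz yields no samples")
    i = np.arange(n)
    if spec.shape is Shape.CONSTANT:
        return np.full(n, spec.offset, dtype=float)
    if spec.shape is Shape.SAMPLES:
        if spec.samples is None:
            raise SpecificationError("SAMPLES waveform requires explicit samples")
        arr = np.asarray(spec.samples, dtype=float)
        if arr.size != n:
            raise SpecificationError(
                f"explicit sample list has {arr.size} samples, expected {n}")
        return arr.copy()
    if spec.frequency is None:
        if spec.shape is Shape.RAMP:
            ramp = i / (n - 1) if n > 1 else np.zeros(1)
            return spec.offset + spec.amplitude * ramp
        raise SpecificationError(f"{spec.shape.name} waveform requires a frequency")
    frac = (spec.frequency * i / sample_rate + spec.phase / (2 * np.pi)) % 1.0
    if spec.shape is Shape.SINE:
        return spec.offset + spec.amplitude * np.sin(
            2 * np.pi * spec.frequency * i / sample_rate + spec.phase)
    if spec.shape is Shape.SQUARE:
        return np.where(frac < spec.duty, spec.offset + spec.amplitude, spec.offset)
    if spec.shape is Shape.RAMP:
        return spec.offset + spec.amplitude * frac
    raise SpecificationError(f"unknown waveform shape {spec.shape}")  # pragma: no cover


@dataclass(frozen=True)
class PatternBlock:
    """An aligned multi-channel waveform segment plus virtual events."""

    sample_rate: float
    length: int
    channel_tracks: Mapping[str, np.ndarray]
    virtual_events: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        for name, track in self.channel_tracks.items():
            if len(track) != self.length:
                raise SpecificationError(
                    f"channel {name!r} has {len(track)} samples, block length is {self.length}")
        for index, instruction in self.virtual_events:
            if not 0 <= index < self.length:
                raise SpecificationError(
                    f"virtual event {instruction!r} at index {index} outside [0, {self.length})")


def build_block(sample_rate: float, duration: float,
                tracks: Mapping[str, WaveformSpec | np.ndarray | Sequence[float]],
                virtual: Sequence[tuple[int, str]] = ()) -> PatternBlock:
    """Synthesize each channel's waveform to a common length and validate
    the virtual-event schedule. Tracks may be given as parametric specs or
    as raw sample arrays (which must already have the right length)."""
    rendered: dict[str, np.ndarray] = {}
    for name, track in tracks.items():
        if isinstance(track, WaveformSpec):
            rendered[name] = synthesize(track, sample_rate, duration)
        else:
            rendered[name] = np.asarray(track, dtype=float)
    lengths = {name: len(a) for name, a in rendered.items()}
    if len(set(lengths.values())) > 1:
        raise SpecificationError(f"channel lengths are not aligned: {lengths}")
    length = next(iter(lengths.values())) if lengths else int(round(sample_rate * duration))
    return PatternBlock(sample_rate, length, rendered,
                        tuple((int(i), str(instr)) for i, instr in virtual))


@dataclass(frozen=True)
class SequencedOutput:
    """Concatenated per-channel arrays plus the absolute virtual timeline."""

    sample_rate: Optional[float]
    channel_arrays: Mapping[str, np.ndarray]
    total_length: int
    virtual_timeline: tuple[tuple[int, str], ...]  # (absolute sample index, instruction)

    def to_csv(self, path: str | Path) -> None:
        names = sorted(self.channel_arrays)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(names)
            for row in zip(*(self.channel_arrays[n] for n in names)):
                writer.writerow([f"{v:g}" for v in row])


def sequence(schedule: Sequence[tuple[PatternBlock, int]]) -> SequencedOutput:
    """Concatenate blocks in schedule order with repeats. All blocks must
    share one sample rate and one channel set; virtual events are offset by
    the cumulative sample position of each repetition."""
    if not schedule:
        return SequencedOutput(None, {}, 0, ())
    rates = {block.sample_rate for block, _ in schedule}
    if len(rates) > 1:
        raise SpecificationError(f"heterogeneous sample rates: {sorted(rates)}")
    channel_sets = {frozenset(block.channel_tracks) for block, _ in schedule}
    if len(channel_sets) > 1:
        raise SpecificationError("blocks do not share one channel set")
    channels = sorted(next(iter(channel_sets)))
    pieces: dict[str, list[np.ndarray]] = {name: [] for name in channels}
    timeline: list[tuple[int, str]] = []
    position = 0
    for block, repeats in schedule:
        if repeats < 0:
            raise SpecificationError(f"negative repeat count {repeats}")
        for _ in range(repeats):
            for name in channels:
                pieces[name].append(block.channel_tracks[name])
            for index, instruction in block.virtual_events:
                timeline.append((position + index, instruction))
            position += block.length
    arrays = {name: (np.concatenate(chunks) if chunks else np.empty(0))
              for name, chunks in pieces.items()}
    timeline.sort(key=lambda e: e[0])
    return SequencedOutput(schedule[0][0].sample_rate, arrays, position, tuple(timeline))


@dataclass(frozen=True)
class FiredEvent:
    intended_index: int
    fired_order: int
    instruction: str
    error: Optional[str] = None


class SimulatedClock:
    """A software sample clock: advances monotonically through absolute
    sample indices. Stands in for hardware pacing when no device exists."""

    def __init__(self):
        self.position = 0

    def advance_to(self, index: int) -> None:
        if index < self.position:
            raise ConfigurationError("simulated clock cannot run backwards")
        self.position = index


def run_virtual(sequenced: SequencedOutput,
                handlers: Mapping[str, Callable[[int], None]],
                clock: Optional[SimulatedClock] = None) -> list[FiredEvent]:
    """Fire every virtual-timeline instruction exactly once, in absolute
    index order, against the provided handlers. Missing handlers are a
    pre-run validation error; a raising handler is recorded in the fired log
    and the remaining events still fire."""
    instructions = {instr for _, instr in sequenced.virtual_timeline}
    missing = instructions - set(handlers)
    if missing:
        raise ConfigurationError(f"no handler for instruction(s): {sorted(missing)}")
    clock = clock or SimulatedClock()
    log: list[FiredEvent] = []
    for order, (index, instruction) in enumerate(sequenced.virtual_timeline):
        clock.advance_to(index)
        error = None
        try:
            handlers[instruction](index)
        except Exception as exc:  # noqa: BLE001 - handler failures are contained
            error = f"{type(exc).__name__}: {exc}"
        log.append(FiredEvent(index, order, instruction, error))
    return log
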