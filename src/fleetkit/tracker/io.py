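"""Recording components: text metrics, raw binary frame stream, metadata export.

Text records: one line per tracked frame, ``frame_index<TAB>angle_1..angle_N``
(angles in radians, 6 decimals). Binary stream: frames concatenated, each
preceded by a fixed 16-byte header — 4-byte magic ``SFRM``, then width,
height and frame index as little-endian uint32 — followed by the raw
``width*height`` uint8 pixels. The experiment-metadata manager creates one
output folder per export and hands the writer vessels their paths, so
recording only starts after an export established where data belongs.
"""

from __future__ import annotations

import datetime as _dt
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np

from ..errors import PreconditionError
from .pipeline import TailTrackResult
from .synthetic import SyntheticFrame

FRAME_MAGIC = b"SFRM"
_HEADER = struct.Struct("<4sIII")  # magic, width, height, frame_index


class TextRecordWriter:
    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh = open(self.path, "a", encoding="utf-8")
        self.lines_written = 0

    def write_result(self, result: TailTrackResult) -> None:
        angles = "\t".join(f"{a:.6f}" for a in result.segment_angles)
        self._fh.write(f"{result.frame_index}\t{angles}\n")
        self._fh.flush()
        self.lines_written += 1

    def close(self) -> None:
        self._fh.close()


class BinaryFrameWriter:
    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh = open(self.path, "ab")
        self.frames_written = 0

    def write_frame(self, frame: SyntheticFrame) -> None:
        self._fh.write(_HEADER.pack(FRAME_MAGIC, frame.width, frame.height,
                                    frame.frame_index))
        self._fh.write(frame.pixels.tobytes())
        self._fh.flush()
        self.frames_written += 1

    def close(self) -> None:
        self._fh.close()


def read_text_records(path: str | Path) -> list[tuple[int, tuple[float, ...]]]:
    records = []
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        records.append((int(parts[0]), tuple(float(p) for p in parts[1:])))
    return records


def read_binary_frames(path: str | Path) -> list[tuple[int, np.ndarray]]:
    """Parse the raw stream back into (frame_index, pixels) pairs."""
    blob = Path(path).read_bytes()
    frames = []
    pos = 0
    while pos + _HEADER.size <= len(blob):
        magic, width, height, index = _HEADER.unpack_from(blob, pos)
        if magic != FRAME_MAGIC:
            raise ValueError(f"bad frame magic at byte {pos}")
        pos += _HEADER.size
        pixels = np.frombuffer(blob, dtype=np.uint8, count=width * height,
                               offset=pos).reshape(height, width)
        pos += width * height
        frames.append((index, pixels))
    return frames


@dataclass(frozen=True)
class ExportPaths:
    folder: Path
    metadata_file: Path
    text_path: Path
    binary_path: Path


class ExperimentMetadataManager:
    """Collects experiment information and establishes the recording paths.

    ``export`` creates exactly one new output folder (experiment name plus a
    timestamp, suffixed if it collides), writes the human-readable metadata
    file, and records the text/binary paths the writer vessels will open on
    their next reload.
    """

    def __init__(self, base_dir: str | Path):
        self.base_dir = Path(base_dir)
        self.info: dict[str, Any] = {}
        self.current: Optional[ExportPaths] = None

    def set_info(self, **info: Any) -> None:
        self.info.update(info)

    def export(self, acquisition_parameters: dict[str, Any] | None = None) -> ExportPaths:
        name = str(self.info.get("experiment_name", "experiment"))
        stamp = _dt.datetime.now().strftime("%Y%m%d-%H%M%S")
        folder = self.base_dir / f"{name}_{stamp}"
        suffix = 0
        while folder.exists():
            suffix += 1
            folder = self.base_dir / f"{name}_{stamp}_{suffix}"
        folder.mkdir(parents=True)
        paths = ExportPaths(folder=folder,
                            metadata_file=folder / "metadata.txt",
                            text_path=folder / "tracking.txt",
                            binary_path=folder / "frames.bin")
        lines = [f"# experiment metadata, exported {_dt.datetime.now().isoformat()}"]
        for key in sorted(self.info):
            lines.append(f"{key} = {self.info[key]}")
        for key in sorted(acquisition_parameters or {}):
            lines.append(f"{key} = {(acquisition_parameters or {})[key]}")
        paths.metadata_file.write_text("\n".join(lines) + "\n")
        self.current = paths
        return paths

    @property
    def text_path(self) -> Path:
        if self.current is None:
            raise PreconditionError("no export performed yet: recording paths unset")
        return self.current.text_path

    @property
    def binary_path(self) -> Path:
        if self.current is None:
            raise PreconditionError("no export performed yet: recording paths unset")
        return self.current.binary_path
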