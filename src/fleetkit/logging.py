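"""Fleet logger: eight ordered severity levels, an in-memory ring, an optional
line-oriented log file, and per-vessel capture of component standard output.

Log file format is one record per line::

    ISO8601<TAB>LEVEL<TAB>origin<TAB>text
"""

from __future__ import annotations

import datetime as _dt
import io
import sys
import threading
from collections import deque
from contextlib import contextmanager
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterator


class LogLevel(IntEnum):
    """Eight totally ordered importance levels."""

    TRACE = 0
    DEBUG = 1
    INFO = 2
    NOTICE = 3
    WARNING = 4
    ERROR = 5
    CRITICAL = 6
    FATAL = 7


@dataclass(frozen=True)
class LogRecord:
    timestamp: _dt.datetime
    origin: str
    level: LogLevel
    text: str

    def to_line(self) -> str:
        return f"{self.timestamp.isoformat()}\t{self.level.name}\t{self.origin}\t{self.text}"


class FleetLogger:
    """Thread-safe logger shared by a fleet and all of its vessels.

    Records are kept in a bounded in-memory ring (for inspection and the
    status tooling) and, when a file path is configured, appended to a
    plain-text log file.
    """

    def __init__(self, ring_size: int = 10_000, file_path: str | Path | None = None):
        self._ring: deque[LogRecord] = deque(maxlen=ring_size)
        self._lock = threading.Lock()
        self._file = None
        if file_path is not None:
            self.open_file(file_path)

    def open_file(self, file_path: str | Path) -> None:
        path = Path(file_path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with self._lock:
            if self._file is not None:
                self._file.close()
            self._file = open(path, "a", encoding="utf-8")

    def log(self, origin: str, text: str, level: LogLevel = LogLevel.INFO) -> LogRecord:
        record = LogRecord(_dt.datetime.now(), origin, LogLevel(level), text)
        with self._lock:
            self._ring.append(record)
            if self._file is not None:
                self._file.write(record.to_line() + "\n")
        return record

    def records(self, min_level: LogLevel = LogLevel.TRACE) -> list[LogRecord]:
        with self._lock:
            return [r for r in self._ring if r.level >= min_level]

    def flush(self) -> None:
        with self._lock:
            if self._file is not None:
                self._file.flush()

    def close(self) -> None:
        with self._lock:
            if self._file is not None:
                self._file.close()
                self._file = None


class _StdoutRouter(io.TextIOBase):
    """Routes writes made while a capture scope is active to a fleet logger,
    attributed to the vessel owning the scope; all other writes pass through
    to the interpreter's previous stdout."""

    def __init__(self, underlying):
        self._underlying = underlying
        self._local = threading.local()

    # -- capture scope management (thread-local stack) -------------------
    def _stack(self):
        if not hasattr(self._local, "stack"):
            self._local.stack = []
        return self._local.stack

    def push(self, origin: str, logger: FleetLogger) -> None:
        self._stack().append((origin, logger, []))

    def pop(self) -> None:
        origin, logger, buf = self._stack().pop()
        if buf:
            text = "".join(buf)
            for line in text.splitlines():
                if line:
                    logger.log(origin, line, LogLevel.INFO)

    # -- file-object protocol --------------------------------------------
    def write(self, s: str) -> int:
        stack = self._stack()
        if stack:
            origin, logger, buf = stack[-1]
            buf.append(s)
            while True:
                joined = "".join(buf)
                if "\n" not in joined:
                    break
                line, _, rest = joined.partition("\n")
                buf.clear()
                if rest:
                    buf.append(rest)
                if line:
                    logger.log(origin, line, LogLevel.INFO)
            return len(s)
        return self._underlying.write(s)

    def flush(self) -> None:  # pragma: no cover - passthrough
        self._underlying.flush()

    @property
    def underlying(self):
        return self._underlying


_router_lock = threading.Lock()
_router: _StdoutRouter | None = None
_router_refs = 0


@contextmanager
def capture_stdout(origin: str, logger: FleetLogger) -> Iterator[None]:
    """Context manager rerouting ``sys.stdout`` writes on the current thread
    to ``logger``, attributed to ``origin``.

    Installation of the router is reference counted so nested and concurrent
    captures share one stdout swap; writes from threads without an active
    capture pass through unchanged.
    """
    global _router, _router_refs
    with _router_lock:
        if _router_refs == 0:
            _router = _StdoutRouter(sys.stdout)
            sys.stdout = _router
        _router_refs += 1
        router = _router
    router.push(origin, logger)
    try:
        yield
    finally:
        router.pop()
        with _router_lock:
            _router_refs -= 1
            if _router_refs == 0:
                if sys.stdout is _router:
                    sys.stdout = _router.underlying
                _router = None
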