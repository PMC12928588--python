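"""The vessel: a fault-isolating wrapper around one system component.

A vessel owns the component's build/teardown logic (builder, optional
initializer and invalidator), its lifecycle state (OFFLINE / LOADING /
ONLINE), a user-controlled activity flag that gates data traffic, a bounded
FIFO inbox of incoming messages, and the data operations (sources,
transformers, sinks) attached to it.

The component handle is reachable only while the vessel is ONLINE, and all
external code touching the component goes through :meth:`Vessel.execute_call`,
which converts any raised exception into an invalidation of the vessel rather
than letting it escape to the caller.
"""

from __future__ import annotations

import threading
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Any, Callable, Iterable, Optional

from .errors import ErrorRecord, SpecificationError
from .logging import LogLevel, capture_stdout
from .messages import Message

if TYPE_CHECKING:  # pragma: no cover
    from .data import DataOperation
    from .fleet import Fleet


class VesselState(Enum):
    OFFLINE = "offline"
    LOADING = "loading"
    ONLINE = "online"


class InvalidationCause(Enum):
    NONE = "none"
    LOCAL_FAILURE = "local_failure"
    USER = "user"
    CASCADE = "cascade"
    SHUTDOWN = "shutdown"


class DataHandlingStrategy(Enum):
    QUEUED = "queued"
    DIRECT = "direct"


@dataclass
class ComponentSpec:
    """Recipe for freighting one component into a vessel.

    ``builder`` receives the dependency component handles positionally in
    declaration order and returns the component instance. ``initializer`` and
    ``invalidator`` receive the dependency handles followed by the component.
    """

    name: str
    builder: Callable[..., Any]
    initializer: Optional[Callable[..., None]] = None
    invalidator: Optional[Callable[..., None]] = None
    dependencies: list["Vessel"] = field(default_factory=list)
    queue_capacity: int = 64
    data_handling_strategy: DataHandlingStrategy = DataHandlingStrategy.QUEUED
    source_rate: Optional[float] = None
    capture_logs: bool = True

    def validate(self) -> None:
        if self.queue_capacity < 1:
            raise SpecificationError(f"vessel {self.name!r}: queue_capacity must be >= 1")
        names = [d.name for d in self.dependencies]
        if len(set(names)) != len(names):
            raise SpecificationError(f"vessel {self.name!r}: duplicate dependencies")
        if self.name in names:
            raise SpecificationError(f"vessel {self.name!r} cannot depend on itself")


@dataclass(frozen=True)
class CallResult:
    """Outcome of a guarded call into component code: a value or an error."""

    ok: bool
    value: Any = None
    error: Optional[ErrorRecord] = None


@dataclass(frozen=True)
class ReloadReport:
    success: bool
    error: Optional[ErrorRecord] = None


class Vessel:
    """Lifecycle wrapper around one component; create via :meth:`Fleet.freight`."""

    def __init__(self, spec: ComponentSpec, fleet: "Fleet"):
        spec.validate()
        self.spec = spec
        self.fleet = fleet
        self.state = VesselState.OFFLINE
        self.is_active = True
        self.last_error: Optional[ErrorRecord] = None
        self.invalidation_cause = InvalidationCause.NONE
        self.component: Any = None
        self.inbox: deque[Message] = deque()
        self.operations: list["DataOperation"] = []
        self.dropped_count = 0
        self.builder_calls = 0
        self.invalidator_calls = 0
        # _lifecycle guards state transitions; _process enforces one
        # in-flight message per vessel; _inbox guards the queue itself.
        self._lifecycle = threading.RLock()
        self._process = threading.RLock()
        self._inbox_lock = threading.Lock()
        self.inbox_not_empty = threading.Condition(self._inbox_lock)

    # ------------------------------------------------------------------
    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def is_online(self) -> bool:
        return self.state is VesselState.ONLINE

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Vessel {self.name} {self.state.value} active={self.is_active}>"

    # -- logging helpers -------------------------------------------------
    def log(self, text: str, level: LogLevel = LogLevel.INFO) -> None:
        self.fleet.logger.log(self.name, text, level)

    def _record_error(self, phase: str, exc: BaseException) -> ErrorRecord:
        record = ErrorRecord(origin=self.name, phase=phase,
                             message=f"{type(exc).__name__}: {exc}", exception=exc)
        self.last_error = record
        self.log(f"error in {phase}: {record.message}", LogLevel.ERROR)
        return record

    def _set_state(self, state: VesselState) -> None:
        if state is not self.state:
            self.state = state
            self.fleet.logger.log(self.name, f"state -> {state.value}", LogLevel.NOTICE)
            self.fleet._note_state_change(self, state)

    # -- lifecycle -------------------------------------------------------
    def reload(self) -> ReloadReport:
        """Build (and initialize) the component, moving OFFLINE -> LOADING ->
        ONLINE. An already-ONLINE vessel is first invalidated (USER) and
        rebuilt. Any error leaves the vessel OFFLINE and is reported, never
        raised."""
        with self._lifecycle:
            offline_dep = next((d for d in self.spec.dependencies if not d.is_online), None)
            if offline_dep is not None:
                record = ErrorRecord(
                    origin=self.name, phase="reload",
                    message=f"dependency {offline_dep.name!r} is not online")
                self.log(f"reload refused: {record.message}", LogLevel.WARNING)
                return ReloadReport(False, record)
            if self.is_online:
                self.invalidate(InvalidationCause.USER, _propagate=False)
            self._set_state(VesselState.LOADING)
            handles = [d.component for d in self.spec.dependencies]
            try:
                with self._maybe_capture():
                    self.builder_calls += 1
                    component = self.spec.builder(*handles)
                if component is None:
                    raise RuntimeError("builder returned no component")
            except BaseException as exc:  # noqa: BLE001 - contained by design
                record = self._record_error("builder", exc)
                self.component = None
                self._set_state(VesselState.OFFLINE)
                self.invalidation_cause = InvalidationCause.LOCAL_FAILURE
                return ReloadReport(False, record)
            self.component = component
            if self.spec.initializer is not None:
                try:
                    with self._maybe_capture():
                        self.spec.initializer(*handles, component)
                except BaseException as exc:  # noqa: BLE001
                    record = self._record_error("initializer", exc)
                    # the component exists, so teardown is owed before
                    # declaring the build failed
                    self._run_invalidator(handles)
                    self.component = None
                    self._set_state(VesselState.OFFLINE)
                    self.invalidation_cause = InvalidationCause.LOCAL_FAILURE
                    return ReloadReport(False, record)
            self.invalidation_cause = InvalidationCause.NONE
            self._set_state(VesselState.ONLINE)
            return ReloadReport(True)

    def _run_invalidator(self, handles: Iterable[Any]) -> None:
        if self.spec.invalidator is None:
            return
        try:
            with self._maybe_capture():
                self.invalidator_calls += 1
                self.spec.invalidator(*handles, self.component)
        except BaseException as exc:  # noqa: BLE001
            self._record_error("invalidator", exc)

    def invalidate(self, cause: InvalidationCause = InvalidationCause.USER,
                   _propagate: bool = True) -> None:
        """Tear down the component and go OFFLINE; a no-op on vessels that
        are not ONLINE. A downstream-invalidation signal is handed to the
        fleet's link graph unless suppressed (internal rebuilds, cascades).

        Messages already queued are retained for processing after a restore.
        """
        with self._lifecycle:
            if not self.is_online:
                return
            handles = [d.component for d in self.spec.dependencies]
            self._run_invalidator(handles)
            self.component = None
            self.invalidation_cause = cause
            self._set_state(VesselState.OFFLINE)
        if _propagate:
            self.fleet._signal_invalidated(self)

    def execute_call(self, action: Callable[[Any], Any]) -> CallResult:
        """Run ``action(component)`` under the framework's guard.

        OFFLINE vessels return a not-available error without invoking the
        action. A raising action invalidates the vessel (LOCAL_FAILURE) and
        the error is returned, never re-raised.
        """
        with self._lifecycle:
            if not self.is_online:
                return CallResult(False, error=ErrorRecord(
                    origin=self.name, phase="execute_call",
                    message="vessel is not available (offline)"))
            component = self.component
        try:
            with self._maybe_capture():
                value = action(component)
        except BaseException as exc:  # noqa: BLE001
            record = self._record_error("execute_call", exc)
            self.invalidate(InvalidationCause.LOCAL_FAILURE)
            return CallResult(False, error=record)
        return CallResult(True, value=value)

    def _maybe_capture(self):
        if self.spec.capture_logs:
            return capture_stdout(self.name, self.fleet.logger)
        import contextlib

        return contextlib.nullcontext()

    # -- activity --------------------------------------------------------
    def set_active(self, flag: bool) -> None:
        """Toggle participation in the data graph. Inactive vessels are not
        polled, do not receive messages, and do not process their queue;
        already-queued messages stay queued. Independent of lifecycle state."""
        self.is_active = bool(flag)
        with self.inbox_not_empty:
            self.inbox_not_empty.notify_all()

    # -- inbox -----------------------------------------------------------
    def queue_occupancy(self) -> float:
        with self._inbox_lock:
            return len(self.inbox) / self.spec.queue_capacity

    def enqueue(self, message: Message) -> bool:
        """Non-blocking append; returns False (and counts a drop) when full."""
        with self.inbox_not_empty:
            if len(self.inbox) >= self.spec.queue_capacity:
                self.dropped_count += 1
                self.fleet.logger.log(
                    self.name, f"inbox full, dropping message {message.metadata.message_id}",
                    LogLevel.WARNING)
                return False
            self.inbox.append(message)
            self.inbox_not_empty.notify()
            return True
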