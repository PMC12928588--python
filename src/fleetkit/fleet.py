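"""Fleet assembly, launch/shutdown sequence, and status reporting.

A fleet is the unit an application runs: the registry of vessels, the two
graphs built over them (the link graph of hard dependencies and the data
graph of typed message routes), the shared services pool, the settings
document, the logger, and the fleet-global message-id counter.

Launch order: settings are loaded at construction; ``launch()`` freezes the
vessel set, builds and validates the link graph (a dependency cycle aborts),
builds the data graph, starts vessels rank by rank, and finally starts the
inbox workers and source pollers when a threaded runtime is requested.
Individual vessel failures never abort a launch.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Optional, Sequence

from . import data as _data
from . import links as _links
from .errors import RegistrationError
from .logging import FleetLogger, LogLevel
from .services import CommandRegistry, SettingsDocument, ServicePool, collect_metadata
from .vessel import (CallResult, ComponentSpec, DataHandlingStrategy,
                     InvalidationCause, Vessel, VesselState)

DEFAULT_SETTINGS_FILENAME = "SARDINE.xml"


@dataclass(frozen=True)
class StatusRow:
    name: str
    state: str
    active: bool
    occupancy: float  # fraction of inbox capacity in use
    dropped: int


class Fleet:
    """A set of vessels plus their graphs and shared services."""

    def __init__(self, name: str = "fleet",
                 settings_path: str | Path | None = DEFAULT_SETTINGS_FILENAME,
                 log_file: str | Path | None = None):
        self.name = name
        self.settings = SettingsDocument.load(settings_path)
        self.logger = FleetLogger()
        user_data = self.settings.fetch_setting("Application", "UserDataPath")
        if log_file is not None:
            self.logger.open_file(log_file)
        elif user_data:
            self.logger.open_file(Path(user_data) / f"{name}.log")
        self.vessels: dict[str, Vessel] = {}
        self.services = ServicePool()
        self.commands = CommandRegistry()
        self.widenings: set[tuple[type, type]] = set()
        self.link_graph: Optional[_links.LinkGraph] = None
        self.data_graph: Optional[_data.DataGraph] = None
        self._data_graph_stale = True
        self._id_lock = threading.Lock()
        self._next_id = 0
        self._pollers: dict[str, _data.Poller] = {}
        self._workers: dict[str, _data.Worker] = {}
        self._running = False
        self.state_changes: list[tuple[str, VesselState]] = []
        self._state_log_lock = threading.Lock()

    # ------------------------------------------------------------------
    # assembly
    def freight(self, name: str, builder: Callable[..., Any], *,
                initializer: Optional[Callable[..., None]] = None,
                invalidator: Optional[Callable[..., None]] = None,
                dependencies: Sequence[Vessel] = (),
                queue_capacity: int = 64,
                data_handling_strategy: DataHandlingStrategy = DataHandlingStrategy.QUEUED,
                source_rate: Optional[float] = None,
                capture_logs: bool = True) -> Vessel:
        """Wrap a component recipe into a new OFFLINE, active vessel."""
        spec = ComponentSpec(name=name, builder=builder, initializer=initializer,
                             invalidator=invalidator, dependencies=list(dependencies),
                             queue_capacity=queue_capacity,
                             data_handling_strategy=data_handling_strategy,
                             source_rate=source_rate, capture_logs=capture_logs)
        return self.add_vessel(spec)

    def add_vessel(self, spec: ComponentSpec) -> Vessel:
        if spec.name in self.vessels:
            raise RegistrationError(f"vessel name {spec.name!r} already registered")
        for dep in spec.dependencies:
            if dep.name not in self.vessels or self.vessels[dep.name] is not dep:
                raise RegistrationError(
                    f"vessel {spec.name!r}: dependency {dep.name!r} is not "
                    f"registered with this fleet")
        vessel = Vessel(spec, self)
        self.vessels[spec.name] = vessel
        self._data_graph_stale = True
        self.link_graph = None
        return vessel

    def register_widening(self, produced: type, accepted: type) -> None:
        """Declare that payloads of type ``produced`` may be routed to
        consumers accepting ``accepted``."""
        self.widenings.add((produced, accepted))
        self._mark_data_graph_stale()

    # ------------------------------------------------------------------
    # internals used by vessels / data plane
    def next_message_id(self) -> int:
        with self._id_lock:
            mid = self._next_id
            self._next_id += 1
            return mid

    def _mark_data_graph_stale(self) -> None:
        self._data_graph_stale = True

    def _note_state_change(self, vessel: Vessel, state: VesselState) -> None:
        with self._state_log_lock:
            self.state_changes.append((vessel.name, state))

    def _signal_invalidated(self, vessel: Vessel) -> None:
        """Downstream-invalidation signal: take the vessel's link-graph
        descendants down with it (cause CASCADE)."""
        if self.link_graph is None or vessel not in self.link_graph.graph:
            return
        for dependent in sorted(self.link_graph.descendants(vessel),
                                key=lambda v: (self.link_graph.ranks[v], v.name)):
            if dependent.is_online:
                dependent.invalidate(InvalidationCause.CASCADE, _propagate=False)

    def _reschedule_poller(self, vessel: Vessel) -> None:
        poller = self._pollers.pop(vessel.name, None)
        if poller is not None:
            poller.stop()
            poller.join(timeout=2.0)
        if self._running and vessel.spec.source_rate:
            self._start_poller(vessel)

    def _start_poller(self, vessel: Vessel) -> None:
        poller = _data.Poller(vessel, vessel.spec.source_rate)
        self._pollers[vessel.name] = poller
        poller.start()

    # ------------------------------------------------------------------
    # graphs
    def build_graphs(self) -> None:
        self.link_graph = _links.build_link_graph(self.vessels.values())
        self.rebuild_data_graph()

    def rebuild_data_graph(self) -> _data.DataGraph:
        self.data_graph = _data.build_data_graph(self)
        self._data_graph_stale = False
        return self.data_graph

    # ------------------------------------------------------------------
    # lifecycle
    def launch(self, threaded: bool = True) -> _links.StartReport:
        """Build both graphs, start every vessel in dependency order, and
        (when threaded) start inbox workers and source pollers. A dependency
        cycle aborts the launch; individual vessel failures do not."""
        self.logger.log(self.name, "launching fleet", LogLevel.NOTICE)
        self.build_graphs()
        report = _links.start_in_order(self.link_graph)
        if threaded:
            self.start_runtime()
        return report

    def start_runtime(self) -> None:
        """Start worker threads for QUEUED vessels and pollers for vessels
        with a source rate."""
        if self._running:
            return
        self._running = True
        for vessel in self.vessels.values():
            if vessel.spec.data_handling_strategy is DataHandlingStrategy.QUEUED:
                worker = _data.Worker(vessel)
                self._workers[vessel.name] = worker
                worker.start()
        for vessel in self.vessels.values():
            if vessel.spec.source_rate:
                self._start_poller(vessel)

    def stop_runtime(self) -> None:
        for poller in self._pollers.values():
            poller.stop()
        for poller in self._pollers.values():
            poller.join(timeout=2.0)
        self._pollers.clear()
        for worker in self._workers.values():
            worker.stop()
        for worker in self._workers.values():
            worker.join(timeout=2.0)
        self._workers.clear()
        self._running = False

    def shutdown(self) -> None:
        """Stop pollers and workers, invalidate every vessel dependents-first
        (cause SHUTDOWN), and flush the log. Idempotent."""
        self.stop_runtime()
        order = (self.link_graph.shutdown_order() if self.link_graph is not None
                 else list(self.vessels.values()))
        for vessel in order:
            vessel.invalidate(InvalidationCause.SHUTDOWN, _propagate=False)
        self.logger.log(self.name, "fleet shut down", LogLevel.NOTICE)
        self.logger.flush()

    # ------------------------------------------------------------------
    # data-plane conveniences
    def pump(self, max_rounds: int = 1_000_000) -> int:
        """Synchronously drain every inbox (for unthreaded, deterministic
        runs). Returns the number of messages processed."""
        processed = 0
        for _ in range(max_rounds):
            progressed = False
            for vessel in self.vessels.values():
                if _data.process_inbox_step(vessel) is not None:
                    processed += 1
                    progressed = True
            if not progressed:
                break
        return processed

    # ------------------------------------------------------------------
    # reporting
    def status_snapshot(self) -> list[StatusRow]:
        rows = []
        for vessel in sorted(self.vessels.values(), key=lambda v: v.name):
            rows.append(StatusRow(
                name=vessel.name, state=vessel.state.value, active=vessel.is_active,
                occupancy=vessel.queue_occupancy(), dropped=vessel.dropped_count))
        return rows

    def status_table(self) -> str:
        rows = self.status_snapshot()
        widths = max((len(r.name) for r in rows), default=4)
        lines = [f"{'vessel':<{widths}}  state    active  queue  dropped"]
        for r in rows:
            lines.append(f"{r.name:<{widths}}  {r.state:<7}  {str(r.active):<6}  "
                         f"{r.occupancy:>4.0%}  {r.dropped:>7}")
        return "\n".join(lines)

    def to_dot(self) -> str:
        return _links.to_dot(self)

    # ------------------------------------------------------------------
    # services / commands passthroughs
    def get_service(self, service_type: type) -> Any:
        return self.services.get(service_type)

    def collect_metadata(self, spec: dict[str, Sequence[str]]):
        return collect_metadata(self, spec)

    def register_command(self, vessel: Vessel, name: str, action: Callable) -> None:
        self.commands.register(vessel, name, action)

    def invoke_command(self, name: str, *args: Any, **kwargs: Any) -> CallResult:
        return self.commands.invoke(name, *args, **kwargs)
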