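"""Typed asynchronous messaging between vessels.

Data operations come in three kinds: sources produce new payloads when a
vessel's *generate data* step runs (polled at a configurable rate or invoked
manually), transformers turn an incoming payload into a new one, and sinks
consume payloads. Routes between operations are computed from declared
payload types (exact match plus explicitly registered widenings) into a
multidigraph; messages are multicast along those routes into per-vessel
bounded FIFO inboxes, or handed over synchronously for vessels that opted
into DIRECT handling.

The inbox queue decouples producers from consumers: a slow or stalled
consumer fills its own queue (overflow drops the newest message, with a
logged warning and a per-vessel drop counter) and never delays the producer.
"""

from __future__ import annotations

import threading
import time
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Any, Callable, Optional

import networkx as nx

from .errors import ConfigurationError
from .messages import Message, stamp_source
from .vessel import DataHandlingStrategy, Vessel

if TYPE_CHECKING:  # pragma: no cover
    from .fleet import Fleet


class OperationKind(Enum):
    SOURCE = "source"
    TRANSFORMER = "transformer"
    SINK = "sink"


@dataclass(eq=False)
class DataOperation:
    """One attached data operation.

    Body contracts (component = the owner's component handle):

    * SOURCE: ``body(component) -> (payload | None, has_more)``
    * TRANSFORMER: ``body(component, payload, metadata) -> payload | None``
    * SINK: ``body(component, payload, metadata) -> None``
    """

    kind: OperationKind
    owner: Vessel
    body: Callable[..., Any]
    input_type: Optional[type] = None
    output_type: Optional[type] = None
    source_filter: Optional[frozenset[str]] = None
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = f"{self.owner.name}.{getattr(self.body, '__name__', self.kind.value)}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.kind.value} {self.name}>"


@dataclass
class DataGraph:
    """Multidigraph of operation-to-operation routes, rebuilt on demand."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    def routes_from(self, op: DataOperation) -> list[DataOperation]:
        if op not in self.graph:
            return []
        return [v for _, v in self.graph.out_edges(op)]

    @property
    def routes(self) -> list[tuple[DataOperation, DataOperation]]:
        return list(self.graph.edges())


# ----------------------------------------------------------------------
# attachment


def _attach(vessel: Vessel, op: DataOperation) -> DataOperation:
    vessel.operations.append(op)
    vessel.fleet._mark_data_graph_stale()
    return op


def add_source(vessel: Vessel, body: Callable, output_type: type,
               name: str = "") -> DataOperation:
    return _attach(vessel, DataOperation(OperationKind.SOURCE, vessel, body,
                                         output_type=output_type, name=name))


def add_transformer(vessel: Vessel, body: Callable, input_type: type,
                    output_type: type, source_filter=None, name: str = "") -> DataOperation:
    return _attach(vessel, DataOperation(
        OperationKind.TRANSFORMER, vessel, body, input_type=input_type,
        output_type=output_type,
        source_filter=frozenset(source_filter) if source_filter else None, name=name))


def add_sink(vessel: Vessel, body: Callable, input_type: type,
             source_filter=None, name: str = "") -> DataOperation:
    return _attach(vessel, DataOperation(
        OperationKind.SINK, vessel, body, input_type=input_type,
        source_filter=frozenset(source_filter) if source_filter else None, name=name))


# ----------------------------------------------------------------------
# routing


def types_compatible(produced: Optional[type], accepted: Optional[type],
                     widenings: set[tuple[type, type]]) -> bool:
    """Exact type match, or an explicitly registered widening. No implicit
    structural or subclass acceptance: routing stays predictable."""
    if produced is None or accepted is None:
        return False
    return produced is accepted or (produced, accepted) in widenings


def build_data_graph(fleet: "Fleet") -> DataGraph:
    """Connect every producing operation to every operation that can accept
    its output. Same-vessel self-routing is excluded (a vessel's own output
    is not fed back to itself); vessels that are offline or inactive are kept
    in the graph and skipped at dispatch time instead."""
    g = nx.MultiDiGraph()
    ops = [op for v in fleet.vessels.values() for op in v.operations]
    g.add_nodes_from(ops)
    producers = [op for op in ops if op.output_type is not None]
    consumers = [op for op in ops if op.input_type is not None]
    for p in producers:
        for c in consumers:
            if p is c or p.owner is c.owner:
                continue
            if not types_compatible(p.output_type, c.input_type, fleet.widenings):
                continue
            # structural source filtering: a route straight from a source
            # whose vessel the consumer excludes can never carry a wanted
            # message, so it is pruned at build time
            if (c.source_filter is not None and p.kind is OperationKind.SOURCE
                    and p.owner.name not in c.source_filter):
                continue
            g.add_edge(p, c)
    return DataGraph(g)


# ----------------------------------------------------------------------
# emission and delivery


def generate_data(vessel: Vessel) -> int:
    """Run every SOURCE on the vessel, emitting and dispatching one message
    per produced payload. A source reporting ``has_more`` is re-invoked up to
    ``queue_capacity`` times per call (the drain cap). Returns the number of
    messages emitted. Offline or inactive vessels emit nothing."""
    if not vessel.is_online or not vessel.is_active:
        return 0
    fleet = vessel.fleet
    emitted = 0
    for op in [o for o in vessel.operations if o.kind is OperationKind.SOURCE]:
        drain_cap = vessel.spec.queue_capacity
        for _ in range(drain_cap):
            result = vessel.execute_call(lambda comp: op.body(comp))
            if not result.ok:
                return emitted
            payload, has_more = result.value
            if payload is not None:
                message = stamp_source(payload, op.output_type, vessel.name,
                                       vessel.spec.source_rate, fleet.next_message_id())
                dispatch(fleet, message, op)
                emitted += 1
            if not has_more:
                break
    return emitted


def dispatch(fleet: "Fleet", message: Message, producing_op: DataOperation) -> int:
    """Multicast a message along the data-graph routes leaving the producing
    operation. Consumers whose vessel is offline or inactive are skipped, as
    are consumers whose source filter excludes the message's original source.
    Each consuming vessel receives the message once (its matching operations
    all see it during processing): QUEUED vessels get a non-blocking enqueue
    (overflow drops and counts), DIRECT vessels process synchronously in the
    caller's flow. Returns the number of successful deliveries."""
    graph = fleet.data_graph
    delivered = 0
    seen_owners: set[Vessel] = set()
    for consumer in graph.routes_from(producing_op):
        owner = consumer.owner
        if owner in seen_owners:
            continue
        if not owner.is_online or not owner.is_active:
            continue
        if (consumer.source_filter is not None
                and message.metadata.original_source not in consumer.source_filter):
            continue
        seen_owners.add(owner)
        if owner.spec.data_handling_strategy is DataHandlingStrategy.DIRECT:
            with owner._process:  # per-vessel sequentiality holds in DIRECT mode too
                _process_message(owner, message)
            delivered += 1
        else:
            if owner.enqueue(message):
                delivered += 1
    return delivered


def process_inbox_step(vessel: Vessel) -> Optional[Message]:
    """Pop and process the oldest queued message (FIFO). At most one message
    is in flight per vessel at a time; distinct vessels process
    independently. Returns the processed message, or None if the queue was
    empty or the vessel is not online/active."""
    with vessel._process:
        if not vessel.is_online or not vessel.is_active:
            return None
        with vessel._inbox_lock:
            if not vessel.inbox:
                return None
            message = vessel.inbox.popleft()
        _process_message(vessel, message)
        return message


def _process_message(vessel: Vessel, message: Message) -> None:
    """Feed one message to every matching transformer/sink on the vessel.
    Transformer outputs are emitted as new messages (new id, sender updated,
    original source preserved). A raising body invalidates the vessel via
    the execute-call guard; the in-flight message is consumed but the rest
    of the queue is retained for a later restore."""
    fleet = vessel.fleet
    for op in list(vessel.operations):
        if op.kind is OperationKind.SOURCE:
            continue
        if not types_compatible(message.metadata.payload_type, op.input_type, fleet.widenings):
            continue
        if (op.source_filter is not None
                and message.metadata.original_source not in op.source_filter):
            continue
        result = vessel.execute_call(
            lambda comp: op.body(comp, message.payload, message.metadata))
        if not result.ok:
            return
        if op.kind is OperationKind.TRANSFORMER and result.value is not None:
            out = Message(result.value,
                          message.metadata.rehop(vessel.name, op.output_type,
                                                 fleet.next_message_id()))
            dispatch(fleet, out, op)


# ----------------------------------------------------------------------
# polling


def set_source_rate(vessel: Vessel, hz: Optional[float]) -> None:
    """Set (or clear) the polling rate for the vessel's sources. The rate is
    stamped into emitted metadata; the fleet's scheduler polls generate_data
    at this rate while running."""
    if hz is not None and hz <= 0:
        raise ConfigurationError(f"source rate must be positive, got {hz}")
    vessel.spec.source_rate = hz
    vessel.fleet._reschedule_poller(vessel)


class Poller(threading.Thread):
    """Fixed-rate scheduler thread invoking generate_data on one vessel.

    Scheduling is absolute (next deadline = start + k/rate) so occasional
    slow emissions do not accumulate drift.
    """

    def __init__(self, vessel: Vessel, hz: float):
        super().__init__(name=f"poller-{vessel.name}", daemon=True)
        self.vessel = vessel
        self.period = 1.0 / hz
        self._stop_event = threading.Event()

    def stop(self) -> None:
        self._stop_event.set()

    def run(self) -> None:  # pragma: no cover - timing loop
        start = time.monotonic()
        k = 1
        while not self._stop_event.is_set():
            deadline = start + k * self.period
            delay = deadline - time.monotonic()
            if delay > 0:
                if self._stop_event.wait(delay):
                    break
            generate_data(self.vessel)
            k += 1


class Worker(threading.Thread):
    """Inbox-consuming thread for one QUEUED vessel."""

    def __init__(self, vessel: Vessel):
        super().__init__(name=f"worker-{vessel.name}", daemon=True)
        self.vessel = vessel
        self._stop_event = threading.Event()

    def stop(self) -> None:
        self._stop_event.set()
        with self.vessel.inbox_not_empty:
            self.vessel.inbox_not_empty.notify_all()

    def run(self) -> None:
        v = self.vessel
        while not self._stop_event.is_set():
            with v.inbox_not_empty:
                while ((not v.inbox or not v.is_active or not v.is_online)
                       and not self._stop_event.is_set()):
                    v.inbox_not_empty.wait(timeout=0.1)
                if self._stop_event.is_set():
                    break
            process_inbox_step(v)
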