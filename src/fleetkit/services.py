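"""Fleet-scoped support services.

Services are lazily constructed singletons kept in a pool attached to the
fleet: the first request for a service type constructs it (no-argument
constructor), later requests return the same instance, and access can be
serialized so two callers never interleave inside one service. The built-in
support systems live here as well: the XML settings document, the metadata
collector, and the text-command registry.
"""

from __future__ import annotations

import datetime as _dt
import threading
import xml.etree.ElementTree as ET
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Any, Callable, Iterator, Optional, Sequence

from .errors import RegistrationError, SettingsError
from .vessel import CallResult, ErrorRecord, Vessel

if TYPE_CHECKING:  # pragma: no cover
    from .fleet import Fleet


class ServicePool:
    """At most one instance per service type, created on first request."""

    def __init__(self):
        self._instances: dict[type, Any] = {}
        self._access_locks: dict[type, threading.RLock] = {}
        self._meta = threading.Lock()
        self._construct_locks: dict[type, threading.Lock] = {}

    def get(self, service_type: type) -> Any:
        """Return the pooled instance, constructing it on first request.
        A failing constructor caches nothing; the next request retries."""
        with self._meta:
            if service_type in self._instances:
                return self._instances[service_type]
            lock = self._construct_locks.setdefault(service_type, threading.Lock())
        with lock:
            with self._meta:
                if service_type in self._instances:
                    return self._instances[service_type]
            instance = service_type()  # may raise: nothing is cached then
            with self._meta:
                self._instances[service_type] = instance
                self._access_locks[service_type] = threading.RLock()
            return instance

    @contextmanager
    def access(self, service_type: type) -> Iterator[Any]:
        """Yield the pooled instance under its access guard: one caller at a
        time per service."""
        instance = self.get(service_type)
        with self._meta:
            lock = self._access_locks[service_type]
        with lock:
            yield instance


# ----------------------------------------------------------------------
# settings


class SettingsDocument:
    """Read-only view of the fleet settings file (``SARDINE.xml`` dialect):
    nested named elements carrying attribute key/value pairs. A missing file
    yields an empty document; every lookup on it returns None."""

    def __init__(self, root: Optional[ET.Element] = None, path: Optional[Path] = None):
        self._root = root
        self.path = path

    @classmethod
    def load(cls, path: str | Path | None) -> "SettingsDocument":
        if path is None:
            return cls()
        path = Path(path)
        if not path.exists():
            return cls(path=path)
        try:
            tree = ET.parse(path)
        except ET.ParseError as exc:
            line, col = exc.position
            raise SettingsError(
                f"malformed settings file {path} at line {line}, column {col}: {exc}"
            ) from exc
        return cls(tree.getroot(), path)

    def fetch_setting(self, path: str | Sequence[str], name: str) -> Optional[str]:
        """Walk nested elements by name and return the attribute value, or
        None when any step is missing. Never raises on absent keys."""
        if self._root is None:
            return None
        if isinstance(path, str):
            path = [path]
        node = self._root
        for step in path:
            node = node.find(step)
            if node is None:
                return None
        return node.get(name)

    def fetch_settings(self, path: str | Sequence[str]) -> dict[str, str]:
        """All attributes of the addressed element (empty when missing)."""
        if self._root is None:
            return {}
        if isinstance(path, str):
            path = [path]
        node = self._root
        for step in path:
            node = node.find(step)
            if node is None:
                return {}
        return dict(node.attrib)


def fetch_setting(doc: SettingsDocument, path, name: str) -> Optional[str]:
    return doc.fetch_setting(path, name)


# ----------------------------------------------------------------------
# metadata collection


@dataclass(frozen=True)
class MetadataReport:
    """Point-in-time snapshot of requested component parameters."""

    values: dict[str, Any]  # vessel name -> {param: value} or "unavailable"
    timestamp: _dt.datetime = field(default_factory=_dt.datetime.now)

    def to_text(self) -> str:
        lines = [f"# metadata snapshot {self.timestamp.isoformat()}"]
        for vessel_name in sorted(self.values):
            entry = self.values[vessel_name]
            if entry == "unavailable":
                lines.append(f"{vessel_name}: unavailable")
                continue
            for key in sorted(entry):
                lines.append(f"{vessel_name}.{key} = {entry[key]!r}")
        return "\n".join(lines) + "\n"


def collect_metadata(fleet: "Fleet", spec: dict[str, Sequence[str]]) -> MetadataReport:
    """Snapshot the named readable parameters of each listed vessel. Offline
    vessels are reported unavailable; unknown parameters are recorded as
    missing rather than failing the collection."""
    values: dict[str, Any] = {}
    for vessel_name, params in spec.items():
        vessel = fleet.vessels[vessel_name]
        if not vessel.is_online:
            values[vessel_name] = "unavailable"
            continue
        snapshot: dict[str, Any] = {}
        missing = object()
        for param in params:
            # a default keeps an unknown parameter from reading as a
            # component failure (which would invalidate the vessel)
            result = vessel.execute_call(lambda comp, p=param: getattr(comp, p, missing))
            value = result.value if result.ok else missing
            snapshot[param] = "<missing>" if value is missing else value
        values[vessel_name] = snapshot
    return MetadataReport(values)


# ----------------------------------------------------------------------
# text-command registry


class CommandRegistry:
    """Associates fleet-unique text commands with actions on a vessel's
    component. Invocation goes through the execute-call guard: a failing
    action invalidates the owning vessel, never the caller."""

    def __init__(self):
        self._commands: dict[str, tuple[Vessel, Callable]] = {}
        self._lock = threading.Lock()

    def register(self, vessel: Vessel, name: str, action: Callable) -> None:
        with self._lock:
            if name in self._commands:
                raise RegistrationError(f"command {name!r} already registered")
            self._commands[name] = (vessel, action)

    def invoke(self, name: str, *args: Any, **kwargs: Any) -> CallResult:
        with self._lock:
            entry = self._commands.get(name)
        if entry is None:
            return CallResult(False, error=ErrorRecord(
                origin="commands", phase="invoke", message=f"unknown command {name!r}"))
        vessel, action = entry
        return vessel.execute_call(lambda comp: action(comp, *args, **kwargs))
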