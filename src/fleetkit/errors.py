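"""Exception hierarchy and the structured error record used across the fleet."""

from __future__ import annotations

import time
from dataclasses import dataclass, field


class FleetError(Exception):
    """Base class for all fleetkit errors."""


class SpecificationError(FleetError):
    """A component specification violates its invariants (self-dependency, bad capacity, ...)."""


class RegistrationError(FleetError):
    """A vessel or command name collides with one already registered."""


class ConfigurationError(FleetError):
    """The fleet cannot be assembled (dependency cycle, bad source rate, ...)."""


class PreconditionError(FleetError):
    """An operation was invoked while its stated precondition does not hold."""


class SettingsError(FleetError):
    """The settings file could not be parsed."""


@dataclass(frozen=True)
class ErrorRecord:
    """Structured record of an error caught by the framework.

    Every error raised inside user-supplied code (builders, initializers,
    invalidators, actions, data-operation bodies) is captured as one of
    these instead of propagating to the caller.
    """

    origin: str
    phase: str
    message: str
    exception: BaseException | None = None
    timestamp_ns: int = field(default_factory=time.monotonic_ns)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.origin}/{self.phase}] {self.message}"
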