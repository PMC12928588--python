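"""Typed messages and their provenance metadata.

Every payload travelling the data graph is wrapped in a :class:`Message`
carrying a :class:`MessageMetadata` record: the declared payload type, the
vessel that emitted this hop (``sender``), the first producer of the chain
(``original_source``, preserved across transformer hops), the polling rate of
that producer when one is configured, a fleet-global strictly increasing
message id, and a monotonic-clock timestamp in nanoseconds.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Any


@dataclass(frozen=True)
class MessageMetadata:
    payload_type: type
    sender: str
    original_source: str
    source_rate: float | None
    message_id: int
    timestamp_ns: int

    def rehop(self, sender: str, payload_type: type, message_id: int) -> "MessageMetadata":
        """Metadata for a transformer hop: sender and id are renewed,
        provenance (original source and its rate) is preserved."""
        return MessageMetadata(
            payload_type=payload_type,
            sender=sender,
            original_source=self.original_source,
            source_rate=self.source_rate,
            message_id=message_id,
            timestamp_ns=time.monotonic_ns(),
        )


@dataclass(frozen=True)
class Message:
    payload: Any
    metadata: MessageMetadata

    def __post_init__(self):
        if not isinstance(self.payload, self.metadata.payload_type):
            raise TypeError(
                f"payload of type {type(self.payload).__name__} does not match "
                f"declared type {self.metadata.payload_type.__name__}"
            )


def stamp_source(payload: Any, payload_type: type, vessel_name: str,
                 source_rate: float | None, message_id: int) -> Message:
    """Build the message for a freshly sourced payload (sender == original source)."""
    return Message(
        payload=payload,
        metadata=MessageMetadata(
            payload_type=payload_type,
            sender=vessel_name,
            original_source=vessel_name,
            source_rate=source_rate,
            message_id=message_id,
            timestamp_ns=time.monotonic_ns(),
        ),
    )
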