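"""Message data model and JSON wire codec.

Every unit of communication in the twin — a sensor reading, a transport
life-cycle event, a prediction query, a model-instantiation announcement or a
model result — is a :class:`Message`: a time-stamped, topic-addressed field
map.  Timestamps are *logical* time in hours since scenario start, so model
time is decoupled from wall-clock playback speed.

The wire format is one JSON object per message with envelope keys ``topic``,
``timestamp``, ``shipment_id``, ``kind`` and a nested ``payload`` object
(JSON-lines in dump files).  ``decode(encode(m)) == m`` for every valid
message; floats survive with full ``repr`` fidelity.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Mapping

from .errors import CodecError, SchemaError, TopicNameError

__all__ = [
    "MessageKind",
    "Message",
    "encode_message",
    "decode_message",
    "validate_topic_name",
    "validate_payload",
]

TOPIC_RE = re.compile(r"^[A-Za-z0-9_]+$")

_ENVELOPE_KEYS = ("topic", "timestamp", "shipment_id", "kind", "payload")


class MessageKind(str, Enum):
    SENSOR = "SENSOR"
    LIFECYCLE = "LIFECYCLE"
    QUERY = "QUERY"
    MODEL_CONFIG = "MODEL_CONFIG"
    RESULT = "RESULT"


def validate_topic_name(topic: str) -> str:
    if not isinstance(topic, str) or not TOPIC_RE.match(topic):
        raise TopicNameError(f"invalid topic name: {topic!r}")
    return topic


def _valid_scalar(v: Any) -> bool:
    return v is None or isinstance(v, (bool, int, float, str))


def validate_payload(payload: Mapping[str, Any]) -> None:
    """Reject payloads the JSON codec cannot round-trip losslessly.

    Allowed values are scalars (bool/int/float/str/None) and flat numeric
    arrays; NaN/Inf are rejected because they are not valid JSON.
    """
    if not isinstance(payload, Mapping):
        raise CodecError(f"payload must be a mapping, got {type(payload).__name__}")
    for k, v in payload.items():
        if not isinstance(k, str):
            raise CodecError(f"payload field names must be strings, got {k!r}")
        if isinstance(v, float) and not math.isfinite(v):
            raise CodecError(f"non-finite value in field {k!r}")
        if _valid_scalar(v):
            continue
        if isinstance(v, (list, tuple)):
            if all(isinstance(x, (int, float)) and not isinstance(x, bool)
                   and math.isfinite(x) for x in v):
                continue
            raise CodecError(f"field {k!r}: arrays must hold finite numbers")
        raise CodecError(f"field {k!r} has unserializable type {type(v).__name__}")


@dataclass
class Message:
    """A time-stamped, topic-addressed field map.

    ``shipment_id`` must be non-empty for every kind except ``MODEL_CONFIG``
    (instantiation announcements address a model type, not a shipment,
    although in practice they carry the shipment id too).
    """

    topic: str
    timestamp: float
    shipment_id: str
    kind: MessageKind
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_topic_name(self.topic)
        self.kind = MessageKind(self.kind)
        if self.timestamp < 0:
            raise ValueError(f"timestamp must be >= 0, got {self.timestamp}")
        if not self.shipment_id and self.kind is not MessageKind.MODEL_CONFIG:
            raise ValueError(f"shipment_id required for kind {self.kind.value}")

    def with_topic(self, topic: str) -> "Message":
        return replace(self, topic=topic, payload=dict(self.payload))


def encode_message(message: Message) -> str:
    """Serialize a message to its one-line JSON wire form."""
    validate_payload(message.payload)
    obj = {
        "topic": message.topic,
        "timestamp": message.timestamp,
        "shipment_id": message.shipment_id,
        "kind": message.kind.value,
        "payload": {k: list(v) if isinstance(v, tuple) else v
                    for k, v in message.payload.items()},
    }
    try:
        return json.dumps(obj, separators=(",", ":"), allow_nan=False)
    except (TypeError, ValueError) as exc:  # pragma: no cover - guarded above
        raise CodecError(str(exc)) from exc


def decode_message(text: str, *, context: str = "") -> Message:
    """Parse the JSON wire form back into a :class:`Message`.

    Unknown top-level keys are preserved by folding them into the payload.
    ``context`` (e.g. "topic Foo offset 3") is included in error messages.
    """
    where = f" ({context})" if context else ""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CodecError(f"malformed JSON{where}: {exc}") from exc
    if not isinstance(obj, dict):
        raise SchemaError(f"message must be a JSON object{where}")
    missing = [k for k in ("topic", "timestamp", "kind", "payload") if k not in obj]
    if missing:
        raise SchemaError(f"missing envelope field(s) {missing}{where}")
    payload = obj["payload"]
    if not isinstance(payload, dict):
        raise SchemaError(f"payload must be a JSON object{where}")
    extras = {k: v for k, v in obj.items() if k not in _ENVELOPE_KEYS}
    if extras:
        payload = {**payload, **extras}
    try:
        kind = MessageKind(obj["kind"])
    except ValueError as exc:
        raise SchemaError(f"unknown message kind {obj['kind']!r}{where}") from exc
    return Message(
        topic=obj["topic"],
        timestamp=float(obj["timestamp"]),
        shipment_id=obj.get("shipment_id", ""),
        kind=kind,
        payload=payload,
    )
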