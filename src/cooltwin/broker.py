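"""In-memory ordered pub/sub topic log — the streaming-platform abstraction.

Log semantics, not ephemeral pub/sub: every topic is an append-only sequence
of (offset, message); a subscriber attached from offset ``k`` replays history
and then receives every later entry, in offset order.  Delivery is
at-least-once with in-order replay, so handlers must be idempotent per
(topic, offset).

The broker is single-threaded and re-entrant: a handler may publish or
subscribe while a delivery is in progress; new work is appended to the
delivery queue and drained iteratively (no recursion).  External brokers
(Kafka, MQTT) can substitute this class behind the same publish/subscribe
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .errors import RangeError
from .messages import Message, validate_payload, validate_topic_name

__all__ = ["TopicLog", "Subscription", "InMemoryBroker"]

Handler = Callable[[Message], None]


@dataclass
class TopicLog:
    """Append-only, offset-indexed message log for one topic."""

    topic: str
    entries: list[Message] = field(default_factory=list)

    def append(self, message: Message) -> int:
        self.entries.append(message)
        return len(self.entries) - 1

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Subscription:
    """A consumer's position on one topic log."""

    topic: str
    handler: Handler
    cursor: int  # next offset to deliver
    active: bool = True

    def cancel(self) -> None:
        self.active = False


class InMemoryBroker:
    """Reference implementation of the publish/subscribe contract."""

    def __init__(self) -> None:
        self._logs: dict[str, TopicLog] = {}
        self._subs: list[Subscription] = []
        self._draining = False

    # -- log access ------------------------------------------------------

    def topics(self) -> list[str]:
        return list(self._logs)

    def log(self, topic: str) -> TopicLog:
        validate_topic_name(topic)
        if topic not in self._logs:
            self._logs[topic] = TopicLog(topic)
        return self._logs[topic]

    def length(self, topic: str) -> int:
        return len(self._logs[topic]) if topic in self._logs else 0

    # -- contract --------------------------------------------------------

    def publish(self, topic: str, message: Message) -> int:
        """Append ``message`` to ``topic`` and deliver to all subscribers.

        Returns the offset at which the message was stored.  Raises
        :class:`TopicNameError` for a bad topic name and :class:`CodecError`
        for a payload the wire codec cannot represent.
        """
        validate_topic_name(topic)
        validate_payload(message.payload)
        if message.topic != topic:
            message = message.with_topic(topic)
        offset = self.log(topic).append(message)
        self._drain()
        return offset

    def subscribe(self, topic: str, from_offset: int, handler: Handler) -> Subscription:
        """Attach ``handler`` from ``from_offset``; history is replayed.

        ``from_offset`` may be at most the current log length (subscribing at
        the end means "new messages only").
        """
        validate_topic_name(topic)
        if from_offset < 0 or from_offset > self.length(topic):
            raise RangeError(
                f"from_offset {from_offset} outside log of length "
                f"{self.length(topic)} for topic {topic!r}"
            )
        sub = Subscription(topic=topic, handler=handler, cursor=from_offset)
        self._subs.append(sub)
        self._drain()
        return sub

    # -- delivery loop ---------------------------------------------------

    def _drain(self) -> None:
        # Iterative fixpoint: handlers may publish/subscribe re-entrantly;
        # the outermost call keeps going until no subscriber lags its log.
        if self._draining:
            return
        self._draining = True
        try:
            progress = True
            while progress:
                progress = False
                for sub in list(self._subs):
                    if not sub.active:
                        continue
                    log = self._logs.get(sub.topic)
                    while log is not None and sub.active and sub.cursor < len(log):
                        msg = log.entries[sub.cursor]
                        sub.cursor += 1  # advance before the call: re-entrancy safe
                        progress = True
                        sub.handler(msg)
        finally:
            self._draining = False
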