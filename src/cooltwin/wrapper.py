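"""Generic wrapper framework: model handler, wrapper instance, enrichment.

Three entities connect an updateable model to the streaming platform:

* :class:`ModelHandler` — subscribes to ``Model_Config`` and starts one
  wrapper instance per announced shipment (filtered by model name).
* :class:`WrapperInstance` — the generic wrapper: subscribes to the model's
  input topic, drives the life-cycle phase machine
  (WAITING → COLLECTING → ARMED → ACTIVE → STOPPED), verifies the sampling
  interval, fills sensor gaps with the last known value, and copies every
  input message to the output topic *enriched* with the model's result
  fields (namespaced ``Model.field``).
* :class:`SpecificWrapper` — the per-model part: ``collect()`` during early
  life-cycle phases, ``step()`` for one model update, ``predict()`` for
  query events.  Only this part must be written anew for each model type.

Enriched streams keep every model listening to a single topic: downstream
models read their predecessors' results as extra payload fields of the same
message stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Optional

from .config import Command, ModelBinding, MODEL_CONFIG_TOPIC, binding_from_announcement
from .errors import DataOutageError, QueryError
from .messages import Message, MessageKind

__all__ = [
    "Phase",
    "IntervalCheck",
    "SpecificWrapper",
    "WrapperInstance",
    "ModelHandler",
    "enrich",
    "check_interval",
    "LatencyTracker",
]

log = logging.getLogger("cooltwin")


def _log_event(level: int, event: str, **fields: Any) -> None:
    """Structured JSON-lines log record."""
    log.log(level, json.dumps({"event": event, **fields}, default=str))


class Phase(str, Enum):
    WAITING = "WAITING"
    COLLECTING = "COLLECTING"
    ARMED = "ARMED"
    ACTIVE = "ACTIVE"
    STOPPED = "STOPPED"


#: Legal phase transitions per command.
_TRANSITIONS: dict[Command, dict[Phase, Phase]] = {
    Command.START_COLLECT: {Phase.WAITING: Phase.COLLECTING},
    Command.STOP_COLLECT: {Phase.COLLECTING: Phase.ARMED},
    Command.START_MODEL: {Phase.WAITING: Phase.ACTIVE, Phase.ARMED: Phase.ACTIVE},
    Command.STOP_MODEL: {Phase.ACTIVE: Phase.STOPPED,
                         Phase.COLLECTING: Phase.STOPPED},
}


class IntervalCheck(Enum):
    OK = "OK"
    GAP = "GAP"
    REJECT = "REJECT"


def check_interval(last_t: float, t: float, nominal: float,
                   tol: float) -> IntervalCheck:
    """Classify the spacing between consecutive samples.

    OK when the interval is within ``tol`` of nominal (a gap of exactly one
    nominal interval is OK); GAP when longer (triggers gap filling); REJECT
    for non-advancing timestamps (duplicates / out-of-order) and for
    oversampled intervals shorter than ``(1 - tol) * nominal``.
    """
    if t <= last_t:
        return IntervalCheck.REJECT
    dt = t - last_t
    if abs(dt - nominal) <= tol * nominal:
        return IntervalCheck.OK
    if dt > (1.0 + tol) * nominal:
        return IntervalCheck.GAP
    return IntervalCheck.REJECT


def enrich(input_msg: Message, model_name: str,
           result: Optional[Mapping[str, Any]], *,
           topic: Optional[str] = None) -> Message:
    """Copy a message, appending result fields namespaced ``model.key``.

    Input fields are carried over unchanged (enrichment conservation); a
    ``None`` result yields an exact copy.  Namespacing precludes collisions
    between models in a chain.
    """
    payload = dict(input_msg.payload)
    if result is not None:
        for k, v in result.items():
            payload[f"{model_name}.{k}"] = v
    return Message(
        topic=topic if topic is not None else input_msg.topic,
        timestamp=input_msg.timestamp,
        shipment_id=input_msg.shipment_id,
        kind=input_msg.kind,
        payload=payload,
    )


class SpecificWrapper:
    """Contract each model implements behind the generic wrapper.

    Subclasses set :attr:`model_name`, optionally :attr:`required_fields`,
    :attr:`nominal_interval` (hours) and :attr:`interval_tolerance`
    (fraction), and override :meth:`step` — deterministic given the model
    state and inputs; return ``None`` to postpone output.  Collector models
    also override :meth:`collect`; prediction models override
    :meth:`predict`.
    """

    model_name: str = "Model"
    required_fields: tuple[str, ...] = ()
    nominal_interval: float = 1.0
    interval_tolerance: float = 0.1

    def collect(self, payload: Mapping[str, Any]) -> None:  # noqa: B027
        """Gather information during the COLLECTING phase (default: no-op)."""

    def step(self, payload: Mapping[str, Any], dt: float) -> Optional[dict]:
        """One model update; return result fields or None (output postponed)."""
        raise NotImplementedError

    def predict(self, payload: Mapping[str, Any], horizon: int,
                overrides: Mapping[str, Any]) -> Optional[dict]:
        """Answer a query event; None forwards the query untouched."""
        return None


@dataclass
class WrapperInstance:
    """Per-shipment, per-model stateful processor with a phase machine."""

    binding: ModelBinding
    shipment_id: str
    wrapper: SpecificWrapper
    broker: Any
    phase: Phase = Phase.WAITING
    max_fill: int = 48
    collected: list = field(default_factory=list)
    last_payload: Optional[dict] = None
    last_timestamp: Optional[float] = None
    call_log: list = field(default_factory=list)  # (method, phase, t)
    in_count: int = 0
    out_count: int = 0
    rejected: int = 0

    # -- phase machine ---------------------------------------------------

    def apply_command(self, command: Command, t: float) -> bool:
        """Apply a life-cycle command; illegal commands leave state unchanged."""
        target = _TRANSITIONS[command].get(self.phase)
        if target is None:
            _log_event(logging.WARNING, "illegal_command",
                       shipment=self.shipment_id, model=self.binding.model_name,
                       command=command.value, phase=self.phase.value, t=t)
            return False
        self.phase = target
        _log_event(logging.INFO, "phase_transition",
                   shipment=self.shipment_id, model=self.binding.model_name,
                   command=command.value, phase=target.value, t=t)
        return True

    # -- message processing ---------------------------------------------

    def dispatch(self, msg: Message) -> list[Message]:
        """Process one input message; returns the messages published.

        Every well-timed input produces exactly one output on the model's
        output topic (stream continuity); REJECTed samples are dropped with
        a logged warning.
        """
        self.in_count += 1
        if msg.kind is MessageKind.LIFECYCLE:
            out = self._on_lifecycle(msg)
        elif msg.kind is MessageKind.QUERY:
            out = self._on_query(msg)
        else:  # SENSOR / RESULT / stray MODEL_CONFIG all flow through
            out = self._on_sample(msg)
        published = []
        for m in out:
            self.broker.publish(self.binding.topic_out, m)
            self.out_count += 1
            published.append(m)
        return published

    def _forward(self, msg: Message) -> Message:
        return enrich(msg, self.binding.model_name, None,
                      topic=self.binding.topic_out)

    def _on_lifecycle(self, msg: Message) -> list[Message]:
        event = msg.payload.get("event", "")
        command = self.binding.lifecycle_translate.get(event)
        if command is not None:
            self.apply_command(command, msg.timestamp)
        # lifecycle events always travel down the chain
        return [self._forward(msg)]

    def _on_sample(self, msg: Message) -> list[Message]:
        if self.phase is Phase.COLLECTING:
            self.call_log.append(("collect", self.phase.value, msg.timestamp))
            self.wrapper.collect(msg.payload)
            self.collected.append(dict(msg.payload))
            return [self._forward(msg)]
        if self.phase is not Phase.ACTIVE:
            return [self._forward(msg)]

        t = msg.timestamp
        nominal = self.wrapper.nominal_interval
        if self.last_timestamp is None:
            dt = nominal
        else:
            verdict = check_interval(self.last_timestamp, t, nominal,
                                     self.wrapper.interval_tolerance)
            if verdict is IntervalCheck.REJECT:
                self.rejected += 1
                self.in_count -= 1  # not part of the accepted stream
                _log_event(logging.WARNING, "sample_rejected",
                           shipment=self.shipment_id,
                           model=self.binding.model_name,
                           t=t, last_t=self.last_timestamp)
                return []
            if verdict is IntervalCheck.GAP:
                try:
                    self.fill_gap(t)
                except DataOutageError as exc:
                    _log_event(logging.ERROR, "data_outage",
                               shipment=self.shipment_id,
                               model=self.binding.model_name,
                               t=t, detail=str(exc))
                    self.last_timestamp = t
                    self.last_payload = dict(msg.payload)
                    return [self._forward(msg)]
            dt = t - (self.last_timestamp or t)
        self.call_log.append(("step", self.phase.value, t))
        result = self.wrapper.step(msg.payload, dt)
        self.last_timestamp = t
        self.last_payload = dict(msg.payload)
        return [enrich(msg, self.binding.model_name, result,
                       topic=self.binding.topic_out)]

    def fill_gap(self, t: float) -> int:
        """Feed last-known payloads at nominal ticks strictly inside the gap.

        Synthetic steps advance the model state but publish nothing; a gap
        longer than ``max_fill`` ticks raises :class:`DataOutageError` (the
        instance keeps its state and resumes on the next sample).
        """
        assert self.last_timestamp is not None and self.last_payload is not None
        nominal = self.wrapper.nominal_interval
        ticks = []
        tick = self.last_timestamp + nominal
        while tick < t - 1e-9 * max(1.0, abs(t)):
            ticks.append(tick)
            tick += nominal
        if len(ticks) > self.max_fill:
            raise DataOutageError(
                f"gap of {len(ticks)} ticks exceeds max_fill={self.max_fill}")
        for tk in ticks:
            self.call_log.append(("step", self.phase.value, tk))
            self.wrapper.step(self.last_payload, nominal)
            self.last_timestamp = tk
        if ticks:
            _log_event(logging.INFO, "gap_filled",
                       shipment=self.shipment_id,
                       model=self.binding.model_name,
                       n_ticks=len(ticks), until=t)
        return len(ticks)

    def _on_query(self, msg: Message) -> list[Message]:
        if self.phase is not Phase.ACTIVE:
            _log_event(logging.INFO, "query_forwarded_inactive",
                       shipment=self.shipment_id,
                       model=self.binding.model_name,
                       phase=self.phase.value, t=msg.timestamp)
            return [self._forward(msg)]
        return [self.run_query(msg)]

    def run_query(self, msg: Message) -> Message:
        """Run the model's prediction for a query event.

        The horizon is ``arrival_time - t`` in whole hours (one predicted
        value per hour until the estimated arrival).  Payload fields other
        than the envelope act as what-if overrides (e.g. a setpoint change).
        """
        payload = msg.payload
        if "arrival_time" not in payload:
            err = enrich(msg, self.binding.model_name,
                         {"error": "query missing arrival_time"},
                         topic=self.binding.topic_out)
            _log_event(logging.ERROR, "query_error",
                       shipment=self.shipment_id,
                       model=self.binding.model_name, t=msg.timestamp)
            return err
        horizon = max(0, int(round(float(payload["arrival_time"]) - msg.timestamp)))
        overrides = {k: v for k, v in payload.items()
                     if k in ("setpoint", "setpoint_delta")}
        self.call_log.append(("predict", self.phase.value, msg.timestamp))
        result = self.wrapper.predict(payload, horizon, overrides)
        return enrich(msg, self.binding.model_name, result,
                      topic=self.binding.topic_out)


class ModelHandler:
    """Spawns and owns one :class:`WrapperInstance` per announced shipment.

    The handler subscribes to the configuration topic; when it detects its
    own model name in an announcement it starts a new instance subscribed to
    the announced input topic from offset 0 (late instances replay history).
    Duplicate announcements — at-least-once delivery — are suppressed keyed
    on (shipment_id, model_name).
    """

    def __init__(self, model_name: str, wrapper_factory, broker,
                 max_fill: int = 48) -> None:
        self.model_name = model_name
        self.wrapper_factory = wrapper_factory
        self.broker = broker
        self.max_fill = max_fill
        self.instances: dict[str, WrapperInstance] = {}
        broker.subscribe(MODEL_CONFIG_TOPIC, broker.length(MODEL_CONFIG_TOPIC),
                         self.handle_config_message)

    def handle_config_message(self, msg: Message) -> Optional[WrapperInstance]:
        if msg.kind is not MessageKind.MODEL_CONFIG:
            return None
        if msg.payload.get("model_name") != self.model_name:
            return None
        shipment = msg.payload.get("shipment_id") or msg.shipment_id
        if shipment in self.instances:
            _log_event(logging.INFO, "duplicate_announcement",
                       shipment=shipment, model=self.model_name)
            return None
        binding = binding_from_announcement(msg)
        instance = WrapperInstance(
            binding=binding,
            shipment_id=shipment,
            wrapper=self.wrapper_factory(binding, shipment),
            broker=self.broker,
            max_fill=self.max_fill,
        )
        self.instances[shipment] = instance
        _log_event(logging.INFO, "instance_created",
                   shipment=shipment, model=self.model_name,
                   topic_in=binding.topic_in, topic_out=binding.topic_out)
        self.broker.subscribe(binding.topic_in, 0, instance.dispatch)
        return instance


@dataclass
class LatencyTracker:
    """Wall-clock latency from sensor publish to final chain result.

    Correlation ids must be present end-to-end (the enrichment copy rule
    preserves them).  Unmatched ids are counted as lost.
    """

    starts: dict[str, float] = field(default_factory=dict)
    records: dict[str, float] = field(default_factory=dict)

    def start(self, corr_id: str, wallclock: float) -> None:
        self.starts[corr_id] = wallclock

    def finish(self, corr_id: str, wallclock: float) -> None:
        if corr_id in self.starts and corr_id not in self.records:
            self.records[corr_id] = (wallclock - self.starts[corr_id]) * 1000.0

    def summary(self) -> dict:
        lat = list(self.records.values())
        return {
            "n": len(lat),
            "mean_ms": sum(lat) / len(lat) if lat else 0.0,
            "max_ms": max(lat) if lat else 0.0,
            "lost": len(self.starts) - len(self.records),
        }
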