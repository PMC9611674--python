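"""Cargo-type configuration: model linking schemas and life-cycle translation.

A configuration document is YAML of the shape

.. code-block:: yaml

    Bananas:
      CoolIdent:
        Topic_In: Transports_Shipment_#ID_Sensors
        Topic_Out: Transports_Shipment_#ID_CoolPara
        LifeCycleTranslate:
          Start_Transport: Start_Model
          Arrive_Transport: Stop_Model
      ...
    models:          # optional parameter section, not a cargo type
      GreenLife: {GL0: 28.0, Q10: 3.0, T_ref: 13.0}

Each cargo type maps model names to their stream wiring.  Topic patterns may
contain the literal token ``#ID``; when a shipment of that cargo type is
announced, a concrete plan is generated by replacing ``#ID`` with the
shipment number, and one MODEL_CONFIG message per binding is published to the
shared ``Model_Config`` topic.  Model handlers filter these announcements by
model name and spin up one wrapper instance per shipment.

``LifeCycleTranslate`` maps transport events (Start_Transport, ...) to the
closed command vocabulary that drives each wrapper's phase machine:
Start_Collect, Stop_Collect, Start_Model, Stop_Model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import yaml

from .errors import ConfigError, WiringError
from .messages import Message, MessageKind, validate_topic_name

__all__ = [
    "Command",
    "ModelBinding",
    "ShipmentPlan",
    "TwinConfig",
    "parse_config",
    "load_config",
    "serialize_config",
    "instantiate_plan",
    "announce_plan",
    "translate_event",
    "sensor_topic",
    "DEFAULT_BANANA_CONFIG",
]

ID_TOKEN = "#ID"
MODEL_CONFIG_TOPIC = "Model_Config"
PARAMS_KEY = "models"


class Command(str, Enum):
    """Closed command set driving the wrapper phase machine."""

    START_COLLECT = "Start_Collect"
    STOP_COLLECT = "Stop_Collect"
    START_MODEL = "Start_Model"
    STOP_MODEL = "Stop_Model"


def sensor_topic(shipment_id: str) -> str:
    """Name of the raw sensor topic for one shipment (head of every chain)."""
    return f"Transports_Shipment_{shipment_id}_Sensors"


@dataclass
class ModelBinding:
    """One model's wiring for one cargo type (possibly still with #ID)."""

    cargo_type: str
    model_name: str
    topic_in: str
    topic_out: str
    lifecycle_translate: dict[str, Command] = field(default_factory=dict)

    def substitute(self, shipment_id: str) -> "ModelBinding":
        return replace(
            self,
            topic_in=self.topic_in.replace(ID_TOKEN, shipment_id),
            topic_out=self.topic_out.replace(ID_TOKEN, shipment_id),
            lifecycle_translate=dict(self.lifecycle_translate),
        )


@dataclass
class ShipmentPlan:
    """Concrete (``#ID``-substituted) chain of bindings for one shipment."""

    shipment_id: str
    cargo_type: str
    bindings: list[ModelBinding]

    @property
    def final_topic(self) -> str:
        return self.bindings[-1].topic_out


@dataclass
class TwinConfig:
    """Parsed configuration: cargo-type schemas plus model parameters."""

    cargo_types: dict[str, list[ModelBinding]]
    model_params: dict[str, dict] = field(default_factory=dict)


def _parse_binding(cargo: str, model: str, entry: dict) -> ModelBinding:
    if not isinstance(entry, dict):
        raise ConfigError(f"{cargo}.{model}: expected a mapping")
    try:
        topic_in = entry["Topic_In"]
        topic_out = entry["Topic_Out"]
    except KeyError as exc:
        raise ConfigError(f"{cargo}.{model}: missing {exc.args[0]}") from exc
    translate: dict[str, Command] = {}
    for event, cmd in (entry.get("LifeCycleTranslate") or {}).items():
        try:
            translate[str(event)] = Command(cmd)
        except ValueError as exc:
            raise ConfigError(
                f"{cargo}.{model}.LifeCycleTranslate.{event}: "
                f"unknown command {cmd!r}"
            ) from exc
    binding = ModelBinding(
        cargo_type=cargo,
        model_name=model,
        topic_in=str(topic_in),
        topic_out=str(topic_out),
        lifecycle_translate=translate,
    )
    if binding.topic_in == binding.topic_out:
        raise ConfigError(f"{cargo}.{model}: Topic_In equals Topic_Out")
    return binding


def parse_config(text: str) -> dict[str, list[ModelBinding]]:
    """Parse a configuration document into cargo-type → binding list.

    Model order in the document is the chain order.  An empty cargo section
    yields an empty list.  The reserved top-level key ``models`` holds model
    parameters and is ignored here (see :func:`load_config`).
    """
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigError("top level must map cargo types to model sections")
    schemas: dict[str, list[ModelBinding]] = {}
    for cargo, models in doc.items():
        if cargo == PARAMS_KEY:
            continue
        bindings: list[ModelBinding] = []
        for model, entry in (models or {}).items():
            bindings.append(_parse_binding(str(cargo), str(model), entry))
        schemas[str(cargo)] = bindings
    return schemas


def load_config(text: str) -> TwinConfig:
    """Parse schemas *and* the optional ``models:`` parameter section."""
    schemas = parse_config(text)
    doc = yaml.safe_load(io.StringIO(text)) or {}
    params = doc.get(PARAMS_KEY) or {} if isinstance(doc, dict) else {}
    if params and not isinstance(params, dict):
        raise ConfigError("'models' section must be a mapping")
    return TwinConfig(cargo_types=schemas, model_params=dict(params))


def serialize_config(schemas: dict[str, list[ModelBinding]]) -> str:
    """Inverse of :func:`parse_config` (round-trips to an equal schema map)."""
    doc: dict = {}
    for cargo, bindings in schemas.items():
        doc[cargo] = {
            b.model_name: {
                "Topic_In": b.topic_in,
                "Topic_Out": b.topic_out,
                "LifeCycleTranslate": {e: c.value for e, c in
                                       b.lifecycle_translate.items()},
            }
            for b in bindings
        }
    return yaml.safe_dump(doc, sort_keys=False)


def instantiate_plan(
    cargo_type: str,
    shipment_id: str,
    schemas: dict[str, list[ModelBinding]],
) -> ShipmentPlan:
    """Generate the concrete per-shipment plan by ``#ID`` substitution.

    The bindings must form a connected linear chain: the first model reads
    the shipment sensor topic, and every later model reads either the sensor
    topic or a topic some earlier model writes.
    """
    if cargo_type not in schemas:
        raise ConfigError(f"unknown cargo type {cargo_type!r}")
    if not shipment_id or not shipment_id.isalnum():
        raise ConfigError(f"shipment id must be alphanumeric, got {shipment_id!r}")
    bindings = [b.substitute(shipment_id) for b in schemas[cargo_type]]
    produced = {sensor_topic(shipment_id)}
    for b in bindings:
        validate_topic_name(b.topic_in)
        validate_topic_name(b.topic_out)
        if b.topic_in not in produced:
            raise WiringError(
                f"{cargo_type}.{b.model_name}: input topic {b.topic_in!r} is "
                "neither the shipment sensor topic nor produced upstream"
            )
        produced.add(b.topic_out)
    return ShipmentPlan(shipment_id=shipment_id, cargo_type=cargo_type,
                        bindings=bindings)


def announce_plan(plan: ShipmentPlan, broker, timestamp: float = 0.0) -> list[int]:
    """Publish one MODEL_CONFIG message per binding to ``Model_Config``.

    Handlers for all model types subscribe to this topic and filter by model
    name; re-announcing the same plan is harmless because handlers suppress
    duplicates keyed on (shipment_id, model_name).
    """
    offsets = []
    for b in plan.bindings:
        msg = Message(
            topic=MODEL_CONFIG_TOPIC,
            timestamp=timestamp,
            shipment_id=plan.shipment_id,
            kind=MessageKind.MODEL_CONFIG,
            payload={
                "model_name": b.model_name,
                "cargo_type": b.cargo_type,
                "shipment_id": plan.shipment_id,
                "topic_in": b.topic_in,
                "topic_out": b.topic_out,
                "lifecycle_translate": None,  # placeholder, replaced below
            },
        )
        # translate table as flat namespaced fields (wire format is scalars)
        msg.payload.pop("lifecycle_translate")
        for event, cmd in b.lifecycle_translate.items():
            msg.payload[f"translate.{event}"] = cmd.value
        offsets.append(broker.publish(MODEL_CONFIG_TOPIC, msg))
    return offsets


def binding_from_announcement(msg: Message) -> ModelBinding:
    """Rebuild a concrete :class:`ModelBinding` from a MODEL_CONFIG message."""
    p = msg.payload
    translate = {
        k[len("translate."):]: Command(v)
        for k, v in p.items() if k.startswith("translate.")
    }
    return ModelBinding(
        cargo_type=p.get("cargo_type", ""),
        model_name=p["model_name"],
        topic_in=p["topic_in"],
        topic_out=p["topic_out"],
        lifecycle_translate=translate,
    )


def translate_event(event_name: str, binding: ModelBinding) -> Optional[Command]:
    """Map a transport event to this model's command; unmapped events → None."""
    return binding.lifecycle_translate.get(event_name)


#: Default banana-chain configuration: the prediction scenario rearranged to
#: a linear enriched-stream chain (identification → temperature prediction →
#: ripening-heat observation → green-life prediction).
DEFAULT_BANANA_CONFIG = """\
Bananas:
  CoolIdent:
    Topic_In: Transports_Shipment_#ID_Sensors
    Topic_Out: Transports_Shipment_#ID_CoolPara
    LifeCycleTranslate:
      Start_Transport: Start_Model
      Arrive_Transport: Stop_Model
  CoolPredict:
    Topic_In: Transports_Shipment_#ID_CoolPara
    Topic_Out: Transports_Shipment_#ID_CoolPred
    LifeCycleTranslate:
      Start_Transport: Start_Model
      Stop_Ripening: Stop_Model
  RipeHeat:
    Topic_In: Transports_Shipment_#ID_CoolPred
    Topic_Out: Transports_Shipment_#ID_RipePara
    LifeCycleTranslate:
      Start_Transport: Start_Collect
      Arrive_Transport: Stop_Collect
      Start_Ripening: Start_Model
      Stop_Ripening: Stop_Model
  GreenLife:
    Topic_In: Transports_Shipment_#ID_RipePara
    Topic_Out: Transports_Shipment_#ID_GreenLife
    LifeCycleTranslate:
      Start_Transport: Start_Model
      Stop_Ripening: Stop_Model
"""
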