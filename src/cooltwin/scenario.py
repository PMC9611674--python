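"""Synthetic cool-chain scenarios and accelerated playback.

The generator emulates the four banana-chain phases — warm loading/packing,
cooling ocean transport, a harbor gap with cooling off, and artificial
ripening with its heat pulse — as a deterministic, seeded message list
(sensor samples, life-cycle events and prediction queries).  Playback
publishes the list into a broker either as fast as possible (deterministic
runs) or paced at a configurable message rate per shipment, emulating hourly
measurements replayed at accelerated speed.

Box temperatures are generated with the same explicit-Euler thermal update
the models assume; supply-air noise enters the dynamics (the container
reacts to its actual supply air), while box-sensor noise is measurement-only.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .broker import InMemoryBroker
from .errors import ScenarioError
from .messages import Message, MessageKind, decode_message, encode_message
from .config import sensor_topic
from .models import ThermalParams, cool_step
from .wrapper import LatencyTracker

__all__ = [
    "ScenarioSpec",
    "build_scenario",
    "play",
    "PlaybackReport",
    "export_run",
    "load_dump",
    "reference_scenario",
]

_ENVELOPE_COLS = ["offset", "topic", "timestamp", "shipment_id", "kind"]


@dataclass
class ScenarioSpec:
    """Study conditions for one synthetic run.

    Phase starts are hours since scenario start and must strictly increase;
    ``harbor_start`` doubles as the estimated arrival time carried by query
    events.  Defaults describe the reference scenario: bananas loaded warm
    at 26 °C, a 14-day crossing cooled to a 13.2 °C setpoint, a 12 h harbor
    gap drifting toward 18 °C ambient, then four days of ripening releasing
    0.3 K/h — all synthetic defaults (the setpoint matches the typical
    13.0–14.4 °C band).
    """

    shipment_ids: tuple[str, ...] = ("4711",)
    cargo_type: str = "Bananas"
    packing_start: float = 0.0
    transport_start: float = 6.0
    harbor_start: float = 342.0     # transport_start + 14 d
    ripening_start: float = 354.0   # + 12 h harbor gap
    end: float = 450.0              # + 4 d ripening
    t_load: float = 26.0            # °C, "warm" loading
    setpoint: float = 13.2          # °C supply-air setpoint
    true_k_m: float = 0.05          # 1/h
    ripening_q: float = 0.3         # K/h during ripening
    supply_noise: float = 0.05      # K, enters the dynamics
    box_noise: float = 0.05         # K, measurement only
    sampling_interval: float = 1.0  # h
    ambient: float = 18.0           # °C, harbor surroundings
    harbor_k: float = 0.02          # 1/h drift rate with cooling off
    queries: tuple[tuple[float, dict], ...] = ()  # (hour, overrides)
    seed: int = 42

    def validate(self) -> None:
        starts = [self.packing_start, self.transport_start, self.harbor_start,
                  self.ripening_start, self.end]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ScenarioError(f"phase starts must strictly increase: {starts}")
        if self.sampling_interval <= 0:
            raise ScenarioError("sampling interval must be positive")
        if min(self.supply_noise, self.box_noise) < 0:
            raise ScenarioError("noise levels must be non-negative")
        for t, _ in self.queries:
            if not self.packing_start <= t <= self.end:
                raise ScenarioError(f"query at {t} h outside scenario")

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        import yaml

        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ScenarioError("scenario file must be a mapping")
        queries = tuple(
            (float(q["at"]), {k: v for k, v in q.items() if k != "at"})
            for q in doc.pop("queries", [])
        )
        ids = doc.pop("shipment_ids", None)
        kwargs = {k: v for k, v in doc.items()}
        if ids is not None:
            kwargs["shipment_ids"] = tuple(str(i) for i in ids)
        try:
            spec = cls(queries=queries, **kwargs)
        except TypeError as exc:
            raise ScenarioError(f"unknown scenario key: {exc}") from exc
        spec.validate()
        return spec


_LIFECYCLE_AT = (
    ("transport_start", "Start_Transport"),
    ("harbor_start", "Arrive_Transport"),
    ("ripening_start", "Start_Ripening"),
    ("end", "Stop_Ripening"),
)


def _phase_of(spec: ScenarioSpec, t: float) -> str:
    if t < spec.transport_start:
        return "packing"
    if t < spec.harbor_start:
        return "transport"
    if t < spec.ripening_start:
        return "harbor"
    return "ripening"


def build_scenario(spec: ScenarioSpec) -> list[Message]:
    """Generate the full ordered message list for all shipments.

    Life-cycle events are emitted before the sensor sample of their boundary
    hour, so the first sample a newly active model sees is the initial state
    of its phase.  The same seed always yields a byte-identical list.
    """
    spec.validate()
    per_shipment: list[list[Message]] = []
    for idx, sid in enumerate(spec.shipment_ids):
        rng = np.random.default_rng([spec.seed, idx])
        topic = sensor_topic(sid)
        msgs: list[Message] = []
        fired = set()
        queries = sorted(
            ((t, dict(o)) for t, o in spec.queries), key=lambda q: q[0])
        qi = 0
        T = spec.t_load  # true box state
        t = spec.packing_start
        n_q = 0
        while t <= spec.end + 1e-9:
            for attr, event in _LIFECYCLE_AT:
                bound = getattr(spec, attr)
                if event not in fired and t >= bound - 1e-9:
                    fired.add(event)
                    msgs.append(Message(topic, max(bound, 0.0), sid,
                                        MessageKind.LIFECYCLE,
                                        {"event": event}))
            phase = _phase_of(spec, t)
            if phase in ("transport", "ripening"):
                supply = spec.setpoint + (
                    rng.normal(0.0, spec.supply_noise) if spec.supply_noise else 0.0)
                params = ThermalParams(
                    k_M=spec.true_k_m,
                    q=spec.ripening_q if phase == "ripening" else 0.0)
            else:  # packing / harbor: cooling off, slow drift toward ambient
                supply = spec.ambient + (
                    rng.normal(0.0, spec.supply_noise) if spec.supply_noise else 0.0)
                params = ThermalParams(k_M=spec.harbor_k)
            box_meas = T + (rng.normal(0.0, spec.box_noise)
                            if spec.box_noise else 0.0)
            msgs.append(Message(topic, t, sid, MessageKind.SENSOR,
                                {"T_Box": box_meas, "T_Supply": supply}))
            while qi < len(queries) and queries[qi][0] <= t + 1e-9:
                q_t, overrides = queries[qi]
                n_q += 1
                payload = {"query_id": f"{sid}-q{n_q}",
                           "arrival_time": spec.harbor_start, **overrides}
                msgs.append(Message(topic, t, sid, MessageKind.QUERY, payload))
                qi += 1
            # advance the true state over [t, t + dt)
            T = cool_step(T, supply, params, spec.sampling_interval)
            t += spec.sampling_interval
        per_shipment.append(msgs)
    # stable merge by timestamp; ties keep shipment order
    merged: list[Message] = []
    cursors = [0] * len(per_shipment)
    while True:
        best = None
        for i, msgs in enumerate(per_shipment):
            if cursors[i] < len(msgs):
                ts = msgs[cursors[i]].timestamp
                if best is None or ts < per_shipment[best][cursors[best]].timestamp:
                    best = i
        if best is None:
            break
        merged.append(per_shipment[best][cursors[best]])
        cursors[best] += 1
    return merged


@dataclass
class PlaybackReport:
    published: dict[str, int] = field(default_factory=dict)
    total: int = 0
    lost: int = 0
    mode: str = "fast"
    target_spacing_s: Optional[float] = None
    latency: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def play(
    messages: list[Message],
    broker: InMemoryBroker,
    *,
    speed: float = 10.0,
    mode: str = "fast",
    tracker: Optional[LatencyTracker] = None,
) -> PlaybackReport:
    """Publish a scenario into the broker, per-shipment sensor topics.

    ``mode='fast'`` publishes as fast as possible (deterministic runs);
    ``mode='wallclock'`` paces at ``speed`` messages per second per shipment.
    Each message is stamped with a correlation id (``_corr`` payload field)
    so end-to-end latency can be matched on the final chain topic.
    """
    if mode not in ("fast", "wallclock"):
        raise ValueError(f"unknown playback mode {mode!r}")
    n_ship = len({m.shipment_id for m in messages}) or 1
    spacing = (1.0 / speed) / n_ship if mode == "wallclock" else None
    report = PlaybackReport(mode=mode, target_spacing_s=spacing)
    for i, msg in enumerate(messages):
        corr = f"{msg.shipment_id}:{i}"
        stamped = replace(msg, payload={**msg.payload, "_corr": corr})
        if tracker is not None:
            tracker.start(corr, time.perf_counter())
        if spacing is not None and i:
            time.sleep(spacing)
        broker.publish(msg.topic, stamped)
        report.published[msg.topic] = report.published.get(msg.topic, 0) + 1
        report.total += 1
    if tracker is not None:
        report.latency = tracker.summary()
        report.lost = report.latency["lost"]
    return report


def _cell(value):
    if isinstance(value, (list, tuple)):
        return json.dumps(list(value))
    return value


def export_run(broker: InMemoryBroker, topics: list[str], path) -> list[Path]:
    """Dump each topic as JSON-lines and as a tidy CSV.

    The CSV has one row per message and one column per payload field (in
    first-seen order); array fields are embedded as JSON strings.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for topic in topics:
        entries = broker.log(topic).entries
        jl = outdir / f"{topic}.jsonl"
        jl.write_text("".join(encode_message(m) + "\n" for m in entries))
        written.append(jl)
        cols = list(_ENVELOPE_COLS)
        rows = []
        for off, m in enumerate(entries):
            row = {"offset": off, "topic": m.topic, "timestamp": m.timestamp,
                   "shipment_id": m.shipment_id, "kind": m.kind.value}
            for k, v in m.payload.items():
                if k not in cols:
                    cols.append(k)
                row[k] = _cell(v)
            rows.append(row)
        df = pd.DataFrame(rows, columns=cols)
        csv = outdir / f"{topic}.csv"
        df.to_csv(csv, index=False)
        written.append(csv)
    return written


def load_dump(path) -> list[Message]:
    """Reload a JSON-lines topic dump written by :func:`export_run`."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if line.strip():
            out.append(decode_message(line, context=f"{path} line {i + 1}"))
    return out


def reference_scenario(**overrides) -> ScenarioSpec:
    """The default single-shipment reference scenario (see class docstring)."""
    return replace(ScenarioSpec(), **overrides) if overrides else ScenarioSpec()
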