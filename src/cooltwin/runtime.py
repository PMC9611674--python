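"""Glue layer: wire config, handlers, scenario playback and reporting."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .broker import InMemoryBroker
from .config import ShipmentPlan, TwinConfig, announce_plan, instantiate_plan
from .errors import WiringError
from .messages import Message
from .models import MODEL_TYPES
from .scenario import PlaybackReport, ScenarioSpec, build_scenario, export_run, play
from .wrapper import LatencyTracker, ModelHandler, Phase

__all__ = ["TwinRuntime", "InvariantReport"]


@dataclass
class InvariantReport:
    """Post-run framework health check (used by tests and the CLI)."""

    continuity_ok: bool = True
    phase_legality_ok: bool = True
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.continuity_ok and self.phase_legality_ok


class TwinRuntime:
    """One broker, one handler per configured model type, many shipments."""

    def __init__(self, config: TwinConfig,
                 broker: Optional[InMemoryBroker] = None) -> None:
        self.config = config
        self.broker = broker or InMemoryBroker()
        self.handlers: dict[str, ModelHandler] = {}
        self.tracker = LatencyTracker()
        self._final_topics: dict[str, str] = {}  # shipment -> last chain topic
        names: list[str] = []
        for bindings in config.cargo_types.values():
            for b in bindings:
                if b.model_name not in names:
                    names.append(b.model_name)
        for name in names:
            if name not in MODEL_TYPES:
                raise WiringError(f"no wrapper registered for model {name!r}")
            params = config.model_params.get(name)
            self.handlers[name] = ModelHandler(
                name,
                lambda binding, shipment, _n=name, _p=params: MODEL_TYPES[_n](_p),
                self.broker,
            )

    # -- shipments -------------------------------------------------------

    def announce(self, shipment_id: str, cargo_type: str) -> ShipmentPlan:
        plan = instantiate_plan(cargo_type, shipment_id, self.config.cargo_types)
        announce_plan(plan, self.broker)
        final = plan.final_topic
        self._final_topics[shipment_id] = final
        self.broker.subscribe(
            final, 0,
            lambda m: self.tracker.finish(m.payload.get("_corr", ""),
                                          time.perf_counter()))
        return plan

    def final_topic(self, shipment_id: str) -> str:
        return self._final_topics[shipment_id]

    def chain_topics(self, shipment_id: str, cargo_type: str) -> list[str]:
        plan = instantiate_plan(cargo_type, shipment_id, self.config.cargo_types)
        return [plan.bindings[0].topic_in] + [b.topic_out for b in plan.bindings]

    # -- end-to-end ------------------------------------------------------

    def run_scenario(self, spec: ScenarioSpec, *, mode: str = "fast",
                     speed: float = 10.0) -> PlaybackReport:
        for sid in spec.shipment_ids:
            self.announce(sid, spec.cargo_type)
        messages = build_scenario(spec)
        return play(messages, self.broker, speed=speed, mode=mode,
                    tracker=self.tracker)

    def export(self, spec: ScenarioSpec, outdir) -> list[Path]:
        topics: list[str] = []
        for sid in spec.shipment_ids:
            for t in self.chain_topics(sid, spec.cargo_type):
                if t not in topics:
                    topics.append(t)
        return export_run(self.broker, topics, outdir)

    def latency_csv(self, path) -> Path:
        """Latency summary as CSV (shipment, model, n, mean_ms, max_ms, lost)."""
        rows = []
        s = self.tracker.summary()
        for sid, topic in self._final_topics.items():
            per = [v for k, v in self.tracker.records.items()
                   if k.startswith(f"{sid}:")]
            started = [k for k in self.tracker.starts if k.startswith(f"{sid}:")]
            rows.append({
                "shipment": sid,
                "model": topic,
                "n": len(per),
                "mean_ms": sum(per) / len(per) if per else 0.0,
                "max_ms": max(per) if per else 0.0,
                "lost": len(started) - len(per),
            })
        rows.append({"shipment": "ALL", "model": "", **s})
        out = Path(path)
        pd.DataFrame(rows).to_csv(out, index=False)
        return out

    # -- invariants ------------------------------------------------------

    def instances(self):
        for handler in self.handlers.values():
            yield from handler.instances.values()

    def check_invariants(self) -> InvariantReport:
        """Stream continuity and phase legality over every instance."""
        report = InvariantReport()
        for inst in self.instances():
            label = f"{inst.binding.model_name}/{inst.shipment_id}"
            if inst.out_count != inst.in_count:
                report.continuity_ok = False
                report.violations.append(
                    f"{label}: out {inst.out_count} != in {inst.in_count}")
            for method, phase, t in inst.call_log:
                legal = (method == "step" and phase == Phase.ACTIVE.value) or \
                        (method == "collect" and phase == Phase.COLLECTING.value) or \
                        (method == "predict" and phase == Phase.ACTIVE.value)
                if not legal:
                    report.phase_legality_ok = False
                    report.violations.append(
                        f"{label}: {method}() in phase {phase} at t={t}")
        return report

    def query_results(self, shipment_id: str, query_id: str) -> list[Message]:
        """All final-topic messages carrying the given query id."""
        topic = self._final_topics[shipment_id]
        return [m for m in self.broker.log(topic).entries
                if m.payload.get("query_id") == query_id]
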