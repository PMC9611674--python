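"""Generic wrapper: phase machine, enrichment, sampling checks, queries."""

import pytest

from cooltwin import (
    Command,
    IntervalCheck,
    LatencyTracker,
    Message,
    MessageKind,
    ModelBinding,
    Phase,
    WrapperInstance,
    check_interval,
    enrich,
)
from cooltwin.wrapper import SpecificWrapper


class EchoWrapper(SpecificWrapper):
    """Counts calls; step returns a running index."""

    model_name = "Echo"

    def __init__(self):
        self.steps = 0
        self.collects = 0

    def collect(self, payload):
        self.collects += 1

    def step(self, payload, dt):
        self.steps += 1
        return {"i": self.steps}

    def predict(self, payload, horizon, overrides):
        return {"prediction": [0.0] * horizon}


def make_instance(broker, translate=None, **kw):
    binding = ModelBinding(
        cargo_type="Bananas", model_name="Echo",
        topic_in="In4711", topic_out="Out4711",
        lifecycle_translate=translate or {
            "Start_Transport": Command.START_COLLECT,
            "Arrive_Transport": Command.STOP_COLLECT,
            "Start_Ripening": Command.START_MODEL,
            "Stop_Ripening": Command.STOP_MODEL,
        },
    )
    return WrapperInstance(binding=binding, shipment_id="4711",
                           wrapper=EchoWrapper(), broker=broker, **kw)


def sensor(t, **fields):
    return Message("In4711", t, "4711", MessageKind.SENSOR,
                   fields or {"T_Box": 20.0, "T_Supply": 13.2})


def lifecycle(t, event):
    return Message("In4711", t, "4711", MessageKind.LIFECYCLE, {"event": event})


def query(t, **fields):
    return Message("In4711", t, "4711", MessageKind.QUERY, fields)


class TestPhaseMachine:
    def test_full_lifecycle_path(self, broker):
        inst = make_instance(broker)
        assert inst.phase is Phase.WAITING
        inst.dispatch(lifecycle(0.0, "Start_Transport"))
        assert inst.phase is Phase.COLLECTING
        inst.dispatch(lifecycle(10.0, "Arrive_Transport"))
        assert inst.phase is Phase.ARMED
        inst.dispatch(lifecycle(12.0, "Start_Ripening"))
        assert inst.phase is Phase.ACTIVE
        inst.dispatch(lifecycle(20.0, "Stop_Ripening"))
        assert inst.phase is Phase.STOPPED

    def test_collector_phase_can_be_omitted(self, broker):
        inst = make_instance(broker, translate={
            "Start_Transport": Command.START_MODEL})
        inst.dispatch(lifecycle(0.0, "Start_Transport"))
        assert inst.phase is Phase.ACTIVE

    def test_illegal_command_leaves_state_unchanged(self, broker):
        inst = make_instance(broker)
        inst.dispatch(lifecycle(0.0, "Arrive_Transport"))  # Stop_Collect in WAITING
        assert inst.phase is Phase.WAITING

    def test_unmapped_event_ignored(self, broker):
        inst = make_instance(broker)
        inst.dispatch(lifecycle(0.0, "Door_Opened"))
        assert inst.phase is Phase.WAITING

    def test_lifecycle_events_forwarded_downstream(self, broker):
        inst = make_instance(broker)
        (out,) = inst.dispatch(lifecycle(0.0, "Start_Transport"))
        assert out.topic == "Out4711" and out.payload == {"event": "Start_Transport"}


class TestDispatch:
    def test_waiting_pass_through_is_pure_copy(self, broker):
        inst = make_instance(broker)
        msg = sensor(1.0)
        (out,) = inst.dispatch(msg)
        assert out.payload == msg.payload and out.topic == "Out4711"
        assert out.timestamp == msg.timestamp

    def test_active_sensor_enriched_with_model_fields(self, broker):
        inst = make_instance(broker, translate={"Go": Command.START_MODEL})
        inst.dispatch(lifecycle(0.0, "Go"))
        (out,) = inst.dispatch(sensor(1.0))
        assert out.payload["Echo.i"] == 1
        assert out.payload["T_Box"] == 20.0 and out.payload["T_Supply"] == 13.2

    def test_collect_count_matches_instrumented_log(self, broker):
        inst = make_instance(broker)
        inst.dispatch(lifecycle(0.0, "Start_Transport"))
        for h in range(72):
            inst.dispatch(sensor(float(h)))
        inst.dispatch(lifecycle(72.0, "Arrive_Transport"))
        inst.dispatch(lifecycle(80.0, "Start_Ripening"))
        assert inst.phase is Phase.ACTIVE
        assert inst.wrapper.collects == 72
        assert len(inst.collected) == 72
        assert sum(1 for m, _, _ in inst.call_log if m == "collect") == 72

    def test_stream_continuity_over_mixed_run(self, broker):
        inst = make_instance(broker)
        inst.dispatch(lifecycle(0.0, "Start_Transport"))
        for h in range(10):
            inst.dispatch(sensor(float(h)))
        inst.dispatch(lifecycle(10.0, "Arrive_Transport"))
        inst.dispatch(lifecycle(12.0, "Start_Ripening"))
        for h in range(12, 20):
            inst.dispatch(sensor(float(h)))
        assert inst.out_count == inst.in_count
        assert broker.length("Out4711") == inst.out_count

    def test_phase_legality_by_construction(self, broker):
        inst = make_instance(broker)
        inst.dispatch(sensor(0.0))                      # WAITING: no calls
        inst.dispatch(lifecycle(0.0, "Start_Transport"))
        inst.dispatch(sensor(1.0))                      # COLLECTING: collect
        inst.dispatch(lifecycle(2.0, "Arrive_Transport"))
        inst.dispatch(sensor(2.0))                      # ARMED: pass-through
        inst.dispatch(lifecycle(3.0, "Start_Ripening"))
        inst.dispatch(sensor(3.0))                      # ACTIVE: step
        for method, phase, _ in inst.call_log:
            assert (method, phase) in {("collect", "COLLECTING"),
                                       ("step", "ACTIVE"),
                                       ("predict", "ACTIVE")}


class TestEnrich:
    def test_none_result_is_identity(self):
        msg = sensor(1.0)
        out = enrich(msg, "CoolIdent", None)
        assert out.payload == msg.payload

    def test_namespaced_result_fields(self):
        msg = sensor(1.0)
        out = enrich(msg, "CoolIdent", {"k_M": 0.05})
        assert out.payload["CoolIdent.k_M"] == 0.05
        assert out.payload["T_Box"] == msg.payload["T_Box"]

    def test_chained_enrichment_is_superset(self):
        msg = sensor(1.0)
        out = msg
        for name in ("CoolIdent", "CoolPredict", "RipeHeat"):
            out = enrich(out, name, {"v": 1.0})
        assert set(msg.payload) <= set(out.payload)
        assert {f"{n}.v" for n in ("CoolIdent", "CoolPredict", "RipeHeat")} <= set(
            out.payload)


class TestIntervalCheck:
    @pytest.mark.parametrize("last,t,expected", [
        (10.0, 11.0, IntervalCheck.OK),
        (10.0, 11.05, IntervalCheck.OK),
        (10.0, 11.1, IntervalCheck.OK),      # boundary of tolerance band
        (10.0, 13.0, IntervalCheck.GAP),
        (10.0, 11.2, IntervalCheck.GAP),
        (10.0, 10.0, IntervalCheck.REJECT),  # non-advancing time
        (10.0, 9.5, IntervalCheck.REJECT),
        (10.0, 10.2, IntervalCheck.REJECT),  # oversampled
    ])
    def test_classification(self, last, t, expected):
        assert check_interval(last, t, 1.0, 0.1) is expected


class TestGapFilling:
    def active_instance(self, broker, **kw):
        inst = make_instance(broker, translate={"Go": Command.START_MODEL}, **kw)
        inst.dispatch(lifecycle(0.0, "Go"))
        return inst

    def test_three_hour_gap_yields_two_synthetic_steps(self, broker):
        inst = self.active_instance(broker)
        inst.dispatch(sensor(10.0))
        inst.dispatch(sensor(13.0))
        # 1 step at t=10, synthetic at 11 and 12, real at 13
        assert inst.wrapper.steps == 4
        # forwarded lifecycle + 2 sensor outputs; synthetic steps publish nothing
        assert broker.length("Out4711") == 3

    def test_exact_nominal_interval_is_not_a_gap(self, broker):
        inst = self.active_instance(broker)
        inst.dispatch(sensor(10.0))
        inst.dispatch(sensor(11.0))
        assert inst.wrapper.steps == 2

    def test_outage_beyond_max_fill(self, broker):
        inst = self.active_instance(broker, max_fill=48)
        inst.dispatch(sensor(0.0))
        (out,) = inst.dispatch(sensor(200.0))  # forwarded, state kept
        assert inst.wrapper.steps == 1
        assert out.payload == sensor(200.0).payload
        inst.dispatch(sensor(201.0))  # resumes on next OK sample
        assert inst.wrapper.steps == 2

    def test_rejected_sample_produces_no_output(self, broker):
        inst = self.active_instance(broker)
        inst.dispatch(sensor(10.0))
        assert inst.dispatch(sensor(10.0)) == []
        assert inst.rejected == 1


class TestQueries:
    def active_instance(self, broker):
        inst = make_instance(broker, translate={"Go": Command.START_MODEL})
        inst.dispatch(lifecycle(0.0, "Go"))
        return inst

    def test_horizon_until_arrival(self, broker):
        inst = self.active_instance(broker)
        (out,) = inst.dispatch(query(72.0, arrival_time=336.0))
        assert len(out.payload["Echo.prediction"]) == 264

    def test_zero_horizon(self, broker):
        inst = self.active_instance(broker)
        (out,) = inst.dispatch(query(336.0, arrival_time=336.0))
        assert out.payload["Echo.prediction"] == []

    def test_missing_arrival_time_yields_error_message(self, broker):
        inst = self.active_instance(broker)
        (out,) = inst.dispatch(query(72.0, query_id="q1"))
        assert "arrival_time" in out.payload["Echo.error"]

    def test_query_in_waiting_forwarded_untouched(self, broker):
        inst = make_instance(broker)
        msg = query(72.0, arrival_time=336.0)
        (out,) = inst.dispatch(msg)
        assert out.payload == msg.payload


class TestLatency:
    def test_mean_and_max(self):
        tr = LatencyTracker()
        for i in range(100):
            tr.start(f"c{i}", 0.0)
            tr.finish(f"c{i}", (i + 1) / 1000.0)
        s = tr.summary()
        assert s["n"] == 100 and s["lost"] == 0
        assert s["mean_ms"] == pytest.approx(50.5)
        assert s["max_ms"] == pytest.approx(100.0)

    def test_lost_message_counted(self):
        tr = LatencyTracker()
        tr.start("a", 0.0)
        tr.start("b", 0.0)
        tr.finish("a", 0.001)
        assert tr.summary()["lost"] == 1
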