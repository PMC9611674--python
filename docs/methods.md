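# Methods

## Architecture

All communication is a stream of JSON messages on named topics of an ordered,
append-only log (`cooltwin.broker.InMemoryBroker`). Topics are per shipment
and per model; a model never filters — it subscribes to exactly one topic.
The log gives at-least-once delivery with in-order replay, so every handler
is idempotent per (topic, offset); a late subscriber replays history. The
in-memory log is the reference implementation of the publish/subscribe
contract; an external broker (Kafka, MQTT) can substitute it behind the same
two functions, which is why nothing above the broker knows about threads,
sockets or partitions. Partitioning, consumer groups and exactly-once
semantics are out of scope.

Messages carry *logical* time in hours since scenario start. This decouples
model time from playback speed: hourly measurements can be replayed at
hundreds of messages per second without touching the models. Wall-clock time
is used only for latency instrumentation (correlation ids stamped at publish,
matched on the final chain topic).

### Enriched streams

Each wrapper copies its entire input topic to its output topic, appending its
own result fields namespaced `Model.field` (`CoolIdent.k_M`,
`GreenLife.remaining`, ...). Namespacing makes collisions impossible and
lets a chain of models communicate over one linear stream: the ripening-heat
observer reads `CoolIdent.k_M` out of the same messages that carry the
temperatures. Two invariants follow and are checked after every test run:
*stream continuity* (one output message per well-timed input message) and
*enrichment conservation* (input payload is a subset of the output payload,
values unchanged).

### Life-cycle phase machine

Transport events (`Start_Transport`, `Arrive_Transport`, `Start_Ripening`,
`Stop_Ripening`) are translated per model — via the cargo-type configuration
— into a closed command set `{Start_Collect, Stop_Collect, Start_Model,
Stop_Model}` driving the phases

```
WAITING -> COLLECTING -> ARMED -> ACTIVE -> STOPPED
```

with the shortcuts WAITING→ACTIVE (models that need no collector phase) and
COLLECTING→STOPPED. `ARMED` is the package's name for the wait between the
end of collection and model start (the ripening model idles there between
arrival and the start of ripening). A dormant (non-ACTIVE) wrapper forwards
traffic unchanged so downstream models keep receiving the stream. `step()`
can only run in ACTIVE and `collect()` only in COLLECTING; an instrumented
call log verifies this after every scenario run. Illegal commands are logged
and ignored. The command vocabulary is closed deliberately: it makes the
phase machine exhaustively checkable.

### Sampling checks and gap filling

Before each ACTIVE step the wrapper classifies the sample spacing against the
model's nominal interval (default 1 h) with a relative tolerance (default
10 %):

* **OK** — within tolerance (a gap of exactly one nominal interval is OK);
* **GAP** — longer: the gap is filled by feeding the last known payload at
  each missing nominal tick (state advances, nothing is published), up to
  `max_fill` ticks (default 48); beyond that a data-outage error is logged,
  the instance keeps its state and resumes on the next sample;
* **REJECT** — non-advancing timestamps (duplicates, out-of-order), and also
  intervals shorter than `(1 − tol)·nominal`: the classification must be
  total and oversampled readings carry no usable one-step information, so
  they are dropped with a logged warning. Rejected samples are the one case
  that produces no output message.

## Model concretizations

The wrapper architecture is agnostic to the models' inner equations; the
shipped forms are the simplest ones consistent with the models' observable
behavior (inputs, outputs, three-day stability, hourly prediction,
hidden-heat observation), and each sits behind the `SpecificWrapper`
interface so a richer form can be swapped in without touching the framework.

**Thermal model.** Explicit Euler,
`T' = T + dt·(−k_M (T − T_Supply) + q)`, valid for `dt·k_M < 1` (enforced).
`q` absorbs the heat capacity and is expressed in K/h, avoiding an
unidentifiable extra parameter.

**k_M estimator.** Regression through the origin of `y = (T_i − T_{i+1})/dt`
on `x = T_i − T_Supply,i` with running sums (`k̂ = Σxy / Σx²`). During
estimation `q = 0` is assumed (cooling precedes ripening); ripening heat
during the window would appear as a positive residual bias — documented, not
corrected. `Σx² = 0` after ≥ 24 samples raises an identifiability error (no
thermal excitation). The *stable* flag requires ≥ 72 h elapsed **and** a
relative spread of the estimate below 2 % over the trailing 24 h; the 72 h
floor is the three-day rule, the spread rule is this package's criterion
(configurable).

Known limitation: with measurement noise of standard deviation σ on T_Box,
the shared noise term in `x` and `y` biases `k̂` toward 1 by approximately
`nσ²(1 − k)/Σx₀²`. Once the box has equilibrated (time constant `1/k_M`,
20 h at 0.05/h) additional samples contribute noise but no excitation, so
the bias — and eventually the RMSE — *grows* with the window length. On
noiseless data recovery is exact to floating-point precision (the estimator
inverts the generator's own update rule). A consistent alternative
(instrumental variables, or freezing accumulation once stable) is
deliberately not substituted: the through-origin form is the package's
specified estimator, and the bias is reported honestly by
`scripts/acceptance.py` (`k_M_rmse_*`).

**Temperature prediction.** Forward Euler iteration with `q = 0`, constant
supply at the average of the last `supply_window` readings (default 24), one
value per hour until arrival (`horizon = arrival_time − t`). Later queries
read a later, usually better `k̂`.

**Ripening-heat observer.** Exact algebraic inversion of the Euler step
(sample-wise equality to float precision on simulated data, for arbitrary
q(t) sequences). The published `q` is a moving average over `smoothing_window`
raw values (default 5), clipped at 0 with a logged notice; the raw value is
published alongside (`q_raw`).

**Green life.** Dose rate `r(T) = Q10^((T − T_ref)/10)` days per day;
defaults `GL0 = 28 d`, `Q10 = 3`, `T_ref = 13 °C` are configuration entries,
not measured values. Streaming accumulation adds `r(T_cur)·dt/24` per
sample (right-endpoint rule); the query-time integrator applies the *same*
rule to the predicted hourly array, so a prediction fed the measured series
reproduces the hindsight reference bit-for-bit, and dose accumulation is
additive under any split. The what-if comparison runs the temperature
prediction twice (recent supply average vs override) and reports both
green-life outcomes and their difference; overrides below the chilling floor
(default 12.5 °C) are computed but flagged, since bananas suffer chilling
injury below roughly that temperature.

## Scenario generator

The generator emulates the four chain phases with configurable conditions;
defaults (the *reference scenario*): loading at 26 °C, 6 h packing, 14-day
transport cooled to a 13.2 °C setpoint (within the typical 13.0–14.4 °C
band), 12 h harbor gap drifting toward 18 °C ambient at 0.02/h, 4 days of
ripening at q = 0.3 K/h, 1 h sampling, true k_M = 0.05/h, noise σ = 0.05 K
on both sensors. All are synthetic but physiologically plausible defaults;
none are field measurements. Supply-air noise enters the dynamics (the box
reacts to its actual supply air); box-sensor noise is measurement-only.
Life-cycle events are emitted before the sensor sample of their boundary
hour so a newly activated model's first sample is its phase's initial state.
Queries are emitted at the first sampling tick at or after their scheduled
hour and carry the estimated arrival time.

What passing tests show — and what they do not: the generator shares the
explicit-Euler form with the models, so noiseless recovery of `k_M` and `q`
is exact by construction; this validates the estimator/observer algebra and
the framework plumbing, not the thermal model's fidelity to a real
container, where airflow, respiration dynamics and sensor placement all
deviate from the first-order law. Latency numbers from the in-memory broker
characterize the harness, not a production deployment.

## Numerical and design choices

* Test and acceptance runs use desk-scale problem sizes — a single 450 h
  reference shipment, a 10-shipment × ~100-message load shape, 200-replicate
  noise studies — chosen so the whole suite runs in seconds.
* Timestamp comparisons use a 1e-9 h tolerance; gap ticks are enumerated
  strictly inside the gap.
* Query horizons round to whole hours and clamp at 0 (a query after arrival
  predicts nothing rather than failing).
* Replay determinism is byte-level: identical seeds produce identical
  JSON-encoded topic logs, end to end.
* Duplicate shipment announcements are suppressed per (shipment, model);
  re-announcing a plan is safe.
* The default banana chain is linear (CoolIdent → CoolPredict → RipeHeat →
  GreenLife): meshed model graphs are rearranged into a chain by enrichment
  order rather than executed on parallel paths, which sidesteps cross-path
  event-ordering hazards; only linear chains are supported.
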