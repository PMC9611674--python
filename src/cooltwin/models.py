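"""Banana cool-chain model suite behind the specific-wrapper contract.

Four updateable models cover the chain from ocean transport to artificial
ripening:

* **CoolIdent** — estimates the cooling-efficiency rate constant k_M (1/h)
  of the first-order thermal model
  ``dT_Box/dt = -k_M (T_Box - T_Supply) + q`` from the measured box and
  supply-air temperatures during the cooling phase.  The estimator is a
  regression through the origin on one-step temperature differences; a
  stability flag is raised once three days of data have accumulated and the
  estimate has stopped drifting.
* **CoolPredict** — forecasts the future box temperature hourly until the
  estimated arrival, taking the current T_Box as initial state and the
  supply air held constant at the average of the last known values (or a
  what-if setpoint override).
* **RipeHeat** — observes the hidden ripening heat q (expressed as a
  temperature-rise rate, K/h; the heat capacity is absorbed into q) by
  algebraically inverting the thermal model, using the k_M value carried in
  the enriched stream.
* **GreenLife** — accumulates ripening dose under a Q10 rate law
  ``r(T) = Q10**((T - T_ref)/10)`` days-at-reference per day, and predicts
  the remaining green life (days until unwanted spontaneous ripening) by
  combining the accumulated past with a predicted temperature array.

The functional forms are deliberately the simplest ones consistent with the
models' observable behavior; parameter defaults (GL0 = 28 d, Q10 = 3,
T_ref = 13 °C, smoothing window 5, chilling floor 12.5 °C) are configuration
entries, not measured values.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Mapping, NamedTuple, Optional, Sequence

from .errors import IdentifiabilityError, RangeError, StabilityError, WiringError
from .wrapper import SpecificWrapper

__all__ = [
    "ThermalParams",
    "SensorSample",
    "cool_step",
    "KmEstimator",
    "predict_temperature",
    "ripening_heat",
    "GreenLifeParams",
    "GreenLifeState",
    "green_life_rate",
    "green_life_update",
    "green_life_predict",
    "WhatIfResult",
    "what_if",
    "CoolIdentWrapper",
    "CoolPredictWrapper",
    "RipeHeatWrapper",
    "GreenLifeWrapper",
    "MODEL_TYPES",
]

log = logging.getLogger("cooltwin")


@dataclass(frozen=True)
class ThermalParams:
    """First-order thermal model parameters.

    k_M: cooling-efficiency rate constant, 1/h.
    q:   heat production expressed as a temperature-rise rate, K/h.
    """

    k_M: float
    q: float = 0.0

    def __post_init__(self) -> None:
        if self.k_M < 0 or self.q < 0:
            raise ValueError("k_M and q must be non-negative")


class SensorSample(NamedTuple):
    t: float       # hours
    T_Box: float   # °C
    T_Supply: float  # °C


def cool_step(T_Box: float, T_Supply: float, params: ThermalParams,
              dt: float) -> float:
    """One explicit-Euler update of the box temperature.

    ``T' = T + dt * (-k_M (T - T_Supply) + q)``.  Requires ``dt * k_M < 1``
    for stability of the explicit scheme; with q = 0 the update contracts
    toward the supply-air temperature.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt * params.k_M >= 1.0:
        raise StabilityError(
            f"dt*k_M = {dt * params.k_M:.3g} >= 1: explicit step unstable")
    return T_Box + dt * (-params.k_M * (T_Box - T_Supply) + params.q)


class KmEstimator:
    """Running regression-through-origin estimator for k_M.

    For each consecutive sample pair, the one-step cooling rate
    ``y = (T_prev - T_cur) / dt`` is regressed on the driving temperature
    difference ``x = T_prev - T_Supply_prev`` without intercept:
    ``k_hat = Sxy / Sxx`` with running sums ``Sxx += x²``, ``Sxy += x·y``.
    Assumes q = 0 (the cooling phase precedes ripening); ripening heat
    during estimation shows up as a positive residual bias.

    The estimate is flagged *stable* once at least ``stable_after`` hours
    (default three days) have elapsed and the relative spread of the
    estimate over the trailing ``spread_window`` hours is below
    ``spread_tol``.
    """

    def __init__(self, stable_after: float = 72.0, spread_window: float = 24.0,
                 spread_tol: float = 0.02) -> None:
        self.stable_after = stable_after
        self.spread_window = spread_window
        self.spread_tol = spread_tol
        self.n = 0
        self.Sxx = 0.0
        self.Sxy = 0.0
        self.k_hat: Optional[float] = None
        self.history: deque[tuple[float, float]] = deque()
        self.t_start: Optional[float] = None
        self.elapsed = 0.0
        self.stable = False

    def update(self, prev: SensorSample, cur: SensorSample) -> "KmEstimator":
        if cur.t <= prev.t:
            raise ValueError("samples must advance in time")
        if self.t_start is None:
            self.t_start = prev.t
        self.n += 1
        dt = cur.t - prev.t
        x = prev.T_Box - prev.T_Supply
        y = (prev.T_Box - cur.T_Box) / dt
        if x != 0.0:
            self.Sxx += x * x
            self.Sxy += x * y
            self.k_hat = self.Sxy / self.Sxx
        elif self.Sxx == 0.0 and self.n >= 24:
            raise IdentifiabilityError(
                "T_Box tracks T_Supply exactly: no thermal excitation after "
                f"{self.n} samples")
        self.elapsed = cur.t - self.t_start
        if self.k_hat is not None:
            self.history.append((cur.t, self.k_hat))
            while self.history and self.history[0][0] < cur.t - self.spread_window:
                self.history.popleft()
        self.stable = self._check_stable()
        return self

    def _check_stable(self) -> bool:
        if self.elapsed < self.stable_after or not self.history:
            return False
        ks = [k for _, k in self.history]
        mean = sum(ks) / len(ks)
        if mean == 0.0:
            return False
        return (max(ks) - min(ks)) / abs(mean) < self.spread_tol


def predict_temperature(T_now: float, T_Supply_const: float, k_hat: float,
                        horizon: int) -> list[float]:
    """Hourly forward simulation of the cooling model with constant supply.

    Element ``i`` is the predicted box temperature at hour ``i + 1`` after
    now; the series approaches the supply temperature monotonically (q = 0).
    """
    if horizon < 0:
        raise RangeError(f"horizon must be >= 0, got {horizon}")
    if k_hat < 0:
        raise ValueError(f"k_hat must be >= 0, got {k_hat}")
    params = ThermalParams(k_M=k_hat)
    out: list[float] = []
    T = T_now
    for _ in range(int(horizon)):
        T = cool_step(T, T_Supply_const, params, 1.0)
        out.append(T)
    return out


def ripening_heat(k_hat: float, prev: SensorSample, cur: SensorSample) -> float:
    """Raw ripening-heat observation by inverting the cooling model.

    ``q_hat = (T_cur - T_prev)/dt + k_hat (T_prev - T_Supply_prev)`` — the
    exact algebraic inverse of :func:`cool_step`, so on simulated data the
    raw observation reproduces the generating q(t) sample-wise.  Smoothing
    and clipping are applied by the wrapper, not here.
    """
    if cur.t <= prev.t:
        raise ValueError("samples must advance in time")
    dt = cur.t - prev.t
    return (cur.T_Box - prev.T_Box) / dt + k_hat * (prev.T_Box - prev.T_Supply)


# -- green life --------------------------------------------------------------


@dataclass(frozen=True)
class GreenLifeParams:
    """Q10 shelf-life model parameters.

    GL0:   green-life budget at the reference temperature, days.
    Q10:   rate acceleration per 10 K, dimensionless (> 1).
    T_ref: reference temperature, °C.
    """

    GL0: float = 28.0
    Q10: float = 3.0
    T_ref: float = 13.0

    def __post_init__(self) -> None:
        if self.GL0 <= 0:
            raise ValueError("GL0 must be positive")
        if self.Q10 <= 1:
            raise ValueError("Q10 must exceed 1")


@dataclass(frozen=True)
class GreenLifeState:
    """Accumulated ripening dose in days-at-reference-temperature."""

    dose: float = 0.0

    def remaining(self, p: GreenLifeParams) -> float:
        return p.GL0 - self.dose


def green_life_rate(T: float, p: GreenLifeParams) -> float:
    """Dose rate in days consumed per day: ``Q10**((T - T_ref)/10)``."""
    return p.Q10 ** ((T - p.T_ref) / 10.0)


def green_life_update(state: GreenLifeState, T: float, dt: float,
                      p: GreenLifeParams) -> GreenLifeState:
    """Advance the dose by ``dt`` hours at box temperature ``T``."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return GreenLifeState(dose=state.dose + green_life_rate(T, p) * dt / 24.0)


def green_life_predict(
    dose: float,
    future_T: Sequence[float],
    p: GreenLifeParams,
) -> tuple[float, Optional[float]]:
    """Integrate the dose over an hourly temperature forecast.

    Returns the remaining green life (days) at the end of the array and, if
    the remaining life crosses zero inside the horizon, the crossing time in
    hours from now (linear interpolation within the hour).  The integration
    rule — one hour at each array temperature — is identical to the
    streaming accumulation, so feeding the measured series reproduces the
    hindsight value exactly.
    """
    state = GreenLifeState(dose=dose)
    exhaustion: Optional[float] = None
    for i, T in enumerate(future_T):
        before = state.remaining(p)
        state = green_life_update(state, float(T), 1.0, p)
        after = state.remaining(p)
        if exhaustion is None and before > 0.0 >= after:
            frac = before / (before - after) if before != after else 1.0
            exhaustion = i + frac
    return state.remaining(p), exhaustion


@dataclass(frozen=True)
class WhatIfResult:
    baseline_remaining: float
    modified_remaining: float
    gain_days: float
    baseline_supply: float
    modified_supply: float
    chilling_warning: bool
    baseline_exhaustion: Optional[float] = None
    modified_exhaustion: Optional[float] = None


def what_if(
    k_hat: float,
    T_now: float,
    baseline_supply: float,
    override_supply: float,
    dose: float,
    horizon: int,
    p: GreenLifeParams,
    chilling_floor: float = 12.5,
) -> WhatIfResult:
    """Compare green-life outcomes of keeping vs changing the setpoint.

    Runs the temperature prediction twice — supply held at the recent
    average vs at the override — and feeds both into the green-life
    integrator.  An override below the chilling floor flags a
    chilling-injury warning but the computation is still performed.
    """
    base_T = predict_temperature(T_now, baseline_supply, k_hat, horizon)
    mod_T = predict_temperature(T_now, override_supply, k_hat, horizon)
    base_rem, base_x = green_life_predict(dose, base_T, p)
    mod_rem, mod_x = green_life_predict(dose, mod_T, p)
    warn = override_supply < chilling_floor
    if warn:
        log.warning("what-if setpoint %.2f below chilling floor %.2f",
                    override_supply, chilling_floor)
    return WhatIfResult(
        baseline_remaining=base_rem,
        modified_remaining=mod_rem,
        gain_days=mod_rem - base_rem,
        baseline_supply=baseline_supply,
        modified_supply=override_supply,
        chilling_warning=warn,
        baseline_exhaustion=base_x,
        modified_exhaustion=mod_x,
    )


# -- specific wrappers --------------------------------------------------------


def _sample_from(payload: Mapping[str, Any], t: float) -> SensorSample:
    return SensorSample(t=t, T_Box=float(payload["T_Box"]),
                        T_Supply=float(payload["T_Supply"]))


class CoolIdentWrapper(SpecificWrapper):
    """Streaming k_M identification during the cooling phase."""

    model_name = "CoolIdent"
    required_fields = ("T_Box", "T_Supply")

    def __init__(self, params: Optional[Mapping[str, Any]] = None) -> None:
        p = dict(params or {})
        self.estimator = KmEstimator(
            stable_after=float(p.get("stable_after", 72.0)),
            spread_window=float(p.get("spread_window", 24.0)),
            spread_tol=float(p.get("spread_tol", 0.02)),
        )
        self._clock = 0.0
        self._prev: Optional[SensorSample] = None

    def step(self, payload: Mapping[str, Any], dt: float) -> Optional[dict]:
        if any(f not in payload for f in self.required_fields):
            return None
        self._clock += dt
        cur = _sample_from(payload, self._clock)
        if self._prev is not None:
            self.estimator.update(self._prev, cur)
        self._prev = cur
        if self.estimator.k_hat is None:
            return None  # output postponed until enough samples
        return {
            "k_M": self.estimator.k_hat,
            "stable": self.estimator.stable,
            "n": self.estimator.n,
        }


class CoolPredictWrapper(SpecificWrapper):
    """Hourly box-temperature forecast until arrival, on operator query.

    Tracks the most recent k_M from the enriched stream and a trailing
    window of supply-air readings; the forecast holds the supply at the
    window average, or at a what-if override.
    """

    model_name = "CoolPredict"
    required_fields = ("T_Box", "T_Supply")

    def __init__(self, params: Optional[Mapping[str, Any]] = None) -> None:
        p = dict(params or {})
        self.supply_window: deque[float] = deque(
            maxlen=int(p.get("supply_window", 24)))
        self.chilling_floor = float(p.get("chilling_floor", 12.5))
        self.k_hat: Optional[float] = None
        self.T_now: Optional[float] = None

    def step(self, payload: Mapping[str, Any], dt: float) -> Optional[dict]:
        if "T_Supply" in payload:
            self.supply_window.append(float(payload["T_Supply"]))
        if "T_Box" in payload:
            self.T_now = float(payload["T_Box"])
        if "CoolIdent.k_M" in payload:
            self.k_hat = float(payload["CoolIdent.k_M"])
        return None  # enriches only on query

    def predict(self, payload: Mapping[str, Any], horizon: int,
                overrides: Mapping[str, Any]) -> Optional[dict]:
        if self.k_hat is None or self.T_now is None or not self.supply_window:
            return {"error": "prediction unavailable: k_M or samples missing"}
        supply_avg = sum(self.supply_window) / len(self.supply_window)
        result: dict[str, Any] = {
            "prediction": predict_temperature(self.T_now, supply_avg,
                                              self.k_hat, horizon),
            "T_supply_assumed": supply_avg,
            "k_M_used": self.k_hat,
            "horizon": horizon,
        }
        if "query_id" in payload:
            result["query_id"] = payload["query_id"]
        if overrides:
            if "setpoint" in overrides:
                supply_mod = float(overrides["setpoint"])
            else:
                supply_mod = supply_avg + float(overrides["setpoint_delta"])
            result["prediction_whatif"] = predict_temperature(
                self.T_now, supply_mod, self.k_hat, horizon)
            result["T_supply_whatif"] = supply_mod
            result["chilling_warning"] = supply_mod < self.chilling_floor
            if supply_mod < self.chilling_floor:
                log.warning("query override %.2f below chilling floor %.2f",
                            supply_mod, self.chilling_floor)
        return result


class RipeHeatWrapper(SpecificWrapper):
    """Ripening-heat observer, active during the ripening phase.

    Collects the latest k_M estimate from the enriched stream during
    transport; once active, inverts the cooling model per sample and reports
    a centered moving average (negative smoothed values are clipped to 0
    with a logged notice).  The raw per-sample observation is reported too.
    """

    model_name = "RipeHeat"
    required_fields = ("T_Box", "T_Supply")

    def __init__(self, params: Optional[Mapping[str, Any]] = None) -> None:
        p = dict(params or {})
        self.window = int(p.get("smoothing_window", 5))
        self.k_hat: Optional[float] = None
        self._clock = 0.0
        self._prev: Optional[SensorSample] = None
        self._raw: deque[float] = deque(maxlen=self.window)

    def collect(self, payload: Mapping[str, Any]) -> None:
        if "CoolIdent.k_M" in payload:
            self.k_hat = float(payload["CoolIdent.k_M"])

    def step(self, payload: Mapping[str, Any], dt: float) -> Optional[dict]:
        if "CoolIdent.k_M" in payload:  # live value wins over collected one
            self.k_hat = float(payload["CoolIdent.k_M"])
        if self.k_hat is None:
            raise WiringError(
                "RipeHeat has no k_M: announce CoolIdent before RipeHeat "
                "in the chain")
        if any(f not in payload for f in self.required_fields):
            return None
        self._clock += dt
        cur = _sample_from(payload, self._clock)
        if self._prev is None:
            self._prev = cur
            return None
        q_raw = ripening_heat(self.k_hat, self._prev, cur)
        self._prev = cur
        self._raw.append(q_raw)
        result: dict[str, Any] = {"q_raw": q_raw, "k_M_used": self.k_hat}
        if len(self._raw) == self.window:
            smoothed = sum(self._raw) / self.window
            if smoothed < 0.0:
                log.info("smoothed ripening heat %.4g clipped to 0", smoothed)
                smoothed = 0.0
            result["q"] = smoothed
        return result


class GreenLifeWrapper(SpecificWrapper):
    """Streaming green-life accounting and query-time prediction."""

    model_name = "GreenLife"
    required_fields = ("T_Box",)

    def __init__(self, params: Optional[Mapping[str, Any]] = None) -> None:
        p = dict(params or {})
        self.params = GreenLifeParams(
            GL0=float(p.get("GL0", 28.0)),
            Q10=float(p.get("Q10", 3.0)),
            T_ref=float(p.get("T_ref", 13.0)),
        )
        self.state = GreenLifeState()
        self._first = True

    def step(self, payload: Mapping[str, Any], dt: float) -> Optional[dict]:
        if "T_Box" not in payload:
            return None
        if self._first:
            # first sample anchors the clock; the dose integral starts with
            # the first full interval, matching the hindsight reference
            self._first = False
        else:
            self.state = green_life_update(self.state, float(payload["T_Box"]),
                                           dt, self.params)
        remaining = self.state.remaining(self.params)
        result = {"remaining": remaining, "dose": self.state.dose}
        if remaining < 0.0:
            result["exhausted"] = True
        return result

    def predict(self, payload: Mapping[str, Any], horizon: int,
                overrides: Mapping[str, Any]) -> Optional[dict]:
        future = payload.get("CoolPredict.prediction")
        if future is None:
            return None  # nothing to combine with; forward the query
        remaining, exhaustion = green_life_predict(self.state.dose, future,
                                                   self.params)
        result: dict[str, Any] = {
            "remaining_now": self.state.remaining(self.params),
            "prediction": remaining,
        }
        if "query_id" in payload:
            result["query_id"] = payload["query_id"]
        if exhaustion is not None:
            result["exhaustion_in_hours"] = exhaustion
        whatif = payload.get("CoolPredict.prediction_whatif")
        if whatif is not None:
            rem_w, ex_w = green_life_predict(self.state.dose, whatif,
                                             self.params)
            result["prediction_whatif"] = rem_w
            result["gain_days"] = rem_w - remaining
            if ex_w is not None:
                result["exhaustion_whatif_in_hours"] = ex_w
        return result


#: Registry mapping config model names to wrapper classes.
MODEL_TYPES: dict[str, type[SpecificWrapper]] = {
    "CoolIdent": CoolIdentWrapper,
    "CoolPredict": CoolPredictWrapper,
    "RipeHeat": RipeHeatWrapper,
    "GreenLife": GreenLifeWrapper,
}
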