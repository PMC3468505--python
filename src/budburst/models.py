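"""The five temperature-driven budburst models.

Every model accumulates daily rates into states and declares budburst when
the state of forcing ``Sf`` first reaches a forcing requirement ``F*``:

* **TTM** (Thermal Time): growing-degree-day forcing ``max(0, T - Tb)``
  accumulated from a fitted start day ``t1f``; no chilling.
* **SM** (Sequential): triangular chilling accumulated from 1 September;
  sigmoid forcing starts on the first day the state of chilling ``Sc``
  reaches the chilling requirement ``C*`` (that day inclusive).
* **PM** (Parallel): chilling and forcing accumulate in parallel from
  1 September, with the forcing rate scaled by a competence function
  ``Kf(Sc) = Km + (1 - Km) * min(Sc / C*, 1)``.
* **AM** (Alternating): chill days (mean temperature strictly below ``Tc``)
  counted from 1 November; degree-day forcing from 1 January; budburst on
  the first day ``Sf >= a + b * exp(c * Sc)`` with the requirement
  re-evaluated daily against the running chill-day count.
* **UM** (Unified): one sigmoid chilling rate from 1 September and one
  sigmoid forcing rate gated by ``C*``, with
  ``F* = w * exp(k * Sc(t2c))`` fixed by the chilling accumulated up to
  day ``t2c``.

Forcing sigmoids are written with a leading minus in the exponent and
positive slope parameters, so they are increasing in temperature by
construction (equivalent to the historical negative-parameter forms up to
reparameterization).

Each model has a vectorized day loop and a plain day-by-day reference loop
(`predict_budburst_reference`) retained as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .climate import JAN1, JUN30, NOV1, SEP1, DailyTemperatureSeries
from .errors import ParameterError, RangeError

__all__ = [
    "ModelSpec", "ModelState", "BudburstPrediction", "MODEL_SPECS", "MODEL_IDS",
    "get_model_spec", "default_bounds",
    "rate_forcing_linear", "rate_chilling_triangular", "rate_forcing_sigmoid",
    "rate_chilling_chill_day", "forcing_requirement_am",
    "rate_chilling_unified", "rate_forcing_unified", "forcing_requirement_um",
    "predict_budburst", "predict_budburst_reference",
]

_EXP_CLAMP = 700.0  # exp argument beyond this overflows float64


# ---------------------------------------------------------------------------
# Daily rate and threshold functions
# ---------------------------------------------------------------------------

def rate_forcing_linear(T, Tb):
    """Growing-degree-day forcing rate: ``max(0, T - Tb)`` (FU/day)."""
    return np.maximum(0.0, np.asarray(T, dtype=float) - Tb)


def rate_chilling_triangular(T, Tmin, Topt, Tmax):
    """Triangular chilling rate: 0 at/outside (Tmin, Tmax), peak 1 at Topt."""
    if not (Tmin < Topt < Tmax):
        raise ParameterError(
            f"require Tmin < Topt < Tmax, got ({Tmin}, {Topt}, {Tmax})"
        )
    T = np.asarray(T, dtype=float)
    up = (T - Tmin) / (Topt - Tmin)
    down = (Tmax - T) / (Tmax - Topt)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def rate_forcing_sigmoid(T, a, b, c):
    """Sigmoid forcing rate ``c / (1 + exp(-a (T - b)))`` (FU/day).

    Increasing in T for a > 0; asymptote c; value c/2 at T = b.
    """
    T = np.asarray(T, dtype=float)
    expo = np.clip(-a * (T - b), -_EXP_CLAMP, _EXP_CLAMP)
    return c / (1.0 + np.exp(expo))


def rate_chilling_chill_day(T, Tc):
    """Chill-day chilling rate: 1 if the mean temperature is strictly below Tc."""
    return np.where(np.asarray(T, dtype=float) < Tc, 1.0, 0.0)


def forcing_requirement_am(Sc, a, b, c):
    """Alternating-model forcing requirement ``a + b * exp(c * Sc)``, c < 0."""
    return a + b * np.exp(np.clip(c * np.asarray(Sc, dtype=float),
                                  -_EXP_CLAMP, _EXP_CLAMP))


def rate_chilling_unified(T, Ca, Cb, Cc):
    """Unified chilling rate ``1 / (1 + exp(Ca (T-Cc)^2 + Cb (T-Cc)))``."""
    d = np.asarray(T, dtype=float) - Cc
    expo = np.clip(Ca * d * d + Cb * d, -_EXP_CLAMP, _EXP_CLAMP)
    return 1.0 / (1.0 + np.exp(expo))


def rate_forcing_unified(T, Fb, Fc):
    """Unified forcing rate ``1 / (1 + exp(-Fb (T - Fc)))``, increasing in T."""
    expo = np.clip(-Fb * (np.asarray(T, dtype=float) - Fc), -_EXP_CLAMP, _EXP_CLAMP)
    return 1.0 / (1.0 + np.exp(expo))


def forcing_requirement_um(Sc_total, w, k):
    """Unified-model forcing requirement ``w * exp(k * Sc_total)``, k <= 0."""
    return w * np.exp(np.clip(k * np.asarray(Sc_total, dtype=float),
                              -_EXP_CLAMP, _EXP_CLAMP))


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Identity, parameterization and fixed calendar anchors of one model.

    ``n_params`` is the conventional parameter count of the model (used in
    AIC); it can exceed ``len(parameter_names)`` where a nominal parameter is
    fixed by convention (AM's start days) or has no independent role (the
    final chilling day of AM, which coincides with budburst).
    """

    model_id: str
    parameter_names: tuple
    bounds: Mapping[str, tuple]
    fixed_days: Mapping[str, int]
    n_params: int
    description: str = ""

    @property
    def day_valued(self) -> frozenset:
        """Parameters that are day indices (proposed continuously, rounded)."""
        return frozenset(n for n in self.parameter_names if n in ("t1f", "t2c"))

    def validate(self, params: Mapping[str, float]) -> None:
        missing = [n for n in self.parameter_names if n not in params]
        if missing:
            raise ParameterError(f"{self.model_id}: missing parameters {missing}")
        for name in self.parameter_names:
            lo, hi = self.bounds[name]
            v = params[name]
            if not np.isfinite(v) or not (lo <= v <= hi):
                raise ParameterError(
                    f"{self.model_id}: {name}={v} outside bounds [{lo}, {hi}]"
                )
        if {"Tmin", "Topt", "Tmax"} <= set(self.parameter_names):
            if not (params["Tmin"] < params["Topt"] < params["Tmax"]):
                raise ParameterError(
                    f"{self.model_id}: require Tmin < Topt < Tmax"
                )

    def as_array(self, params: Mapping[str, float]) -> np.ndarray:
        return np.array([params[n] for n in self.parameter_names], dtype=float)

    def as_dict(self, values: Sequence[float]) -> dict:
        return {n: float(v) for n, v in zip(self.parameter_names, values)}


# Default flat-prior boxes for calibration.  The ordering Tmin < Topt < Tmax
# is made automatic by keeping the three boxes disjoint.
_B = {
    "TTM": {"t1f": (NOV1, 203.0), "Tb": (-5.0, 15.0), "Fstar": (1e-6, 500.0)},
    "SM": {
        "Tmin": (-70.0, -0.5), "Topt": (-15.0, 8.0), "Tmax": (8.5, 40.0),
        "a": (0.01, 2.0), "b": (-5.0, 25.0), "c": (0.05, 3.0),
        "Cstar": (1e-6, 200.0), "Fstar": (1e-6, 500.0),
    },
    "AM": {
        "Tb": (-5.0, 15.0), "Tc": (-5.0, 15.0),
        "a": (0.0, 300.0), "b": (1e-6, 3000.0), "c": (-1.0, -1e-4),
    },
    "UM": {
        "Ca": (0.0, 1.0), "Cb": (-2.0, 2.0), "Cc": (-5.0, 15.0),
        "Fb": (0.01, 2.0), "Fc": (-5.0, 25.0),
        "Cstar": (1e-6, 200.0), "k": (-0.2, 0.0), "w": (1e-6, 500.0),
        "t2c": (float(JAN1 - 30), 243.0),
    },
}
_B["PM"] = {**_B["SM"], "Km": (0.0, 1.0)}

MODEL_SPECS: dict = {
    "TTM": ModelSpec(
        "TTM", ("t1f", "Tb", "Fstar"), _B["TTM"], {}, 3,
        "Thermal Time model: degree-day forcing from a fitted start day",
    ),
    "SM": ModelSpec(
        "SM",
        ("Tmin", "Topt", "Tmax", "a", "b", "c", "Cstar", "Fstar"),
        _B["SM"], {"t1c": SEP1}, 8,
        "Sequential model: triangular chilling gates sigmoid forcing",
    ),
    "PM": ModelSpec(
        "PM",
        ("Tmin", "Topt", "Tmax", "a", "b", "c", "Cstar", "Fstar", "Km"),
        _B["PM"], {"t1c": SEP1}, 9,
        "Parallel model: competence-scaled forcing alongside chilling",
    ),
    "AM": ModelSpec(
        "AM", ("Tb", "Tc", "a", "b", "c"), _B["AM"],
        {"t1f": JAN1, "t1c": NOV1}, 8,
        "Alternating model: chill days lower an exponential forcing requirement",
    ),
    "UM": ModelSpec(
        "UM",
        ("Ca", "Cb", "Cc", "Fb", "Fc", "Cstar", "k", "w", "t2c"),
        _B["UM"], {"t1c": SEP1}, 9,
        "Unified model: sigmoid chilling and forcing with exponential F*",
    ),
}
MODEL_IDS = tuple(MODEL_SPECS)


def get_model_spec(model_id: str) -> ModelSpec:
    try:
        return MODEL_SPECS[model_id.upper()]
    except KeyError:
        raise ParameterError(
            f"unknown model {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


def default_bounds(model_id: str) -> dict:
    """Shipped flat-prior bounds for a model (copy; safe to modify)."""
    return {k: tuple(v) for k, v in get_model_spec(model_id).bounds.items()}


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelState:
    """Per-day rate and state trajectories from a model run."""

    start_index: int
    rc: np.ndarray
    rf: np.ndarray
    sc: np.ndarray
    sf: np.ndarray


@dataclass(frozen=True)
class BudburstPrediction:
    """Outcome of one model run: the budburst day index, or None."""

    day: Optional[int]
    sc_final: float
    sf_final: float
    threshold: float
    state: Optional[ModelState] = None

    @property
    def doy(self) -> Optional[int]:
        from .climate import index_to_doy

        return None if self.day is None else index_to_doy(self.day)


def _first_reach(cum: np.ndarray, threshold: float) -> int:
    """Index of the first element of a non-decreasing array >= threshold.

    Returns len(cum) when the threshold is never reached.
    """
    return int(np.searchsorted(cum, threshold, side="left"))


def _check_series(series: DailyTemperatureSeries, first_day: int, horizon: int):
    if horizon <= first_day:
        raise RangeError(f"horizon {horizon} not after model start {first_day}")
    if not series.covers(first_day, horizon):
        raise RangeError(
            f"series [{series.start_index}, {series.end_index}] does not cover "
            f"model window [{first_day}, {horizon}]"
        )


def predict_budburst(spec: ModelSpec, params: Mapping[str, float],
                     series: DailyTemperatureSeries, horizon: int = JUN30,
                     validate: bool = True,
                     return_state: bool = False) -> BudburstPrediction:
    """Run a model day loop over the series and locate the budburst day.

    The first day of each accumulation window contributes its full daily
    rate, and forcing begins on the same day the chilling requirement is
    first met.  Returns a prediction with ``day=None`` when the forcing
    requirement is not reached by ``horizon`` (30 June by default).
    """
    if validate:
        spec.validate(params)
    p = params
    mid = spec.model_id

    if mid == "TTM":
        t1f = int(round(p["t1f"]))
        _check_series(series, t1f, horizon)
        T = series.window(t1f, horizon)
        rc = np.zeros_like(T)
        rf = rate_forcing_linear(T, p["Tb"])
        sf = np.cumsum(rf)
        i = _first_reach(sf, p["Fstar"])
        day = t1f + i if i < sf.size else None
        start, sc, thr = t1f, np.zeros_like(sf), p["Fstar"]

    elif mid in ("SM", "PM"):
        start = series.start_index
        _check_series(series, start, horizon)
        T = series.window(start, horizon)
        rc = rate_chilling_triangular(T, p["Tmin"], p["Topt"], p["Tmax"])
        sc = np.cumsum(rc)
        raw_rf = rate_forcing_sigmoid(T, p["a"], p["b"], p["c"])
        if mid == "SM":
            j = _first_reach(sc, p["Cstar"])
            rf = np.zeros_like(T)
            sf = np.zeros_like(T)
            if j < T.size:
                rf[j:] = raw_rf[j:]
                sf[j:] = np.cumsum(raw_rf[j:])
                i = _first_reach(sf[j:], p["Fstar"])
                day = start + j + i if i < T.size - j else None
            else:
                day = None
        else:  # PM: competence rises linearly in Sc and saturates at C*
            kf = p["Km"] + (1.0 - p["Km"]) * np.minimum(sc / p["Cstar"], 1.0)
            rf = kf * raw_rf
            sf = np.cumsum(rf)
            i = _first_reach(sf, p["Fstar"])
            day = start + i if i < sf.size else None
        thr = p["Fstar"]

    elif mid == "AM":
        t1c, t1f = spec.fixed_days["t1c"], spec.fixed_days["t1f"]
        _check_series(series, t1c, horizon)
        Tc_win = series.window(t1c, horizon)
        rc = rate_chilling_chill_day(Tc_win, p["Tc"])
        sc = np.cumsum(rc)
        Tf_win = series.window(t1f, horizon)
        rf = rate_forcing_linear(Tf_win, p["Tb"])
        sf = np.cumsum(rf)
        # requirement re-evaluated daily against the running chill-day count
        fstar = forcing_requirement_am(sc[t1f - t1c :], p["a"], p["b"], p["c"])
        hit = np.flatnonzero(sf >= fstar)
        day = t1f + int(hit[0]) if hit.size else None
        start = t1c
        thr = float(fstar[hit[0]]) if hit.size else float(fstar[-1])

    elif mid == "UM":
        start = series.start_index
        t2c = int(round(np.clip(p["t2c"], start + 1, horizon)))
        _check_series(series, start, horizon)
        T = series.window(start, horizon)
        rc = rate_chilling_unified(T, p["Ca"], p["Cb"], p["Cc"])
        sc = np.cumsum(rc)
        thr = float(forcing_requirement_um(sc[t2c - start], p["w"], p["k"]))
        j = _first_reach(sc, p["Cstar"])
        rf = np.zeros_like(T)
        sf = np.zeros_like(T)
        if j < T.size:
            raw_rf = rate_forcing_unified(T[j:], p["Fb"], p["Fc"])
            rf[j:] = raw_rf
            sf[j:] = np.cumsum(raw_rf)
            i = _first_reach(sf[j:], thr)
            day = start + j + i if i < T.size - j else None
        else:
            day = None

    else:  # pragma: no cover
        raise ParameterError(f"unknown model id {mid}")

    state = ModelState(start, rc, rf, sc, sf) if return_state else None
    return BudburstPrediction(
        day=day,
        sc_final=float(sc[-1]) if sc.size else 0.0,
        sf_final=float(sf[-1]) if sf.size else 0.0,
        threshold=float(thr),
        state=state,
    )


# ---------------------------------------------------------------------------
# Reference day-by-day loop (independent oracle for the vectorized path)
# ---------------------------------------------------------------------------

def predict_budburst_reference(spec: ModelSpec, params: Mapping[str, float],
                               series: DailyTemperatureSeries,
                               horizon: int = JUN30) -> Optional[int]:
    """Plain scalar day loop; returns the budburst day index or None.

    Kept deliberately naive (one day at a time, explicit state updates) as
    the oracle against which the vectorized `predict_budburst` is tested.
    """
    spec.validate(params)
    p = dict(params)
    mid = spec.model_id

    if mid == "TTM":
        t1f = int(round(p["t1f"]))
        _check_series(series, t1f, horizon)
        sf = 0.0
        for d in range(t1f, horizon + 1):
            sf += float(rate_forcing_linear(series.value(d), p["Tb"]))
            if sf >= p["Fstar"]:
                return d
        return None

    if mid == "SM":
        start = series.start_index
        _check_series(series, start, horizon)
        sc, sf, forcing = 0.0, 0.0, False
        for d in range(start, horizon + 1):
            T = series.value(d)
            sc += float(rate_chilling_triangular(T, p["Tmin"], p["Topt"], p["Tmax"]))
            if not forcing and sc >= p["Cstar"]:
                forcing = True  # forcing starts this same day
            if forcing:
                sf += float(rate_forcing_sigmoid(T, p["a"], p["b"], p["c"]))
                if sf >= p["Fstar"]:
                    return d
        return None

    if mid == "PM":
        start = series.start_index
        _check_series(series, start, horizon)
        sc, sf = 0.0, 0.0
        for d in range(start, horizon + 1):
            T = series.value(d)
            sc += float(rate_chilling_triangular(T, p["Tmin"], p["Topt"], p["Tmax"]))
            kf = p["Km"] + (1.0 - p["Km"]) * min(sc / p["Cstar"], 1.0)
            sf += kf * float(rate_forcing_sigmoid(T, p["a"], p["b"], p["c"]))
            if sf >= p["Fstar"]:
                return d
        return None

    if mid == "AM":
        t1c, t1f = spec.fixed_days["t1c"], spec.fixed_days["t1f"]
        _check_series(series, t1c, horizon)
        sc = 0.0
        for d in range(t1c, t1f):
            sc += float(rate_chilling_chill_day(series.value(d), p["Tc"]))
        sf = 0.0
        for d in range(t1f, horizon + 1):
            sc += float(rate_chilling_chill_day(series.value(d), p["Tc"]))
            sf += float(rate_forcing_linear(series.value(d), p["Tb"]))
            if sf >= float(forcing_requirement_am(sc, p["a"], p["b"], p["c"])):
                return d
        return None

    if mid == "UM":
        start = series.start_index
        t2c = int(round(np.clip(p["t2c"], start + 1, horizon)))
        _check_series(series, start, horizon)
        sc = 0.0
        sc_by_day = {}
        for d in range(start, horizon + 1):
            sc += float(rate_chilling_unified(series.value(d), p["Ca"], p["Cb"], p["Cc"]))
            sc_by_day[d] = sc
        fstar = float(forcing_requirement_um(sc_by_day[t2c], p["w"], p["k"]))
        sc, sf, forcing = 0.0, 0.0, False
        for d in range(start, horizon + 1):
            T = series.value(d)
            sc += float(rate_chilling_unified(T, p["Ca"], p["Cb"], p["Cc"]))
            if not forcing and sc >= p["Cstar"]:
                forcing = True
            if forcing:
                sf += float(rate_forcing_unified(T, p["Fb"], p["Fc"]))
                if sf >= fstar:
                    return d
        return None

    raise ParameterError(f"unknown model id {mid}")  # pragma: no cover
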