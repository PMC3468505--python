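"""Goodness of fit, information criteria, cross-validation and sensitivity.

Metrics follow the standard phenology-model comparison toolkit:

* ``RMSE`` (days) — root mean square error of predicted budburst dates;
* ``ME`` — model efficiency (Nash-Sutcliffe), 1 minus the ratio of residual
  to total sum of squares: 1 is perfect, 0 no better than the observed mean;
* ``AIC = t ln(rss / t) + 2 (n_params + 1)`` with ``t`` observations and the
  conventional parameter count of the model, computed on whole-dataset fits.

Predictions that never reach the forcing requirement are scored as the
horizon day (30 June) and flagged, so scores stay finite while heavily
penalizing chilling-failure misfits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import MCMCConfig, best_fit, metropolis_hastings
from .climate import DEC1, JUN30, DailyTemperatureSeries, mean_warming_delta
from .errors import PerfectFitError, ValidationError
from .models import ModelSpec, predict_budburst

__all__ = [
    "rmse", "model_efficiency", "aic", "pearson_r", "split_dataset",
    "predict_observations", "score_predictions", "cross_validate",
    "SensitivityResult", "sensitivity_slope",
]


def _as_arrays(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValidationError("observed and predicted must be equal-length, non-empty")
    if np.isnan(pred).any():
        raise ValidationError(
            "predictions contain missing values; replace unreached predictions "
            "with the horizon day before scoring"
        )
    return obs, pred


def rmse(observed, predicted) -> float:
    """Root mean square error (days)."""
    obs, pred = _as_arrays(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def model_efficiency(observed, predicted) -> float:
    """Nash-Sutcliffe model efficiency; undefined for constant observations."""
    obs, pred = _as_arrays(observed, predicted)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValidationError("model efficiency undefined: observations have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / tss


def aic(rss: float, t: int, n_params: int) -> float:
    """Akaike information criterion ``t ln(rss/t) + 2 (n_params + 1)``."""
    if rss < 0:
        raise ValidationError("rss must be non-negative")
    if rss == 0:
        raise PerfectFitError("AIC undefined for a perfect fit (rss = 0)")
    if t <= n_params + 1:
        raise ValidationError(f"need t > n_params + 1 (t={t}, n_params={n_params})")
    return t * math.log(rss / t) + 2.0 * (n_params + 1)


def pearson_r(observed, predicted) -> float:
    obs, pred = _as_arrays(observed, predicted)
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def split_dataset(observations, fraction: float = 0.5, seed: int = 0):
    """Random split into (train, test), stratified by treatment.

    Every treatment with at least two saplings appears in both halves;
    singleton treatments go to the training half.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    frame = observations.frame
    train_idx, test_idx = [], []
    for _, sub in frame.groupby(["species", "treatment"], sort=True):
        idx = sub.index.to_numpy()
        if idx.size == 1:
            train_idx.extend(idx)
            continue
        perm = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return observations.subset(sorted(train_idx)), observations.subset(sorted(test_idx))


def predict_observations(spec: ModelSpec, params: Mapping[str, float],
                         observations, series_by_treatment,
                         horizon: int = JUN30) -> pd.DataFrame:
    """Per-observation predictions; unreached predictions scored as horizon.

    Returns the observation frame with ``predicted_index`` and an
    ``unreached`` flag column added.
    """
    preds, flags = {}, {}
    for tr in observations.treatments:
        day = predict_budburst(spec, params, series_by_treatment[tr],
                               horizon=horizon).day
        flags[tr] = day is None
        preds[tr] = horizon if day is None else day
    out = observations.frame.copy()
    out["predicted_index"] = out["treatment"].map(preds)
    out["unreached"] = out["treatment"].map(flags)
    return out


def score_predictions(frame: pd.DataFrame) -> dict:
    """RMSE, ME, Pearson r and rss from a predict_observations frame."""
    obs = frame["budburst_index"].to_numpy(dtype=float)
    pred = frame["predicted_index"].to_numpy(dtype=float)
    return {
        "rmse": rmse(obs, pred),
        "me": model_efficiency(obs, pred),
        "pearson_r": pearson_r(obs, pred),
        "rss": float(np.sum((obs - pred) ** 2)),
        "n": int(obs.size),
        "n_unreached": int(frame["unreached"].sum()),
    }


def cross_validate(spec: ModelSpec, observations, series_by_treatment,
                   mode: str = "internal",
                   config: MCMCConfig = MCMCConfig(),
                   split_fraction: float = 0.5,
                   horizon: int = JUN30) -> dict:
    """Calibrate and score one model for one species.

    ``internal``: calibrate and score on the full set. ``external``:
    calibrate on a stratified random half, score on the held-out half.
    Returns a report row with RMSE, ME, Pearson r, rss, t and n_unreached.
    """
    if mode not in ("internal", "external"):
        raise ValidationError(f"mode must be 'internal' or 'external', got {mode!r}")
    if mode == "internal":
        fit_obs, eval_obs = observations, observations
    else:
        fit_obs, eval_obs = split_dataset(observations, split_fraction,
                                          seed=config.seed)
    chain = metropolis_hastings(spec, fit_obs, series_by_treatment,
                                config=config, horizon=horizon)
    params = best_fit(chain)
    frame = predict_observations(spec, params, eval_obs, series_by_treatment,
                                 horizon=horizon)
    row = score_predictions(frame)
    row.update({
        "model": spec.model_id,
        "mode": mode,
        "best_fit": params,
        "acceptance_rate": chain.acceptance_rate,
    })
    return row


@dataclass(frozen=True)
class SensitivityResult:
    """Warming sensitivity of one species: advancement vs mean warming."""

    species: str
    slope: float                 # days per deg C (negative = advancement)
    intercept: float
    per_treatment: pd.DataFrame  # treatment, delta_t, advancement_days
    control_label: str = "W0S0"

    def __post_init__(self):
        ctrl = self.per_treatment[self.per_treatment["treatment"] == self.control_label]
        if len(ctrl) and not (np.allclose(ctrl["delta_t"], 0.0)
                              and np.allclose(ctrl["advancement_days"], 0.0)):
            raise ValidationError(
                "control delta_t and advancement must be zero by construction"
            )


def sensitivity_slope(observations, delta_t_by_treatment: Mapping[str, float],
                      control_label: str = "W0S0") -> dict:
    """Per-species least-squares slope of budburst advancement on warming.

    Advancement is the treatment mean budburst day minus the control mean
    (days; negative = earlier); the regressor is the supplied mean warming
    delta per treatment (deg C).  Fitted unweighted through treatment means.
    """
    results = {}
    for species in observations.species:
        sub = observations.for_species(species)
        means = sub.mean_budburst()
        if control_label not in means.index:
            raise ValidationError(f"{species}: control {control_label!r} missing")
        rows = []
        for tr, mean_bb in means.items():
            if tr not in delta_t_by_treatment:
                raise ValidationError(f"{species}: no delta_t for treatment {tr!r}")
            dt = 0.0 if tr == control_label else float(delta_t_by_treatment[tr])
            adv = 0.0 if tr == control_label else float(mean_bb - means[control_label])
            rows.append({"treatment": tr, "delta_t": dt, "advancement_days": adv})
        table = pd.DataFrame(rows)
        if table["delta_t"].nunique() < 2:
            raise ValidationError(f"{species}: need >= 2 distinct delta_t values")
        slope, intercept = np.polyfit(table["delta_t"], table["advancement_days"], 1)
        results[species] = SensitivityResult(species, float(slope),
                                             float(intercept), table,
                                             control_label)
    return results
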