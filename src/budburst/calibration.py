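"""Bayesian calibration of budburst models by random-walk Metropolis-Hastings.

Priors are flat (uniform) inside per-parameter bounds and zero outside, so
the acceptance probability reduces to a likelihood ratio.  The residual
standard deviation of observed budburst dates, ``sigma`` (days), is not
stated by any model and is calibrated alongside the model parameters as a
nuisance parameter with a flat prior on (0.1, 20] days, unless the config
fixes it.

Proposal scales default to 5% of each prior range and, when ``adapt`` is on,
are rescaled during burn-in (only) toward a 20-50% acceptance rate; the
post-burn-in kernel is therefore fixed and a valid MH transition.
Day-valued parameters (t1f, t2c) are proposed on a continuous support and
rounded only inside the model evaluation, which keeps the walk connected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .climate import JUN30, DailyTemperatureSeries
from .errors import InitializationError, ValidationError
from .models import ModelSpec, predict_budburst

__all__ = [
    "MCMCConfig", "CalibrationChain", "log_likelihood",
    "random_walk_metropolis", "metropolis_hastings", "best_fit",
    "predicted_days_by_treatment",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

SIGMA_BOUNDS = (0.1, 20.0)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length, proposal scales and adaptation settings."""

    n_iterations: int = 50_000
    burn_in: int = 10_000
    proposal_scales: Optional[Mapping[str, float]] = None
    seed: int = 0
    adapt: bool = True
    adapt_interval: int = 200
    target_acceptance: tuple = (0.2, 0.5)
    sigma_fixed: Optional[float] = None
    n_init_draws: int = 100

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValidationError("require 0 <= burn_in < n_iterations")
        if self.sigma_fixed is not None and self.sigma_fixed <= 0:
            raise ValidationError("sigma_fixed must be > 0")


@dataclass(frozen=True)
class CalibrationChain:
    """Post-burn-in samples of one MH run."""

    parameter_names: tuple
    samples: np.ndarray          # (n_kept, n_params)
    log_likelihoods: np.ndarray  # (n_kept,)
    acceptance_rate: float
    seed: int

    def __post_init__(self):
        if self.samples.ndim != 2 or self.samples.shape[0] == 0:
            raise ValidationError("chain must contain at least one sample")
        if self.samples.shape[0] != self.log_likelihoods.size:
            raise ValidationError("samples and log_likelihoods length mismatch")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def best_index(self) -> int:
        """Earliest sample attaining the maximum stored log-likelihood."""
        return int(np.argmax(self.log_likelihoods))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.parameter_names))
        df.insert(0, "iteration", np.arange(len(self)))
        df["log_likelihood"] = self.log_likelihoods
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> dict:
        best = best_fit(self)
        return {
            "n_samples": len(self),
            "acceptance_rate": self.acceptance_rate,
            "seed": self.seed,
            "best_fit": best,
            "best_log_likelihood": float(self.log_likelihoods[self.best_index]),
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def best_fit(chain: CalibrationChain) -> dict:
    """Maximum-likelihood sample of the chain, keyed by parameter name."""
    row = chain.samples[chain.best_index]
    return {n: float(v) for n, v in zip(chain.parameter_names, row)}


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _group_observations(observations) -> list:
    """[(treatment, ndarray of observed budburst day indices), ...]"""
    df = observations.frame
    return [
        (tr, sub["budburst_index"].to_numpy(dtype=float))
        for tr, sub in df.groupby("treatment", sort=True)
    ]


def predicted_days_by_treatment(spec: ModelSpec, params: Mapping[str, float],
                                series_by_treatment: Mapping[str, DailyTemperatureSeries],
                                horizon: int = JUN30,
                                validate: bool = True) -> dict:
    """Predicted budburst day index per treatment (None where unreached)."""
    return {
        tr: predict_budburst(spec, params, s, horizon=horizon, validate=validate).day
        for tr, s in series_by_treatment.items()
    }


def log_likelihood(spec: ModelSpec, params: Mapping[str, float], sigma: float,
                   observations, series_by_treatment,
                   horizon: int = JUN30) -> float:
    """Gaussian log-likelihood of observed budburst dates given a model.

    Residuals are observed minus predicted day indices with common standard
    deviation ``sigma``.  Any treatment whose prediction never reaches the
    forcing requirement contributes ``-inf`` (the proposal is rejected).
    """
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    groups = _group_observations(observations)
    missing = [tr for tr, _ in groups if tr not in series_by_treatment]
    if missing:
        raise LookupError(f"no temperature series for treatments {missing}")
    total, n = 0.0, 0
    for tr, obs in groups:
        pred = predict_budburst(spec, params, series_by_treatment[tr],
                                horizon=horizon).day
        if pred is None:
            return -math.inf
        r = obs - pred
        total += float(r @ r)
        n += r.size
    return -0.5 * total / (sigma * sigma) - n * (math.log(sigma) + _LOG_SQRT_2PI)


# ---------------------------------------------------------------------------
# Generic random-walk sampler
# ---------------------------------------------------------------------------

def random_walk_metropolis(log_density: Callable[[np.ndarray], float],
                           x0: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                           config: MCMCConfig,
                           scales: Optional[np.ndarray] = None):
    """Random-walk MH on a box support with flat prior.

    Returns ``(samples, log_densities, acceptance_rate)`` where samples are
    the post-burn-in states (one per iteration, including repeats).
    """
    rng = np.random.default_rng(config.seed)
    x = np.asarray(x0, dtype=float).copy()
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    k = x.size
    if scales is None:
        scales = 0.05 * (hi - lo)
    scales = np.asarray(scales, dtype=float).copy()
    lp = float(log_density(x))
    if not np.isfinite(lp):
        raise InitializationError("starting point has zero posterior probability")

    n_keep = config.n_iterations - config.burn_in
    samples = np.empty((n_keep, k))
    logps = np.empty(n_keep)
    accepted_post = 0
    window_accepts = 0

    for it in range(config.n_iterations):
        prop = x + scales * rng.standard_normal(k)
        in_box = bool(np.all(prop >= lo) and np.all(prop <= hi))
        accept = False
        if in_box:
            lp_prop = float(log_density(prop))
            if lp_prop >= lp or math.log(rng.random()) < lp_prop - lp:
                accept = True
        if accept:
            x, lp = prop, lp_prop
            window_accepts += 1
            if it >= config.burn_in:
                accepted_post += 1
        if config.adapt and it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            rate = window_accepts / config.adapt_interval
            lo_t, hi_t = config.target_acceptance
            if rate < lo_t:
                scales *= 0.7
            elif rate > hi_t:
                scales *= 1.4
            window_accepts = 0
        if it >= config.burn_in:
            j = it - config.burn_in
            samples[j] = x
            logps[j] = lp

    return samples, logps, accepted_post / max(n_keep, 1)


# ---------------------------------------------------------------------------
# Model calibration front end
# ---------------------------------------------------------------------------

def metropolis_hastings(spec: ModelSpec, observations, series_by_treatment,
                        bounds: Optional[Mapping[str, tuple]] = None,
                        config: MCMCConfig = MCMCConfig(),
                        horizon: int = JUN30) -> CalibrationChain:
    """Calibrate one model against an observation set.

    The chain state is the model parameter vector plus (unless fixed) the
    residual sd ``sigma``.  Starting point: the best of up to
    ``config.n_init_draws`` uniform draws from the prior box with finite
    likelihood; an `InitializationError` is raised if none is found.
    """
    species = observations.species
    if len(species) != 1:
        raise ValidationError(
            f"calibration is per species; got observations for {sorted(species)}"
        )
    bounds = dict(bounds) if bounds is not None else dict(spec.bounds)
    names = list(spec.parameter_names)
    calibrate_sigma = config.sigma_fixed is None
    if calibrate_sigma:
        names = names + ["sigma"]
        bounds["sigma"] = SIGMA_BOUNDS
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    groups = _group_observations(observations)
    series = {tr: series_by_treatment[tr] for tr, _ in groups}

    def log_density(x: np.ndarray) -> float:
        params = dict(zip(spec.parameter_names, x))
        sigma = float(x[-1]) if calibrate_sigma else config.sigma_fixed
        if {"Tmin", "Topt", "Tmax"} <= set(params):
            if not (params["Tmin"] < params["Topt"] < params["Tmax"]):
                return -math.inf
        total, n = 0.0, 0
        for tr, obs in groups:
            pred = predict_budburst(spec, params, series[tr], horizon=horizon,
                                    validate=False).day
            if pred is None:
                return -math.inf
            r = obs - pred
            total += float(r @ r)
            n += r.size
        return -0.5 * total / (sigma * sigma) - n * (math.log(sigma) + _LOG_SQRT_2PI)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB0D]))
    x0, lp0 = None, -math.inf
    for _ in range(config.n_init_draws):
        cand = lo + (hi - lo) * rng.random(len(names))
        lp = log_density(cand)
        if lp > lp0:
            x0, lp0 = cand, lp
    if x0 is None or not np.isfinite(lp0):
        raise InitializationError(
            f"{spec.model_id}: no finite-likelihood start in "
            f"{config.n_init_draws} uniform draws"
        )

    samples, logps, acc = random_walk_metropolis(log_density, x0, lo, hi, config)
    return CalibrationChain(tuple(names), samples, logps, acc, config.seed)
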