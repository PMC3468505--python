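"""Synthetic budburst observation sets emulating a factorial warming experiment.

The generator reproduces the structure of a chamber experiment on beech, oak
and birch saplings under a Belgian climatology: seven warming treatments
(W0S0, W6S0, W0S6, W6S6 plus the auxiliary W2S0, W2S2, W2S6), winter warming
from 1 December, transfer between chambers on 22 February, four chambers per
treatment with three saplings of each species per chamber (12 saplings per
treatment, 48 per species over the four main treatments), and budburst
recording on a fixed-interval monitoring grid.

Each species carries a "true" Sequential-model parameterization with
chilling requirements ordered beech (120) > oak (100) > birch (50)
chill-day-equivalents and forcing requirements tuned so control budburst
falls mid-May (beech), early May (oak) and mid-April (birch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .climate import (DEC1, DOY_OFFSET, FEB22, JUN30, ClimateConfig,
                      DailyTemperatureSeries, TreatmentSchedule,
                      apply_treatment, index_to_doy,
                      synthesize_daily_temperature)
from .errors import DesignError, IntegrityError, ParseError, ValidationError
from .models import get_model_spec, predict_budburst

__all__ = [
    "ObservationSet", "SpeciesTruth", "SyntheticDesign",
    "default_design", "beech_stress_design", "generate_observations",
    "read_observations_csv", "write_observations_csv",
    "MAIN_TREATMENTS", "ALL_TREATMENTS",
]

MAIN_TREATMENTS = ("W0S0", "W6S0", "W0S6", "W6S6")
AUX_TREATMENTS = ("W2S0", "W2S2", "W2S6")
ALL_TREATMENTS = MAIN_TREATMENTS + AUX_TREATMENTS

_OBS_COLUMNS = ["species", "treatment", "chamber", "sapling",
                "budburst_index", "budburst_doy"]


class ObservationSet:
    """Budburst dates by species x treatment x chamber x sapling.

    Thin wrapper around a DataFrame with columns
    ``species, treatment, chamber, sapling, budburst_index, budburst_doy``.
    ``metadata`` records generator provenance (true model, parameters, seed)
    for synthetic sets; it is never consulted by calibration or evaluation.
    """

    def __init__(self, frame: pd.DataFrame, metadata: Optional[dict] = None):
        missing = [c for c in _OBS_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"observation table missing columns {missing}")
        frame = frame[_OBS_COLUMNS].reset_index(drop=True)
        dup = frame.duplicated(subset=["species", "treatment", "chamber", "sapling"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise IntegrityError(
                "duplicate observation key "
                f"({row.species}, {row.treatment}, {row.chamber}, {row.sapling})"
            )
        bad = frame["budburst_doy"] != frame["budburst_index"] - DOY_OFFSET
        if bad.any():
            raise IntegrityError(
                f"budburst_doy inconsistent with budburst_index at row {int(bad.idxmax())}"
            )
        self.frame = frame
        self.metadata = metadata or {}

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> tuple:
        return tuple(sorted(self.frame["species"].unique()))

    @property
    def treatments(self) -> tuple:
        return tuple(sorted(self.frame["treatment"].unique()))

    def for_species(self, species: str) -> "ObservationSet":
        sub = self.frame[self.frame["species"] == species]
        if sub.empty:
            raise ValidationError(f"no observations for species {species!r}")
        return ObservationSet(sub, self.metadata)

    def for_treatments(self, labels: Sequence[str]) -> "ObservationSet":
        sub = self.frame[self.frame["treatment"].isin(list(labels))]
        return ObservationSet(sub, self.metadata)

    def subset(self, index) -> "ObservationSet":
        return ObservationSet(self.frame.loc[index], self.metadata)

    def mean_budburst(self, by: str = "treatment") -> pd.Series:
        return self.frame.groupby(by)["budburst_index"].mean()


@dataclass(frozen=True)
class SpeciesTruth:
    """True generating model and parameters for one species."""

    species: str
    model_id: str
    params: Mapping[str, float]

    def __post_init__(self):
        get_model_spec(self.model_id).validate(self.params)


@dataclass(frozen=True)
class SyntheticDesign:
    """Complete description of a simulated warming experiment."""

    species: tuple                    # of SpeciesTruth
    treatments: tuple                 # of TreatmentSchedule
    chambers_per_treatment: int = 4
    saplings_per_chamber: int = 3
    sapling_jitter_sd: float = 2.0    # days
    chamber_jitter_sd: float = 0.3    # deg C; chambers held warming within ~5%
    monitoring_interval: int = 2      # days between monitoring visits
    monitoring_start: int = 154       # 1 February
    seed: int = 0

    def __post_init__(self):
        if self.sapling_jitter_sd < 0 or self.chamber_jitter_sd < 0:
            raise ValidationError("jitter standard deviations must be >= 0")
        if self.monitoring_interval < 1:
            raise ValidationError("monitoring interval must be >= 1 day")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValidationError("treatment labels must be unique")

    @property
    def saplings_per_treatment(self) -> int:
        return self.chambers_per_treatment * self.saplings_per_chamber

    def to_dict(self) -> dict:
        return {
            "species": [
                {"species": s.species, "model_id": s.model_id,
                 "params": dict(s.params)}
                for s in self.species
            ],
            "treatments": [
                {"label": t.label, "winter_offset_c": t.winter_offset,
                 "spring_offset_c": t.spring_offset,
                 "winter_start": t.winter_start, "transfer_day": t.transfer_day}
                for t in self.treatments
            ],
            "chambers_per_treatment": self.chambers_per_treatment,
            "saplings_per_chamber": self.saplings_per_chamber,
            "sapling_jitter_sd": self.sapling_jitter_sd,
            "chamber_jitter_sd": self.chamber_jitter_sd,
            "monitoring_interval": self.monitoring_interval,
            "monitoring_start": self.monitoring_start,
            "seed": self.seed,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _standard_treatments() -> tuple:
    return tuple(
        TreatmentSchedule(label, float(label[1]), float(label[3]),
                          winter_start=DEC1, transfer_day=FEB22)
        for label in ALL_TREATMENTS
    )


# True Sequential-model parameters per species.  Chilling requirements follow
# the 120/100/50 chill-day ordering for beech/oak/birch; the breadth of each
# triangular chilling response scales with the requirement so that dormancy
# release stays achievable in every warmed treatment, and the forcing
# requirements are tuned so control budburst lands mid-May / early May /
# mid-April (see docs/methods.md).
_DEFAULT_TRUTH = {
    "beech": {"Tmin": -25.0, "Topt": 4.0, "Tmax": 34.0,
              "a": 0.4, "b": 8.0, "c": 1.0, "Cstar": 120.0, "Fstar": 45.0},
    "oak": {"Tmin": -20.0, "Topt": 3.0, "Tmax": 26.0,
            "a": 0.4, "b": 8.0, "c": 1.0, "Cstar": 100.0, "Fstar": 37.0},
    "birch": {"Tmin": -60.0, "Topt": -10.0, "Tmax": 21.0,
              "a": 0.2, "b": 9.0, "c": 1.0, "Cstar": 50.0, "Fstar": 28.0},
}

# Chilling-stressed beech: a narrow chilling response and a requirement that
# control winters only just satisfy, so winter warming stalls dormancy
# release; the Thermal Time model cannot reproduce the resulting treatment
# pattern while the Sequential model (the generator) can.
_STRESS_TRUTH = {
    "beech": {"Tmin": -5.0, "Topt": 2.0, "Tmax": 14.0,
              "a": 0.4, "b": 8.0, "c": 1.0, "Cstar": 70.0, "Fstar": 44.0},
}


def default_design(seed: int = 0) -> SyntheticDesign:
    """Three species x seven treatments, forcing-dominated default scenario."""
    return SyntheticDesign(
        species=tuple(
            SpeciesTruth(name, "SM", dict(params))
            for name, params in _DEFAULT_TRUTH.items()
        ),
        treatments=_standard_treatments(),
        seed=seed,
    )


def beech_stress_design(seed: int = 0) -> SyntheticDesign:
    """Single-species scenario in which the chilling requirement binds."""
    return SyntheticDesign(
        species=(SpeciesTruth("beech", "SM", dict(_STRESS_TRUTH["beech"])),),
        treatments=_standard_treatments(),
        seed=seed,
    )


def _censor_to_visit(day: int, start: int, interval: int) -> int:
    """First monitoring visit on or after ``day`` on the fixed visit grid."""
    if day <= start:
        return start
    return start + interval * int(np.ceil((day - start) / interval))


def generate_observations(design: SyntheticDesign,
                          climate: Optional[ClimateConfig] = None,
                          horizon: int = JUN30) -> ObservationSet:
    """Simulate one run of the warming experiment.

    For each chamber a temperature offset is drawn (chamber jitter) and the
    treatment schedule applied to the shared outdoor series; each sapling's
    true budburst day is predicted with its species' generating model,
    perturbed by rounded Gaussian sapling jitter, and censored forward to
    the next monitoring visit.  Deterministic given the design and climate
    seeds.
    """
    if climate is None:
        climate = ClimateConfig(seed=design.seed)
    base = synthesize_daily_temperature(climate, n_days=horizon)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x5EED]))

    # chamber offsets drawn once per (treatment, chamber)
    chamber_offsets = {
        (t.label, c): rng.normal(0.0, design.chamber_jitter_sd)
        if design.chamber_jitter_sd > 0 else 0.0
        for t in design.treatments
        for c in range(1, design.chambers_per_treatment + 1)
    }

    records = []
    for truth in design.species:
        spec = get_model_spec(truth.model_id)
        control = next((t for t in design.treatments
                        if t.winter_offset == 0 and t.spring_offset == 0), None)
        if control is not None:
            ctrl_pred = predict_budburst(spec, truth.params,
                                         apply_treatment(base, control),
                                         horizon=horizon)
            if ctrl_pred.day is None:
                raise DesignError(
                    f"{truth.species}: control treatment yields no budburst "
                    "before the horizon"
                )
        for sched in design.treatments:
            treated = apply_treatment(base, sched)
            for chamber in range(1, design.chambers_per_treatment + 1):
                offset = chamber_offsets[(sched.label, chamber)]
                series = treated if offset == 0.0 else treated.shifted(
                    np.full(len(treated), offset))
                pred = predict_budburst(spec, truth.params, series,
                                        horizon=horizon)
                if pred.day is None:
                    raise DesignError(
                        f"{truth.species}/{sched.label}: no budburst before "
                        "the horizon; the design must produce observable budburst"
                    )
                for sapling in range(1, design.saplings_per_chamber + 1):
                    day = pred.day
                    if design.sapling_jitter_sd > 0:
                        day += int(round(rng.normal(0.0, design.sapling_jitter_sd)))
                    day = min(max(day, series.start_index), horizon)
                    recorded = _censor_to_visit(day, design.monitoring_start,
                                                design.monitoring_interval)
                    records.append({
                        "species": truth.species,
                        "treatment": sched.label,
                        "chamber": f"{sched.label}-c{chamber}",
                        "sapling": sapling,
                        "budburst_index": recorded,
                        "budburst_doy": index_to_doy(recorded),
                    })

    metadata = {
        "generator": "budburst.synthetic.generate_observations",
        "design": design.to_dict(),
        "climate": {
            "annual_mean": climate.annual_mean,
            "annual_amplitude": climate.annual_amplitude,
            "coldest_day_index": climate.coldest_day_index,
            "ar1_coefficient": climate.ar1_coefficient,
            "noise_sd": climate.noise_sd,
            "seed": climate.seed,
        },
    }
    return ObservationSet(pd.DataFrame.from_records(records), metadata)


def write_observations_csv(obs: ObservationSet, path) -> None:
    obs.frame.to_csv(path, index=False)


def read_observations_csv(path) -> ObservationSet:
    """Read an observation CSV; accepts budburst_doy, budburst_index or both."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"could not read {path}: {exc}") from exc
    required = ["species", "treatment", "chamber", "sapling"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    has_doy = "budburst_doy" in df.columns
    has_idx = "budburst_index" in df.columns
    if not (has_doy or has_idx):
        raise ParseError(f"{path}: need budburst_doy or budburst_index column")
    for col in (c for c in ("budburst_doy", "budburst_index") if c in df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"unparseable {col}",
                             line=int(vals.isna().idxmax()) + 2)
        df[col] = vals.astype(int)
    if has_doy and has_idx:
        bad = df["budburst_doy"] != df["budburst_index"] - DOY_OFFSET
        if bad.any():
            raise ParseError("budburst_doy and budburst_index disagree",
                             line=int(bad.idxmax()) + 2)
    elif has_doy:
        df["budburst_index"] = df["budburst_doy"] + DOY_OFFSET
    else:
        df["budburst_doy"] = df["budburst_index"] - DOY_OFFSET
    return ObservationSet(df)
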