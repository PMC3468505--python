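"""Daily air-temperature series, chamber warming schedules and a weather synthesizer.

Day axis convention
-------------------
All series live on an integer day index with ``1 = 1 September`` of the year
preceding budburst, using a fixed 365-day year (the season of interest never
crosses a leap day).  Day of year (DOY) of the budburst year is
``DOY = index - 122``, so 1 January is index 123.  Fixed anchors used by the
experiment and the models:

========  =====  ================================
anchor    index  meaning
========  =====  ================================
SEP1      1      chilling start (Unified model)
NOV1      62     chilling start (Alternating model)
DEC1      92     warming treatments switch on
JAN1      123    forcing start (Alternating model)
FEB22     175    transfer day between chambers
JUN30     303    prediction horizon
========  =====  ================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError, RangeError, ValidationError

__all__ = [
    "SEP1", "NOV1", "DEC1", "JAN1", "FEB22", "JUN30", "DOY_OFFSET",
    "index_to_doy", "doy_to_index", "date_to_index",
    "DailyTemperatureSeries", "TreatmentSchedule", "ClimateConfig",
    "synthesize_daily_temperature", "apply_treatment", "mean_warming_delta",
    "read_temperature_csv", "write_temperature_csv", "schedule_from_label",
]

SEP1 = 1
NOV1 = 62
DEC1 = 92
JAN1 = 123
FEB22 = 175
JUN30 = 303
DOY_OFFSET = 122
DAYS_PER_YEAR = 365


def index_to_doy(index: int) -> int:
    """Convert a season day index (1 = 1 Sep) to day-of-year of the budburst year."""
    return index - DOY_OFFSET


def doy_to_index(doy: int) -> int:
    """Convert a budburst-year day-of-year to the season day index."""
    return doy + DOY_OFFSET


def date_to_index(d: _date) -> int:
    """Map a calendar date to the season day index.

    Dates from September onward belong to the season starting that year;
    earlier dates belong to the season that started the previous autumn.
    """
    start_year = d.year if d.month >= 9 else d.year - 1
    return (d - _date(start_year, 9, 1)).days + 1


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """An uninterrupted sequence of mean daily air temperatures (deg C)."""

    start_index: int
    temps: np.ndarray

    def __post_init__(self):
        temps = np.asarray(self.temps, dtype=float)
        if temps.ndim != 1 or temps.size == 0:
            raise ValidationError("temps must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(temps)):
            raise ValidationError("temps must contain only finite values")
        temps = temps.copy()
        temps.flags.writeable = False
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "start_index", int(self.start_index))

    def __len__(self) -> int:
        return self.temps.size

    @property
    def end_index(self) -> int:
        """Last covered day index (inclusive)."""
        return self.start_index + len(self) - 1

    @property
    def day_indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.end_index + 1)

    def covers(self, start: int, end: int) -> bool:
        return self.start_index <= start and end <= self.end_index

    def window(self, start: int, end: int) -> np.ndarray:
        """Temperatures on the inclusive day-index window [start, end]."""
        if start > end:
            raise RangeError(f"empty window [{start}, {end}]")
        if not self.covers(start, end):
            raise RangeError(
                f"window [{start}, {end}] outside series support "
                f"[{self.start_index}, {self.end_index}]"
            )
        lo = start - self.start_index
        return self.temps[lo : lo + (end - start + 1)]

    def value(self, index: int) -> float:
        return float(self.window(index, index)[0])

    def shifted(self, offsets: np.ndarray) -> "DailyTemperatureSeries":
        """Return a new series with per-day offsets added."""
        offsets = np.asarray(offsets, dtype=float)
        if offsets.shape != self.temps.shape:
            raise AlignmentError("offset array must match series length")
        return DailyTemperatureSeries(self.start_index, self.temps + offsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day_index": self.day_indices, "tmean_c": self.temps})


@dataclass(frozen=True)
class TreatmentSchedule:
    """Piecewise-constant warming offsets defining one chamber treatment.

    ``winter_offset`` applies on ``[winter_start, transfer_day)`` and
    ``spring_offset`` from ``transfer_day`` (inclusive) to the end of the
    series: the transfer day itself counts as a spring day, because saplings
    were moved between chambers on that morning.
    """

    label: str
    winter_offset: float = 0.0
    spring_offset: float = 0.0
    winter_start: int = DEC1
    transfer_day: int = FEB22

    def __post_init__(self):
        if not (math.isfinite(self.winter_offset) and math.isfinite(self.spring_offset)):
            raise ValidationError(f"{self.label}: offsets must be finite")
        if self.winter_start >= self.transfer_day:
            raise ValidationError(
                f"{self.label}: winter_start ({self.winter_start}) must precede "
                f"transfer_day ({self.transfer_day})"
            )


def schedule_from_label(label: str, winter_start: int = DEC1,
                        transfer_day: int = FEB22) -> TreatmentSchedule:
    """Build a schedule from a 'WxSy' treatment code (x, y in deg C)."""
    import re

    m = re.fullmatch(r"W(\d+(?:\.\d+)?)S(\d+(?:\.\d+)?)", label)
    if m is None:
        raise ValidationError(f"treatment label {label!r} is not of the form WxSy")
    return TreatmentSchedule(label, float(m.group(1)), float(m.group(2)),
                             winter_start, transfer_day)


@dataclass(frozen=True)
class ClimateConfig:
    """Sinusoid + AR(1) model of a mid-latitude daily-temperature climatology.

    Defaults reproduce the Belgian climatology of the experiment site:
    annual mean 9.6 deg C with monthly means ranging from 2.2 deg C in
    January to 17.0 deg C in July (amplitude (17.0 - 2.2)/2 = 7.4 deg C,
    coldest day mid-January).
    """

    annual_mean: float = 9.6
    annual_amplitude: float = 7.4
    coldest_day_index: int = 137  # 15 January
    ar1_coefficient: float = 0.7
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("annual_mean", "annual_amplitude", "ar1_coefficient", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not abs(self.ar1_coefficient) < 1:
            raise ValidationError("|ar1_coefficient| must be < 1")


def synthesize_daily_temperature(config: ClimateConfig, n_days: int = JUN30,
                                 start_index: int = SEP1) -> DailyTemperatureSeries:
    """Generate a seeded synthetic daily temperature series.

    The deterministic part is an annual sinusoid whose minimum falls on
    ``coldest_day_index``; stationary AR(1) noise with marginal standard
    deviation ``noise_sd`` is superimposed.  Bit-reproducible for a given
    config (the seed lives in the config).
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    days = np.arange(start_index, start_index + n_days)
    base = config.annual_mean - config.annual_amplitude * np.cos(
        2.0 * np.pi * (days - config.coldest_day_index) / DAYS_PER_YEAR
    )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        z = rng.standard_normal(n_days)
        phi = config.ar1_coefficient
        noise = np.empty(n_days)
        noise[0] = config.noise_sd * z[0]
        innov_sd = config.noise_sd * math.sqrt(1.0 - phi * phi)
        for t in range(1, n_days):
            noise[t] = phi * noise[t - 1] + innov_sd * z[t]
        base = base + noise
    return DailyTemperatureSeries(start_index, base)


def apply_treatment(series: DailyTemperatureSeries,
                    schedule: TreatmentSchedule) -> DailyTemperatureSeries:
    """Apply a chamber warming schedule, returning a new series.

    Temperatures before ``winter_start`` are unchanged; ``winter_offset`` is
    added on ``[winter_start, transfer_day)`` and ``spring_offset`` from
    ``transfer_day`` to the series end.
    """
    if not series.covers(schedule.winter_start, schedule.transfer_day):
        raise RangeError(
            f"schedule {schedule.label} window [{schedule.winter_start}, "
            f"{schedule.transfer_day}] outside series support "
            f"[{series.start_index}, {series.end_index}]"
        )
    offsets = np.zeros(len(series))
    i_winter = schedule.winter_start - series.start_index
    i_transfer = schedule.transfer_day - series.start_index
    offsets[i_winter:i_transfer] = schedule.winter_offset
    offsets[i_transfer:] = schedule.spring_offset
    return series.shifted(offsets)


def mean_warming_delta(treated: DailyTemperatureSeries,
                       control: DailyTemperatureSeries,
                       start: int, end: int) -> float:
    """Mean treated-minus-control temperature over the inclusive window.

    This is the 'delta T' of the warming-sensitivity analysis: the average
    temperature difference experienced between a reference day (1 December)
    and the observed budburst day.
    """
    if start > end:
        raise RangeError(f"empty window [{start}, {end}]")
    for s, name in ((treated, "treated"), (control, "control")):
        if not s.covers(start, end):
            raise AlignmentError(
                f"{name} series [{s.start_index}, {s.end_index}] does not cover "
                f"[{start}, {end}]"
            )
    return float(np.mean(treated.window(start, end) - control.window(start, end)))


def write_temperature_csv(series: DailyTemperatureSeries, path) -> None:
    """Write a series as a two-column CSV (day_index, tmean_c) at full precision."""
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_temperature_csv(path) -> DailyTemperatureSeries:
    """Read a daily temperature CSV with columns day_index|date and tmean_c."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not read {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "tmean_c" not in cols:
        raise ParseError(f"{path}: missing required column 'tmean_c'")
    if "day_index" in cols:
        raw = df[cols["day_index"]]
        try:
            idx = raw.astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna()].index[0]
            raise ParseError("unparseable day_index", line=int(bad) + 2) from exc
    elif "date" in cols:
        try:
            dates = pd.to_datetime(df[cols["date"]], format="ISO8601")
        except (TypeError, ValueError) as exc:
            raise ParseError(f"unparseable ISO date in {path}: {exc}") from exc
        idx = np.array([date_to_index(d.date()) for d in dates])
    else:
        raise ParseError(f"{path}: need a 'day_index' or 'date' column")
    temps = pd.to_numeric(df[cols["tmean_c"]], errors="coerce").to_numpy()
    if np.isnan(temps).any():
        line = int(np.flatnonzero(np.isnan(temps))[0]) + 2
        raise ParseError("unparseable tmean_c value", line=line)
    order = np.argsort(idx, kind="stable")
    idx, temps = idx[order], temps[order]
    dup = np.flatnonzero(np.diff(idx) == 0)
    if dup.size:
        raise ParseError(f"duplicate day_index {idx[dup[0]]}")
    gaps = np.flatnonzero(np.diff(idx) > 1)
    if gaps.size:
        raise ParseError(f"missing day_index {idx[gaps[0]] + 1}")
    return DailyTemperatureSeries(int(idx[0]), temps)
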