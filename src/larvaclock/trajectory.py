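"""Per-individual growth-trajectory statistics.

Each larva's growth is summarised by a third-degree polynomial fitted to log
head width against age, where age runs on a winter-excluded axis (the
two-week diapause pause does not advance age, so the four measurement events
sit at days 0, 42, 84 and 126).  Seasonal growth rates are the analytic
slopes of the fitted polynomial at fixed anchor ages: day 21 (mid
summer/fall, halfway between events 1 and 2) and day 105 (mid spring,
halfway between events 3 and 4), in units of d(log head width)/day.

With four distinct ages the cubic interpolates the data exactly, so the
slopes are invariant to any invertible reparametrisation of the time axis
used internally; fitting is done on centred age for conditioning, with
coefficients reported on the original axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Measurement",
    "TrajectoryFit",
    "SeasonAnchors",
    "GrowthRateRecord",
    "UnfittableTrajectoryError",
    "winter_adjusted_age",
    "fit_log_cubic",
    "slope_at",
    "seasonal_rates",
    "rates_table",
]

#: Design measurement ages on the winter-excluded axis.
MEASUREMENT_AGES = (0.0, 42.0, 84.0, 126.0)

#: Centring offset for the internal fit (midpoint of the design ages).
_AGE_CENTRE = 63.0


@dataclass(frozen=True)
class Measurement:
    """One photographed head-width measurement of one larva."""

    individual_id: str
    event_index: int
    age_days: float
    head_width_mm: float

    def __post_init__(self) -> None:
        if self.head_width_mm <= 0:
            raise ValueError(
                f"head_width_mm must be positive (log scale), got {self.head_width_mm}"
            )


@dataclass(frozen=True)
class TrajectoryFit:
    """Cubic (or reduced-degree) polynomial on log head width vs age.

    ``coefficients`` are (b0, b1, b2, b3) on the original age axis so that
    log(width) = b0 + b1*t + b2*t**2 + b3*t**3; higher-order terms are zero
    when fewer than four points forced a reduced degree.
    """

    individual_id: str
    coefficients: tuple[float, float, float, float]
    n_points: int
    interpolating: bool

    @property
    def b0(self) -> float:
        return self.coefficients[0]

    @property
    def b1(self) -> float:
        return self.coefficients[1]

    @property
    def b2(self) -> float:
        return self.coefficients[2]

    @property
    def b3(self) -> float:
        return self.coefficients[3]

    def predict_log_width(self, age_days: float) -> float:
        b0, b1, b2, b3 = self.coefficients
        return b0 + b1 * age_days + b2 * age_days**2 + b3 * age_days**3


class UnfittableTrajectoryError(ValueError):
    """Raised when an individual has too few distinct-age measurements."""


@dataclass(frozen=True)
class SeasonAnchors:
    """Ages at which seasonal growth rates are read off the fitted curve."""

    summer_fall_day: float = 21.0
    spring_day: float = 105.0
    winter_exclusion_days: float = 14.0

    def __post_init__(self) -> None:
        if not 0 < self.summer_fall_day < self.spring_day:
            raise ValueError("require 0 < summer_fall_day < spring_day")


@dataclass(frozen=True)
class GrowthRateRecord:
    """Seasonal growth rates of one larva with its design labels."""

    individual_id: str
    family: str
    sub_population: str
    region: str
    photoperiod: str
    summer_fall_rate: float
    spring_rate: float
    hatch_size_mm: float | None = None
    size_day84_mm: float | None = None


def winter_adjusted_age(
    calendar_day_offset: float,
    winter_window: tuple[float, float],
) -> float:
    """Map days since hatching to winter-excluded age.

    Age equals the calendar offset before the winter window, is frozen at the
    window start throughout the window (no growth, no ageing), and advances
    again afterwards with the window length subtracted.  Continuous and
    non-decreasing.
    """
    start, end = winter_window
    if not start < end:
        raise ValueError(f"winter window must satisfy start < end, got {winter_window}")
    if calendar_day_offset <= start:
        return float(calendar_day_offset)
    if calendar_day_offset <= end:
        return float(start)
    return float(calendar_day_offset - (end - start))


def fit_log_cubic(measurements: Sequence[Measurement]) -> TrajectoryFit:
    """Least-squares polynomial of log head width on age, degree min(3, n-1).

    With the full four distinct-age design this is exact interpolation (four
    coefficients, four points).  Internally the fit uses centred age for
    numerical conditioning; reported coefficients are on the original axis.
    """
    if not measurements:
        raise UnfittableTrajectoryError("no measurements")
    ind = measurements[0].individual_id
    ages = np.array([m.age_days for m in measurements], dtype=float)
    widths = np.array([m.head_width_mm for m in measurements], dtype=float)
    distinct = np.unique(ages)
    if distinct.size < 2:
        raise UnfittableTrajectoryError(
            f"individual {ind}: need >= 2 distinct-age measurements, got {distinct.size}"
        )
    degree = min(3, distinct.size - 1)
    log_w = np.log(widths)
    centred = np.polynomial.Polynomial.fit(
        ages - _AGE_CENTRE, log_w, deg=degree, domain=[]
    )
    # Back-transform to the original age axis; exact polynomial identity.
    original = centred(np.polynomial.Polynomial([-_AGE_CENTRE, 1.0]))
    coef = np.zeros(4)
    coef[: len(original.coef)] = original.coef
    return TrajectoryFit(
        individual_id=ind,
        coefficients=tuple(float(c) for c in coef),
        n_points=int(ages.size),
        interpolating=bool(distinct.size >= 4 and ages.size == 4),
    )


def slope_at(fit: TrajectoryFit, day: float, max_age: float = MEASUREMENT_AGES[-1]) -> float:
    """Instantaneous growth rate d(log width)/day of the fitted curve at ``day``."""
    if day < 0 or day > max_age:
        warnings.warn(
            f"slope requested at day {day}, outside the observed range [0, {max_age}]: "
            "extrapolating",
            stacklevel=2,
        )
    _, b1, b2, b3 = fit.coefficients
    return b1 + 2.0 * b2 * day + 3.0 * b3 * day**2


def seasonal_rates(
    measurements: Sequence[Measurement],
    labels: Mapping[str, str],
    anchors: SeasonAnchors = SeasonAnchors(),
    hatch_size_mm: float | None = None,
) -> GrowthRateRecord:
    """Fit one individual and read off its summer/fall and spring rates.

    ``labels`` must provide ``family``, ``sub_population``, ``region`` and
    ``photoperiod``.  The day-84 size covariate is taken from the event at
    age 84 when present and recorded as missing otherwise (never imputed);
    the hatch-size covariate is the family-mean hatchling head width supplied
    by the caller.
    """
    fit = fit_log_cubic(measurements)
    day84 = next(
        (m.head_width_mm for m in measurements if math.isclose(m.age_days, 84.0)), None
    )
    return GrowthRateRecord(
        individual_id=fit.individual_id,
        family=str(labels["family"]),
        sub_population=str(labels["sub_population"]),
        region=str(labels["region"]),
        photoperiod=str(labels["photoperiod"]),
        summer_fall_rate=slope_at(fit, anchors.summer_fall_day),
        spring_rate=slope_at(fit, anchors.spring_day),
        hatch_size_mm=hatch_size_mm,
        size_day84_mm=day84,
    )


REQUIRED_COLUMNS = (
    "individual_id",
    "family",
    "sub_population",
    "region",
    "photoperiod",
    "event_index",
    "age_days",
    "head_width_mm",
)


def rates_table(
    measurements: pd.DataFrame,
    anchors: SeasonAnchors = SeasonAnchors(),
    hatch_sizes: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Vectorised front end: long measurement table -> growth-rate table.

    ``measurements`` follows the input schema (one row per individual per
    event); ``hatch_sizes`` maps family -> family-mean hatchling head width.
    Returns the per-individual rate table and the ids of individuals excluded
    for having fewer than two distinct-age measurements.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if (measurements["head_width_mm"] <= 0).any():
        bad = measurements.loc[measurements["head_width_mm"] <= 0, "individual_id"]
        raise ValueError(f"non-positive head widths for individuals {sorted(set(bad))}")
    records: list[GrowthRateRecord] = []
    excluded: list[str] = []
    for ind, grp in measurements.groupby("individual_id", sort=True):
        grp = grp.sort_values("age_days")
        ms = [
            Measurement(str(ind), int(r.event_index), float(r.age_days), float(r.head_width_mm))
            for r in grp.itertuples()
        ]
        labels = {
            "family": grp["family"].iloc[0],
            "sub_population": grp["sub_population"].iloc[0],
            "region": grp["region"].iloc[0],
            "photoperiod": grp["photoperiod"].iloc[0],
        }
        hatch = None
        if hatch_sizes is not None:
            hatch = hatch_sizes.get(str(labels["family"]))
        try:
            records.append(seasonal_rates(ms, labels, anchors, hatch_size_mm=hatch))
        except UnfittableTrajectoryError:
            excluded.append(str(ind))
    table = pd.DataFrame([r.__dict__ for r in records])
    return table, excluded
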