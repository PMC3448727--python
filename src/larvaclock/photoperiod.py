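"""Day-length and photoperiod-treatment engine.

Computes the duration of the daily light phase at an arbitrary latitude and
date under a configurable twilight rule (daylight plus a fraction of each
civil-twilight period), and generates the full climate-chamber treatment
schedules used in the common-garden rearing experiment: weekly photoperiod
updates, a two-week winter blackout at 5 degC, and a spring restart in which
the chamber jumps forward to track April day lengths.

Only durations are computed, on apparent solar time at the stated meridian;
clock times of sunrise and sunset, longitude corrections and atmospheric
models beyond a fixed refraction constant are out of scope.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import Iterator

__all__ = [
    "GeoDate",
    "TwilightRule",
    "CIVIL_TWILIGHT_RULE",
    "Regime",
    "LightPhase",
    "HMMDuration",
    "TreatmentSchedule",
    "ScheduleEntry",
    "POLAR_DAY",
    "POLAR_NIGHT",
    "solar_declination",
    "altitude_crossing_hours",
    "light_phase",
    "to_hmm",
    "from_hmm",
    "weekly_schedule",
    "experiment_schedule",
]

# Sun-centre altitude at geometric sunrise/sunset: 16' solar radius plus
# 34' standard refraction.
SUNRISE_SUNSET_ALTITUDE = -0.833
CIVIL_TWILIGHT_ALTITUDE = -6.0

#: Sentinels returned by :func:`altitude_crossing_hours` when the sun never
#: crosses the requested altitude on the given day.
POLAR_DAY = "polar_day"
POLAR_NIGHT = "polar_night"


class Regime(str, Enum):
    """Classifies the day/night geometry of a computed light phase."""

    NORMAL = "normal"
    POLAR_DAY = "polar_day"
    POLAR_NIGHT = "polar_night"
    #: The sun sets but never descends below the twilight altitude, so the
    #: entire dark period is twilight (high latitudes in midsummer).
    ALL_NIGHT_TWILIGHT = "all_night_twilight"


@dataclass(frozen=True)
class GeoDate:
    """A latitude/date pair at which to evaluate solar geometry."""

    latitude: float
    calendar_date: date

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not isinstance(self.calendar_date, date):
            raise TypeError("calendar_date must be a datetime.date")


@dataclass(frozen=True)
class TwilightRule:
    """Definition of the light phase in terms of sun-centre altitudes.

    ``light = daylight(rise_set_altitude) + twilight_fraction * twilight``
    where twilight is the time the sun spends between the two altitudes on
    each side of the day.
    """

    rise_set_altitude: float = SUNRISE_SUNSET_ALTITUDE
    twilight_altitude: float = CIVIL_TWILIGHT_ALTITUDE
    twilight_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.twilight_altitude < self.rise_set_altitude <= 0.0:
            raise ValueError(
                "require twilight_altitude < rise_set_altitude <= 0, got "
                f"{self.twilight_altitude} / {self.rise_set_altitude}"
            )
        if not 0.0 <= self.twilight_fraction <= 1.0:
            raise ValueError("twilight_fraction must lie in [0, 1]")


#: The chamber rule: half of each civil twilight counts as light.
CIVIL_TWILIGHT_RULE = TwilightRule()


@dataclass(frozen=True)
class LightPhase:
    """Durations of the light and dark phases of one 24 h cycle."""

    light_hours: float
    regime_flag: Regime = Regime.NORMAL

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.light_hours

    def __post_init__(self) -> None:
        if not 0.0 <= self.light_hours <= 24.0:
            raise ValueError(f"light_hours {self.light_hours} outside [0, 24]")


@dataclass(frozen=True, order=True)
class HMMDuration:
    """A duration in whole hours and minutes (printed as h.mm, 17.15 = 17 h 15 min)."""

    hours: int
    minutes: int

    def __post_init__(self) -> None:
        if self.hours < 0:
            raise ValueError("hours must be >= 0")
        if not 0 <= self.minutes <= 59:
            raise ValueError(f"minutes {self.minutes} outside 0..59")

    @property
    def decimal_hours(self) -> float:
        return self.hours + self.minutes / 60.0

    @property
    def hmm(self) -> float:
        """The duration in h.mm notation as a number (17 h 15 min -> 17.15)."""
        return self.hours + self.minutes / 100.0

    def __str__(self) -> str:
        return f"{self.hours:02d}.{self.minutes:02d}"


def to_hmm(light_hours: float) -> HMMDuration:
    """Round a decimal-hour duration to the nearest minute as an h.mm duration."""
    if not 0.0 <= light_hours <= 24.0:
        raise ValueError(f"duration {light_hours} outside [0, 24]")
    total_minutes = int(round(light_hours * 60.0))
    return HMMDuration(hours=total_minutes // 60, minutes=total_minutes % 60)


def from_hmm(duration: HMMDuration) -> float:
    """Decimal hours of an h.mm duration."""
    return duration.decimal_hours


def _days_in_year(year: int) -> int:
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    return 366 if leap else 365


def solar_declination(calendar_date: date) -> float:
    """Solar declination (degrees) at local solar noon of the given date.

    Low-precision Fourier series in the fractional year (Spencer-type
    expansion); accurate to about 0.3 degrees, which maps to under ~3 min of
    day length at the latitudes of interest.
    """
    doy = calendar_date.timetuple().tm_yday
    gamma = 2.0 * math.pi / _days_in_year(calendar_date.year) * (doy - 1 + 0.5)
    decl_rad = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.001480 * math.sin(3 * gamma)
    )
    return math.degrees(decl_rad)


def altitude_crossing_hours(geo: GeoDate, altitude: float) -> float | str:
    """Hours per day the sun's centre spends above ``altitude`` degrees.

    Returns the :data:`POLAR_DAY` sentinel when the sun never descends to the
    altitude, and :data:`POLAR_NIGHT` when it never ascends to it.
    """
    if not -90.0 < altitude < 90.0:
        raise ValueError(f"altitude {altitude} outside (-90, 90)")
    decl = math.radians(solar_declination(geo.calendar_date))
    phi = math.radians(geo.latitude)
    alt = math.radians(altitude)
    denom = math.cos(phi) * math.cos(decl)
    if denom == 0.0:  # exactly at a pole
        return POLAR_DAY if math.sin(phi) * math.sin(decl) > math.sin(alt) else POLAR_NIGHT
    cos_hour_angle = (math.sin(alt) - math.sin(phi) * math.sin(decl)) / denom
    if cos_hour_angle < -1.0:
        return POLAR_DAY
    if cos_hour_angle > 1.0:
        return POLAR_NIGHT
    return 2.0 * math.degrees(math.acos(cos_hour_angle)) / 15.0


def light_phase(geo: GeoDate, rule: TwilightRule = CIVIL_TWILIGHT_RULE) -> LightPhase:
    """Light-phase duration under a twilight rule.

    Daylight (sun above ``rule.rise_set_altitude``) plus ``twilight_fraction``
    of the morning and of the evening twilight (sun between the twilight and
    rise/set altitudes).  Two polar edge cases:

    * sun never sets -> 24 h of light (``polar_day``);
    * sun sets but never reaches the twilight altitude -> the whole dark
      period is twilight and contributes ``twilight_fraction * (24 - daylight)``
      (``all_night_twilight``).
    """
    daylight = altitude_crossing_hours(geo, rule.rise_set_altitude)
    if daylight == POLAR_DAY:
        return LightPhase(24.0, Regime.POLAR_DAY)
    above_twilight = altitude_crossing_hours(geo, rule.twilight_altitude)
    if daylight == POLAR_NIGHT:
        # No daylight at all; any time above the twilight altitude is twilight.
        if above_twilight == POLAR_NIGHT:
            return LightPhase(0.0, Regime.POLAR_NIGHT)
        twilight = 24.0 if above_twilight == POLAR_DAY else above_twilight
        return LightPhase(rule.twilight_fraction * twilight, Regime.POLAR_NIGHT)
    if above_twilight == POLAR_DAY:
        # Sun sets but never leaves twilight: dark period is all twilight.
        hours = daylight + rule.twilight_fraction * (24.0 - daylight)
        return LightPhase(hours, Regime.ALL_NIGHT_TWILIGHT)
    hours = daylight + rule.twilight_fraction * (above_twilight - daylight)
    return LightPhase(hours, Regime.NORMAL)


def _daterange(start: date, end: date) -> Iterator[date]:
    d = start
    while d <= end:
        yield d
        d += timedelta(days=1)


def weekly_schedule(
    latitude: float,
    start_date: date,
    end_date: date,
    rule: TwilightRule = CIVIL_TWILIGHT_RULE,
    update_weekday: int | None = 5,
) -> list[tuple[date, LightPhase]]:
    """Daily applied light phases with piecewise-constant weekly updates.

    The chamber photoperiod is set from the light phase of ``start_date`` and
    then re-set on every ``update_weekday`` (``date.weekday()`` convention,
    5 = Saturday, matching the experiment) from that day's own light phase.
    ``update_weekday=None`` tracks the true value daily.
    """
    if start_date > end_date:
        raise ValueError("start_date must be <= end_date")
    out: list[tuple[date, LightPhase]] = []
    current: LightPhase | None = None
    for d in _daterange(start_date, end_date):
        if current is None or update_weekday is None or d.weekday() == update_weekday:
            current = light_phase(GeoDate(latitude, d), rule)
        out.append((d, current))
    return out


@dataclass(frozen=True)
class ScheduleEntry:
    calendar_date: date
    #: The date whose solar geometry the chamber is mimicking that day
    #: (None during the winter blackout).
    mapped_solar_date: date | None
    phase: LightPhase
    temperature_c: float


@dataclass(frozen=True)
class TreatmentSchedule:
    treatment_latitude: float
    entries: list[ScheduleEntry] = field(default_factory=list)

    def entry_for(self, calendar_date: date) -> ScheduleEntry:
        for e in self.entries:
            if e.calendar_date == calendar_date:
                return e
        raise KeyError(f"no schedule entry for {calendar_date}")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "calendar_date",
                    "mapped_solar_date",
                    "latitude",
                    "light_hours",
                    "dark_hours",
                    "regime_flag",
                    "temperature_c",
                ]
            )
            for e in self.entries:
                w.writerow(
                    [
                        e.calendar_date.isoformat(),
                        "" if e.mapped_solar_date is None else e.mapped_solar_date.isoformat(),
                        self.treatment_latitude,
                        f"{e.phase.light_hours:.4f}",
                        f"{e.phase.dark_hours:.4f}",
                        e.phase.regime_flag.value,
                        e.temperature_c,
                    ]
                )


# Experiment timeline (calendar dates of the rearing experiment).
EXPERIMENT_START = date(2010, 7, 10)
WINTER_ONSET = date(2010, 10, 9)  # lights off, 5 degC
PRE_WINTER_COOL = date(2010, 10, 8)  # last lit day, 16 degC
SPRING_ONSET = date(2010, 10, 23)  # lights on, mapped to 9 Apr 2011
SPRING_MAPPED_DATE = date(2011, 4, 9)
SPRING_WARMUP_DAYS = 15  # days at 16 degC before returning to 22.5
DEFAULT_EXPERIMENT_END = date(2011, 2, 1)

TEMP_REARING = 22.5
TEMP_TRANSITION = 16.0
TEMP_WINTER = 5.0


def experiment_schedule(
    treatment_latitude: float,
    rule: TwilightRule = CIVIL_TWILIGHT_RULE,
    end_date: date = DEFAULT_EXPERIMENT_END,
    weekly_updates: bool = True,
) -> TreatmentSchedule:
    """Full day-by-day chamber schedule for one photoperiod treatment.

    From 10 Jul 2010 the chamber tracks the real calendar (weekly Saturday
    updates by default).  8 Oct is the last lit pre-winter day at 16 degC;
    9-22 Oct is the winter blackout (0 h light, 5 degC); from 23 Oct the
    lights return, mapped to 9 Apr 2011 and advancing daily, at 16 degC for
    15 days and 22.5 degC thereafter.
    """
    update_weekday = 5 if weekly_updates else None
    summer = weekly_schedule(
        treatment_latitude, EXPERIMENT_START, PRE_WINTER_COOL, rule, update_weekday
    )
    entries: list[ScheduleEntry] = []
    for d, phase in summer:
        temp = TEMP_TRANSITION if d == PRE_WINTER_COOL else TEMP_REARING
        entries.append(ScheduleEntry(d, d, phase, temp))
    for d in _daterange(WINTER_ONSET, SPRING_ONSET - timedelta(days=1)):
        entries.append(
            ScheduleEntry(d, None, LightPhase(0.0, Regime.POLAR_NIGHT), TEMP_WINTER)
        )
    warmup_end = SPRING_ONSET + timedelta(days=SPRING_WARMUP_DAYS - 1)
    for d in _daterange(SPRING_ONSET, end_date):
        mapped = SPRING_MAPPED_DATE + (d - SPRING_ONSET)
        phase = light_phase(GeoDate(treatment_latitude, mapped), rule)
        temp = TEMP_TRANSITION if d <= warmup_end else TEMP_REARING
        entries.append(ScheduleEntry(d, mapped, phase, temp))
    return TreatmentSchedule(treatment_latitude, entries)


#: Latitudes of the two chamber treatments.
TREATMENT_LATITUDES = {"southern": 52.0, "northern": 64.0}
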