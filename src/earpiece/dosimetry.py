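"""Ear-piece noise dosimetry.

Converts self-reported volume-control settings and usage durations into
energy-based exposure metrics:

* ``device_noise`` — total career noise energy in dimensionless units, where
  one unit equals one working year (47 weeks x 40 h) of constant exposure at
  85 dBA (the UK Upper Exposure Action Value).
* ``device_weekly_level`` — the constant sound level that, present for 40 h in
  every working week of ear-piece use, would carry the same total energy
  (the Control of Noise at Work weekly-average metric).
* ``device_volume_average`` — the energy-weighted average volume-control
  setting, obtained by inverting the volume-to-level calibration at the
  energy-average sound level.

All arithmetic follows the equal-energy principle: sound energy is
proportional to duration x 10^(L/10) for an A-weighted level L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "DUTY_CYCLE",
    "REF_LEVEL",
    "WORK_WEEK_H",
    "WORKING_YEAR_WEEKS",
    "UNIT_HOURS",
    "DosimetryDomainError",
    "UndefinedExposureError",
    "CalibrationCurve",
    "CareerSegment",
    "ExposureSummary",
    "default_calibration",
    "volume_to_level",
    "level_to_volume",
    "segment_exposure_hours",
    "device_noise",
    "device_weekly_level",
    "device_volume_average",
    "summarize_career",
    "summarize_career_table",
]

#: Fraction of ear-piece wearing time during which radio speech/chatter is
#: actually transmitted (published channel-activity estimates span 15-30%).
DUTY_CYCLE = 0.2
#: Reference level for exposure units, dBA (UK Upper Exposure Action Value).
REF_LEVEL = 85.0
#: Nominal working week, hours.
WORK_WEEK_H = 40.0
#: Working weeks per year.
WORKING_YEAR_WEEKS = 47
#: Hours in one working year: 47 weeks x 40 h.
UNIT_HOURS = WORKING_YEAR_WEEKS * WORK_WEEK_H  # 1880.0


class DosimetryDomainError(ValueError):
    """Input outside the physical or calibrated domain."""


class UndefinedExposureError(ValueError):
    """Metric undefined because the career carries zero exposure."""


def _energy(level_dba: np.ndarray | float) -> np.ndarray | float:
    """Relative sound energy per hour at ``level_dba``, in 85-dBA-hour units."""
    return 10.0 ** ((np.asarray(level_dba, dtype=float) - REF_LEVEL) / 10.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone mapping between volume-control setting (%) and output level (dBA).

    Anchored at measured (volume, level) pairs; between anchors the curve is a
    shape-preserving monotone piecewise cubic (PCHIP), which reproduces the
    anchors exactly and captures the slightly nonlinear volume/level relation
    of real devices. Strict monotonicity of the anchors makes the curve
    invertible.
    """

    volume_percent: tuple[float, ...]
    level_dba: tuple[float, ...]
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.volume_percent, dtype=float)
        lv = np.asarray(self.level_dba, dtype=float)
        if v.size != lv.size or v.size < 2:
            raise DosimetryDomainError("calibration needs >= 2 (volume, level) points")
        if np.any(v < 0) or np.any(v > 100):
            raise DosimetryDomainError("calibration volumes must lie in [0, 100]%")
        if np.any(np.diff(v) <= 0) or np.any(np.diff(lv) <= 0):
            raise DosimetryDomainError(
                "calibration anchors must be strictly increasing in both columns"
            )
        object.__setattr__(self, "volume_percent", tuple(v))
        object.__setattr__(self, "level_dba", tuple(lv))
        object.__setattr__(self, "_interp", PchipInterpolator(v, lv, extrapolate=False))

    # -- forward map ------------------------------------------------------
    def level(self, volume: float | np.ndarray) -> float | np.ndarray:
        """Estimated output level (dBA) at a volume-control setting (%)."""
        arr = np.asarray(volume, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 100.0):
            raise DosimetryDomainError("volume-control setting outside [0, 100]%")
        lo, hi = self.volume_percent[0], self.volume_percent[-1]
        if np.any(arr < lo) or np.any(arr > hi):
            raise DosimetryDomainError(
                f"volume outside calibrated range [{lo}, {hi}]%: extrapolation refused"
            )
        out = self._interp(arr)
        return float(out) if np.isscalar(volume) or arr.ndim == 0 else out

    # -- inverse map ------------------------------------------------------
    def volume(self, level: float) -> float:
        """Volume-control setting (%) whose output level is ``level`` dBA."""
        lo, hi = self.level_dba[0], self.level_dba[-1]
        if not (lo - 1e-9 <= level <= hi + 1e-9):
            raise DosimetryDomainError(
                f"level {level:.3f} dBA outside calibrated range [{lo}, {hi}] dBA"
            )
        level = min(max(level, lo), hi)
        if level == lo:
            return float(self.volume_percent[0])
        if level == hi:
            return float(self.volume_percent[-1])
        f = self._interp
        return float(
            brentq(
                lambda v: float(f(v)) - level,
                self.volume_percent[0],
                self.volume_percent[-1],
                xtol=1e-9,
            )
        )

    def volume_array(self, levels: Iterable[float]) -> np.ndarray:
        return np.array([self.volume(float(x)) for x in levels])

    @classmethod
    def from_points(cls, points: Sequence[tuple[float, float]]) -> "CalibrationCurve":
        v, lv = zip(*points)
        return cls(tuple(v), tuple(lv))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        missing = {"volume_percent", "level_dba"} - set(df.columns)
        if missing:
            raise DosimetryDomainError(f"calibration file missing columns: {sorted(missing)}")
        return cls(tuple(df["volume_percent"]), tuple(df["level_dba"]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"volume_percent": self.volume_percent, "level_dba": self.level_dba}
        ).to_csv(path, index=False)


#: Default anchors. The top anchor is fixed by the device class ("about
#: 100 dBA" at full volume); the remaining anchors are declared fixture
#: values spanning the full dial, to be replaced with measured output levels
#: when a device-specific calibration table is available.
_DEFAULT_ANCHORS = ((0.0, 58.0), (25.0, 76.0), (50.0, 85.0), (75.0, 93.0), (100.0, 100.0))


def default_calibration() -> CalibrationCurve:
    """The package's replaceable default volume-to-level calibration."""
    return CalibrationCurve.from_points(_DEFAULT_ANCHORS)


def volume_to_level(curve: CalibrationCurve, volume: float) -> float:
    return float(curve.level(volume))


def level_to_volume(curve: CalibrationCurve, level: float) -> float:
    return curve.volume(level)


@dataclass(frozen=True)
class CareerSegment:
    """One career period's ear-piece usage pattern.

    ``volume_loud >= volume_normal`` is not required — respondents may report
    otherwise; such segments are flagged (``inverted_volumes``) but accepted.
    """

    duration_years: float
    hours_per_week: float
    prop_loud: float
    volume_loud: float
    volume_normal: float

    def __post_init__(self) -> None:
        if not self.duration_years > 0:
            raise DosimetryDomainError("duration_years must be > 0")
        if not (0 < self.hours_per_week <= 168):
            raise DosimetryDomainError("hours_per_week must lie in (0, 168]")
        if not (0 <= self.prop_loud <= 1):
            raise DosimetryDomainError("prop_loud must lie in [0, 1]")
        for name in ("volume_loud", "volume_normal"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise DosimetryDomainError(f"{name} must lie in [0, 100]%")

    @property
    def inverted_volumes(self) -> bool:
        return self.volume_loud < self.volume_normal


def segment_exposure_hours(seg: CareerSegment) -> tuple[float, float]:
    """(hours at the loud setting, hours at the normal setting) of actual
    noise exposure, i.e. wearing time scaled by the transmission duty cycle."""
    wearing_h = seg.duration_years * WORKING_YEAR_WEEKS * seg.hours_per_week
    hours_loud = wearing_h * seg.prop_loud * DUTY_CYCLE
    hours_normal = wearing_h * (1.0 - seg.prop_loud) * DUTY_CYCLE
    return hours_loud, hours_normal


def device_noise(segments: Iterable[CareerSegment], curve: CalibrationCurve) -> float:
    """Total career noise energy in units of one working year at 85 dBA.

    noise = sum_i h_i * 10^((L_i - 85)/10) / 1880 over the loud and normal
    sub-exposures of every segment.
    """
    total = 0.0
    for seg in segments:
        h_loud, h_norm = segment_exposure_hours(seg)
        total += h_loud * _energy(curve.level(seg.volume_loud))
        total += h_norm * _energy(curve.level(seg.volume_normal))
    return total / UNIT_HOURS


def device_weekly_level(noise: float, weeks_of_use: float) -> float:
    """Constant dBA level over 40 h/week x ``weeks_of_use`` carrying the same
    energy as ``noise`` units."""
    if noise <= 0 or weeks_of_use <= 0:
        raise UndefinedExposureError("weekly level undefined without positive exposure")
    return REF_LEVEL + 10.0 * np.log10(noise * UNIT_HOURS / (WORK_WEEK_H * weeks_of_use))


def average_exposure_level(noise: float, exposure_hours_total: float) -> float:
    """Energy-average sound level (dBA) over the actually exposed hours."""
    if noise <= 0 or exposure_hours_total <= 0:
        raise UndefinedExposureError("average level undefined without positive exposure")
    return REF_LEVEL + 10.0 * np.log10(noise * UNIT_HOURS / exposure_hours_total)


def device_volume_average(
    noise: float, exposure_hours_total: float, curve: CalibrationCurve
) -> float:
    """Energy-weighted average volume-control setting (%).

    Inverts the calibration at the energy-average level, so a career spent
    entirely at one setting returns that setting, and mixed careers weight
    high settings by their (disproportionate) energy contribution.
    """
    return curve.volume(average_exposure_level(noise, exposure_hours_total))


@dataclass(frozen=True)
class ExposureSummary:
    """Career exposure metrics; level/volume averages are ``None`` when the
    career carries no exposure (never reported as -inf)."""

    device_noise: float
    exposure_hours_total: float
    weeks_of_use: float
    weekly_level: float | None
    volume_average: float | None
    avg_level_during_exposure: float | None

    def __post_init__(self) -> None:
        if (self.device_noise == 0) != (self.exposure_hours_total == 0):
            raise DosimetryDomainError("device_noise is zero iff exposure hours are zero")


def summarize_career(
    segments: Sequence[CareerSegment],
    curve: CalibrationCurve,
    weeks_of_use: float | None = None,
) -> ExposureSummary:
    """All exposure metrics for one career.

    ``weeks_of_use`` defaults to total duration x 47 working weeks/year; pass
    a reported value to override.
    """
    noise = device_noise(segments, curve)
    hours = sum(sum(segment_exposure_hours(s)) for s in segments)
    weeks = (
        weeks_of_use
        if weeks_of_use is not None
        else sum(s.duration_years for s in segments) * WORKING_YEAR_WEEKS
    )
    if noise <= 0:
        return ExposureSummary(0.0, 0.0, weeks, None, None, None)
    return ExposureSummary(
        device_noise=noise,
        exposure_hours_total=hours,
        weeks_of_use=weeks,
        weekly_level=device_weekly_level(noise, weeks),
        volume_average=device_volume_average(noise, hours, curve),
        avg_level_during_exposure=average_exposure_level(noise, hours),
    )


def summarize_career_table(segments: pd.DataFrame, curve: CalibrationCurve) -> pd.DataFrame:
    """Vectorised per-participant exposure summary.

    ``segments`` uses the career-segments schema (participant_id,
    duration_years, hours_per_week, prop_loud, volume_loud, volume_normal).
    Returns one row per participant with columns device_noise,
    exposure_hours, weeks_of_use, weekly_level, volume_average,
    avg_level_during_exposure.
    """
    if segments.empty:
        return pd.DataFrame(
            columns=[
                "device_noise",
                "exposure_hours",
                "weeks_of_use",
                "weekly_level",
                "volume_average",
                "avg_level_during_exposure",
            ]
        )
    years = segments["duration_years"].to_numpy(float)
    hpw = segments["hours_per_week"].to_numpy(float)
    pl = segments["prop_loud"].to_numpy(float)
    wearing = years * WORKING_YEAR_WEEKS * hpw
    h_loud = wearing * pl * DUTY_CYCLE
    h_norm = wearing * (1.0 - pl) * DUTY_CYCLE
    e = h_loud * _energy(curve.level(segments["volume_loud"].to_numpy(float)))
    e = e + h_norm * _energy(curve.level(segments["volume_normal"].to_numpy(float)))
    per = pd.DataFrame(
        {
            "participant_id": segments["participant_id"].to_numpy(),
            "energy": e,
            "hours": h_loud + h_norm,
            "weeks": years * WORKING_YEAR_WEEKS,
        }
    ).groupby("participant_id", sort=True).sum()
    noise = per["energy"].to_numpy() / UNIT_HOURS
    hours = per["hours"].to_numpy()
    weeks = per["weeks"].to_numpy()
    with np.errstate(divide="ignore"):
        weekly = np.where(
            noise > 0,
            REF_LEVEL + 10.0 * np.log10(noise * UNIT_HOURS / (WORK_WEEK_H * weeks)),
            np.nan,
        )
        l_avg = np.where(
            noise > 0, REF_LEVEL + 10.0 * np.log10(noise * UNIT_HOURS / hours), np.nan
        )
    vol_avg = np.full_like(l_avg, np.nan)
    ok = np.isfinite(l_avg)
    if ok.any():
        vol_avg[ok] = curve.volume_array(l_avg[ok])
    return pd.DataFrame(
        {
            "device_noise": noise,
            "exposure_hours": hours,
            "weeks_of_use": weeks,
            "weekly_level": weekly,
            "volume_average": vol_avg,
            "avg_level_during_exposure": l_avg,
        },
        index=per.index,
    )
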