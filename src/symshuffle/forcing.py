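"""Seasonal environmental drivers: solar insolation and sea-surface
temperature.

Each driver follows a locality-specific sinusoid

    value(t) = a + b * sin(c * t + phi)

with mean level *a*, amplitude *b* and annual angular frequency
``c = 2 pi / period``.  A thermal-anomaly schedule can be overlaid on the
SST driver to represent bleaching-stress summers (e.g. +1 degC in July,
+1.5 degC in August, +1 degC in September).

Coefficients for a site are normally fitted from monthly climatology tables
with :func:`fit_seasonal_curve` (ordinary least squares at the fixed annual
frequency).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Tuple

import numpy as np

from . import timebase
from .errors import ParameterError

__all__ = [
    "SeasonalForcing",
    "AnomalySchedule",
    "FitResult",
    "DEFAULT_WARMING",
    "evaluate_driver",
    "apply_anomaly",
    "fit_seasonal_curve",
    "phase_for_peak",
]


def phase_for_peak(peak_day: float, period_days: float = timebase.DAYS_PER_YEAR) -> float:
    """Phase phi such that ``a + b sin(c t + phi)`` peaks at ``peak_day``."""
    return math.pi / 2.0 - 2.0 * math.pi * peak_day / period_days


@dataclass(frozen=True)
class SeasonalForcing:
    """One sinusoidal driver for one site.

    Parameters
    ----------
    mean_level : float
        Annual mean *a*, in driver units (degC or kW m-2 d-1).
    amplitude : float
        Seasonal half-range *b* (>= 0), same units.
    phase : float
        Phase phi in radians.
    period_days : float
        Length of the seasonal cycle; 360 days under the model calendar.
    """

    mean_level: float
    amplitude: float
    phase: float = 0.0
    period_days: float = float(timebase.DAYS_PER_YEAR)

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_level):
            raise ParameterError("mean_level must be finite")
        if not (self.amplitude >= 0.0 and math.isfinite(self.amplitude)):
            raise ParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        if not (self.period_days > 0.0):
            raise ParameterError(f"period_days must be > 0, got {self.period_days}")

    @property
    def angular_frequency(self) -> float:
        """c = 2 pi / period, in rad / day."""
        return 2.0 * math.pi / self.period_days

    def evaluate(self, t):
        """Driver value at day ``t`` (scalar or array)."""
        return self.mean_level + self.amplitude * np.sin(
            self.angular_frequency * np.asarray(t, dtype=float) + self.phase
        )


def evaluate_driver(f: SeasonalForcing, t):
    """Functional form of :meth:`SeasonalForcing.evaluate`."""
    return f.evaluate(t)


@dataclass(frozen=True)
class AnomalySchedule:
    """Monthly temperature offsets overlaid on the SST driver.

    ``entries`` maps 1-based month indices to additive deltas in degC.  In
    ``every_year`` mode the overlay repeats with the calendar year; in
    ``random_years`` mode each year is independently selected with
    ``probability`` using a counter-based draw keyed on ``(seed, year)``,
    so evaluation is order-independent and reproducible.
    """

    entries: Tuple[Tuple[int, float], ...]
    application_mode: Literal["every_year", "random_years"] = "every_year"
    probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for month, delta in self.entries:
            if not 1 <= int(month) <= timebase.MONTHS_PER_YEAR:
                raise ParameterError(f"anomaly month must be in 1..12, got {month}")
            if not math.isfinite(delta):
                raise ParameterError(f"anomaly delta must be finite, got {delta}")
        if self.application_mode not in ("every_year", "random_years"):
            raise ParameterError(
                f"unknown application_mode {self.application_mode!r}"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ParameterError("probability must be in [0, 1]")

    def _year_active(self, year: int) -> bool:
        if self.application_mode == "every_year":
            return True
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(int(year),))
        )
        return bool(rng.random() < self.probability)

    def delta_at(self, t: float) -> float:
        """Temperature offset applying at day ``t`` (0 outside scheduled
        months or in unselected years)."""
        if not self._year_active(timebase.year_of_day(t)):
            return 0.0
        month = timebase.month_of_day(t)
        for m, delta in self.entries:
            if int(m) == month:
                return float(delta)
        return 0.0


#: The elevated-temperature experiment: +1 degC July, +1.5 degC August,
#: +1 degC September, every simulated year.
DEFAULT_WARMING = AnomalySchedule(entries=((7, 1.0), (8, 1.5), (9, 1.0)))


def apply_anomaly(f: SeasonalForcing, sched: Optional[AnomalySchedule], t: float) -> float:
    """Baseline SST at ``t`` plus the scheduled anomaly (if any)."""
    base = float(f.evaluate(t))
    if sched is None:
        return base
    return base + sched.delta_at(t)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares sinusoid fit."""

    forcing: SeasonalForcing
    rss: float
    n_points: int
    residuals: np.ndarray = field(repr=False, compare=False, default=None)


def fit_seasonal_curve(
    samples: Iterable[Tuple[float, float]] | Sequence,
    period_days: float = float(timebase.DAYS_PER_YEAR),
) -> FitResult:
    """Fit ``a + b sin(c t + phi)`` to monthly climatology samples.

    ``samples`` is an iterable of ``(month, value)`` pairs with 1-based
    months; each sample is placed at its mid-month day.  The fit is linear
    least squares on ``[1, sin(c t), cos(c t)]`` at the fixed annual
    frequency, then converted to amplitude/phase form.

    Raises
    ------
    ParameterError
        If fewer than 4 points are supplied or any value is non-finite.
    """
    pairs = [(float(m), float(v)) for m, v in samples]
    if len(pairs) < 4:
        raise ParameterError(
            f"need at least 4 monthly points to fit a sinusoid, got {len(pairs)}"
        )
    months = np.array([m for m, _ in pairs])
    values = np.array([v for _, v in pairs])
    if not np.all(np.isfinite(values)):
        raise ParameterError("climatology values must be finite")

    t = (months - 0.5) * timebase.DAYS_PER_MONTH
    omega = 2.0 * math.pi / period_days
    design = np.column_stack([np.ones_like(t), np.sin(omega * t), np.cos(omega * t)])
    if np.ptp(values) == 0.0:
        # degenerate: constant series carries no seasonal signal
        warnings.warn(
            "constant climatology: fitted amplitude is 0", stacklevel=2
        )
        coef = np.array([values[0], 0.0, 0.0])
    else:
        coef, _, _, _ = np.linalg.lstsq(design, values, rcond=None)
    a, bs, bc = coef
    amplitude = float(math.hypot(bs, bc))
    # b sin(wt + phi) = (b cos phi) sin wt + (b sin phi) cos wt
    phase = float(math.atan2(bc, bs)) if amplitude > 0.0 else 0.0
    residuals = values - design @ coef
    rss = float(residuals @ residuals)
    forcing = SeasonalForcing(
        mean_level=float(a),
        amplitude=amplitude,
        phase=phase,
        period_days=period_days,
    )
    return FitResult(forcing=forcing, rss=rss, n_points=len(pairs), residuals=residuals)
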