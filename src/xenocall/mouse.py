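"""Mouse PDX tumor-volume trajectory analysis.

Secondary-recipient mice start treatment once the tumor reaches 100 mm^3;
response is judged from the caliper volume trajectory relative to the
volume at treatment start:

* MCR — tumor below the measurable cutoff (0.10 cm^3 = 100 mm^3) for the
  entire 3-week window after treatment cessation;
* CR  — below the cutoff at >=1 time point;
* PR  — regression >=50 % at >=1 time point but never below the cutoff;
* SD  — <50 % regression and end-of-study volume <=125 % of initial;
* PD  — <50 % regression and end-of-study volume >125 % of initial.

The group objective response is the median mouse call (ordering
PD < SD < PR < CR < MCR; an even-split median resolves to the worse
category).  Event-free survival uses tumor-volume quadrupling from the
start of treatment as the event, with log-linear interpolation of the
crossing time; curves are Kaplan-Meier estimates compared by log-rank
test.  Engraftment of a primary recipient is the first crossing of
1,000 mm^3; failure is no measurable tumor after 12 months.

All volumes are in mm^3 throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .calls import MOUSE_ORDER, ResponseCall

MEASURABLE_CUTOFF_MM3 = 100.0  # 0.10 cm^3
MCR_WINDOW_DAYS = 21.0  # 3 weeks past cessation of treatment
QUADRUPLING_FACTOR = 4.0
ENGRAFTMENT_THRESHOLD_MM3 = 1000.0
MAX_HOLDING_DAYS = 365.0  # 12-month maximum holding time


@dataclass(frozen=True)
class TumorVolumeSeries:
    """One mouse's timestamped tumor volumes plus the treatment window."""

    mouse_id: str
    model_id: str
    arm: str
    measurements: tuple[tuple[float, float], ...]  # (day, volume_mm3)
    treatment_start_day: float = 0.0
    treatment_end_day: float = 0.0
    study_end_day: float = 0.0

    def __post_init__(self) -> None:
        meas = tuple((float(d), float(v)) for d, v in self.measurements)
        object.__setattr__(self, "measurements", meas)
        days = [d for d, _ in meas]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement days must be strictly ascending")
        if any(v < 0 for _, v in meas):
            raise ValueError("volumes must be non-negative")
        if not self.treatment_start_day <= self.treatment_end_day <= self.study_end_day:
            raise ValueError(
                "need treatment_start_day <= treatment_end_day <= study_end_day"
            )
        if not any(d <= self.treatment_start_day for d in days):
            raise ValueError("need a measurement at or before treatment start")

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(d for d, _ in self.measurements)

    @property
    def volumes(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.measurements)


class SurvivalRecord(NamedTuple):
    """Time to tumor quadrupling (event) or censoring for one mouse."""

    mouse_id: str
    time_days: float
    event: bool


def _interp_volume(series: TumorVolumeSeries, day: float) -> float:
    """Volume at ``day``, log-linear between bracketing measurements."""
    days, vols = series.days, series.volumes
    for (d0, v0), (d1, v1) in zip(series.measurements, series.measurements[1:]):
        if d0 <= day <= d1:
            if day == d0:
                return v0
            if day == d1:
                return v1
            f = (day - d0) / (d1 - d0)
            if v0 > 0 and v1 > 0:
                return math.exp((1 - f) * math.log(v0) + f * math.log(v1))
            return (1 - f) * v0 + f * v1
    if day <= days[0]:
        return vols[0]
    return vols[-1]


def initial_volume(series: TumorVolumeSeries) -> float:
    """Volume at the start of treatment (interpolated if needed)."""
    v0 = _interp_volume(series, series.treatment_start_day)
    if v0 <= 0:
        raise ValueError("zero initial volume at treatment start")
    return v0


def classify_mouse_trajectory(
    series: TumorVolumeSeries,
    measurable_cutoff_mm3: float = MEASURABLE_CUTOFF_MM3,
    mcr_window_days: float = MCR_WINDOW_DAYS,
) -> ResponseCall:
    """Classify one tumor-volume trajectory as MCR/CR/PR/SD/PD.

    Precedence is MCR > CR > PR > SD/PD.  Regression is measured against
    the treatment-start volume; only measurements in the on-study window
    [treatment start, study end] are considered.  MCR requires at least
    one measurement inside the post-cessation window.
    """
    v0 = initial_volume(series)
    on_study = [
        (d, v)
        for d, v in series.measurements
        if series.treatment_start_day <= d <= series.study_end_day
    ]
    if not on_study:
        raise ValueError("no measurements in the on-study window")
    vols = [v for _, v in on_study]
    nadir = min(vols)
    end_volume = vols[-1]

    window_lo = series.treatment_end_day
    window_hi = series.treatment_end_day + mcr_window_days
    in_window = [v for d, v in on_study if window_lo <= d <= window_hi]
    if in_window and all(v < measurable_cutoff_mm3 for v in in_window):
        return ResponseCall("mouse", "MCR")
    if nadir < measurable_cutoff_mm3:
        return ResponseCall("mouse", "CR")
    if (v0 - nadir) / v0 * 100 >= 50:
        return ResponseCall("mouse", "PR")
    if end_volume <= 1.25 * v0:
        return ResponseCall("mouse", "SD")
    return ResponseCall("mouse", "PD")


def group_objective_response(calls: Sequence[ResponseCall]) -> ResponseCall:
    """Median mouse response; even-split medians resolve to the worse category."""
    if not calls:
        raise ValueError("no calls to summarize")
    if any(c.system != "mouse" for c in calls):
        raise ValueError("group_objective_response expects mouse calls")
    ranks = sorted(MOUSE_ORDER.index(c.category) for c in calls)
    median_rank = ranks[(len(ranks) - 1) // 2]  # lower middle = worse
    return ResponseCall("mouse", MOUSE_ORDER[median_rank])


def _crossing_time(
    measurements: Sequence[tuple[float, float]], threshold: float
) -> float | None:
    """First time the volume reaches ``threshold`` (log-linear interpolation)."""
    for (d0, v0), (d1, v1) in zip(measurements, measurements[1:]):
        if v0 >= threshold:
            return d0
        if v1 >= threshold:
            if v0 > 0 and v1 > 0:
                f = (math.log(threshold) - math.log(v0)) / (
                    math.log(v1) - math.log(v0)
                )
            else:
                f = (threshold - v0) / (v1 - v0)
            return d0 + f * (d1 - d0)
    if measurements and measurements[0][1] >= threshold:
        return measurements[0][0]
    return None


def event_time_quadrupling(series: TumorVolumeSeries) -> SurvivalRecord:
    """Time from treatment start to tumor-volume quadrupling.

    Crossing times are interpolated log-linearly between the bracketing
    measurements; a trajectory that never quadruples is censored at its
    last on-study measurement.
    """
    v0 = initial_volume(series)
    start = series.treatment_start_day
    post = [(d, v) for d, v in series.measurements if d >= start]
    t = _crossing_time(post, QUADRUPLING_FACTOR * v0)
    if t is not None:
        return SurvivalRecord(series.mouse_id, t - start, True)
    return SurvivalRecord(series.mouse_id, post[-1][0] - start, False)


def km_estimate(records: Sequence[SurvivalRecord]) -> Callable[[float], float]:
    """Kaplan-Meier survival estimate as a right-continuous step function.

    Returns a callable ``S(t)``; the fitted ``lifelines`` estimator is
    attached as ``S.fitter``.
    """
    if not records:
        raise ValueError("no survival records")
    if any(r.time_days <= 0 for r in records):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(
        [r.time_days for r in records],
        event_observed=[r.event for r in records],
    )

    def survival(t: float) -> float:
        return float(kmf.predict(t))

    survival.fitter = kmf  # type: ignore[attr-defined]
    return survival


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        warnings.warn("no events in either group; log-rank is degenerate")
        return 0.0, 1.0
    res = _ll_logrank(
        [r.time_days for r in group_a],
        [r.time_days for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if math.isnan(stat):
        return 0.0, 1.0
    return stat, p


def engraftment_status(
    series: TumorVolumeSeries,
    threshold_mm3: float = ENGRAFTMENT_THRESHOLD_MM3,
    holding_days: float = MAX_HOLDING_DAYS,
) -> tuple[str, float | None]:
    """Primary-recipient engraftment call.

    Engrafted at the first (log-linear) crossing of ``threshold_mm3``;
    failed when no crossing occurs within the holding period.
    """
    t = _crossing_time(series.measurements, threshold_mm3)
    if t is not None:
        return "engrafted", t
    return "failed", None
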