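"""Free-running period and light-pulse phase-shift estimation.

Daily activity onsets of a nocturnal rodent in constant darkness drift by
(tau - 24) h per day; the free-running period tau is therefore recovered as
24 h plus the least-squares slope of onset time against day. A light-pulse
phase shift is the offset between the pre-pulse regression line,
extrapolated across the pulse, and the post-pulse (steady-state) line.
Convention: phase advances (earlier onsets) are positive, delays negative;
activity onset defines circadian time 12 and circadian hours scale with
tau (CT = 12 + elapsed * 24 / tau).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import FhmapError

#: Period at or below which an animal is classed as a short-period mutant.
MUTANT_TAU_THRESHOLD_H = 23.5

#: Sanity band for mammalian free-running periods (hours).
TAU_SANITY_BAND = (16.0, 32.0)


class InsufficientDataError(FhmapError):
    pass


@dataclass(frozen=True)
class OnsetSeries:
    """Daily activity-onset times around an optional light pulse.

    ``onsets[i]`` is the onset clock time (hours, unwrapped: free to drift
    past midnight without modular folding) on ``days[i]``. ``pulse_time``
    is the clock time of the pulse on ``pulse_day``.
    """

    days: Tuple[int, ...]
    onsets: Tuple[float, ...]
    pulse_day: Optional[int] = None
    pulse_time: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.onsets):
            raise ValueError("days and onsets must have equal length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("day indices must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str, pulse_day: Optional[int] = None,
                 pulse_time: Optional[float] = None) -> "OnsetSeries":
        df = pd.read_csv(path)
        return cls(
            days=tuple(int(d) for d in df["day"]),
            onsets=tuple(float(o) for o in df["onset_hours"]),
            pulse_day=pulse_day,
            pulse_time=pulse_time,
        )

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"day": self.days, "onset_hours": self.onsets}).to_csv(
            path, index=False
        )

    def split_at_pulse(self, transient_days: int = 0, steady_days: int = 10
                       ) -> Tuple["OnsetSeries", "OnsetSeries"]:
        if self.pulse_day is None:
            raise InsufficientDataError("series has no pulse day")
        pre_idx = [i for i, d in enumerate(self.days) if d <= self.pulse_day]
        first_post = self.pulse_day + 1 + transient_days
        post_idx = [
            i
            for i, d in enumerate(self.days)
            if first_post <= d <= self.pulse_day + transient_days + steady_days
        ]
        pre = OnsetSeries(
            tuple(self.days[i] for i in pre_idx), tuple(self.onsets[i] for i in pre_idx)
        )
        post = OnsetSeries(
            tuple(self.days[i] for i in post_idx), tuple(self.onsets[i] for i in post_idx)
        )
        return pre, post


@dataclass(frozen=True)
class PhaseShiftResult:
    tau_pre: float
    tau_post: float
    shift: float  # hours; positive = advance, negative = delay
    pulse_ct: Optional[float]  # circadian time of the pulse in [0, 24)

    @property
    def direction(self) -> str:
        if abs(self.shift) < 1e-9:
            return "none"
        return "advance" if self.shift > 0 else "delay"


def _fit_line(days: Sequence[int], onsets: Sequence[float]) -> Tuple[float, float]:
    """(slope, intercept) of onset vs day by least squares."""
    if len(days) < 3:
        raise InsufficientDataError(
            f"need >= 3 onsets for a regression, got {len(days)}"
        )
    slope, intercept = np.polyfit(np.asarray(days, float), np.asarray(onsets, float), 1)
    return float(slope), float(intercept)


def estimate_period(series: OnsetSeries) -> float:
    """Free-running period: 24 h + daily onset drift."""
    slope, _ = _fit_line(series.days, series.onsets)
    return 24.0 + slope


def pulse_circadian_time(series: OnsetSeries, tau: float) -> float:
    """Circadian time of the light pulse, with onset defined as CT12.

    The pulse-day onset is projected from the pre-pulse regression and the
    elapsed real time since that onset is converted to circadian hours
    (24 circadian hours per tau real hours).
    """
    if series.pulse_day is None or series.pulse_time is None:
        raise InsufficientDataError("series has no pulse")
    pre, _ = series.split_at_pulse()
    slope, intercept = _fit_line(pre.days, pre.onsets)
    projected_onset = slope * series.pulse_day + intercept
    elapsed = series.pulse_time - projected_onset
    return float((12.0 + elapsed * 24.0 / tau) % 24.0)


def estimate_phase_shift(
    series: OnsetSeries, transient_days: int = 0, steady_days: int = 10
) -> PhaseShiftResult:
    """Pre/post regression phase shift around a light pulse.

    Both segments are extrapolated to the first post-pulse cycle; the shift
    is (pre-predicted - post-predicted) onset, so an earlier post-pulse
    onset yields a positive value (advance). The shift is reduced modulo
    the pre-pulse period into (-tau/2, tau/2].
    """
    pre, post = series.split_at_pulse(transient_days, steady_days)
    pre_slope, pre_int = _fit_line(pre.days, pre.onsets)
    post_slope, post_int = _fit_line(post.days, post.onsets)
    tau_pre = 24.0 + pre_slope
    tau_post = 24.0 + post_slope
    d0 = series.pulse_day + 1 + transient_days  # first steady post-pulse cycle
    shift = (pre_slope * d0 + pre_int) - (post_slope * d0 + post_int)
    shift = shift - tau_pre * np.floor(shift / tau_pre + 0.5)  # into (-tau/2, tau/2]
    if shift == -tau_pre / 2.0:
        shift += tau_pre
    ct = None
    if series.pulse_time is not None:
        ct = pulse_circadian_time(series, tau_pre)
    return PhaseShiftResult(
        tau_pre=tau_pre, tau_post=tau_post, shift=float(shift), pulse_ct=ct
    )


def classify_phenotype(tau: float, threshold: float = MUTANT_TAU_THRESHOLD_H) -> str:
    """'mutant_short_period' iff tau <= threshold (inclusive), else 'wild_type'."""
    lo, hi = TAU_SANITY_BAND
    if not (lo < tau < hi):
        raise FhmapError(f"tau {tau} outside sanity band {TAU_SANITY_BAND}")
    return "mutant_short_period" if tau <= threshold else "wild_type"


def segregation_summary(n_mutant: int, n_total: int) -> dict:
    """Mendelian segregation report for an F2 cohort.

    Returns the observed mutant-phenotype percentage alongside the 25%
    recessive expectation.
    """
    if not (0 <= n_mutant <= n_total) or n_total == 0:
        raise ValueError("need 0 <= n_mutant <= n_total, n_total > 0")
    fraction = n_mutant / n_total
    return {
        "n_mutant": n_mutant,
        "n_total": n_total,
        "mutant_fraction": fraction,
        "mutant_percent": round(100.0 * fraction, 1),
        "expected_recessive_percent": 25.0,
    }


def result_to_json(result: PhaseShiftResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "tau_pre_h": result.tau_pre,
                "tau_post_h": result.tau_post,
                "shift_h": result.shift,
                "direction": result.direction,
                "pulse_ct_h": result.pulse_ct,
            },
            fh,
            indent=2,
        )
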