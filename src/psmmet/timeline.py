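"""Somite-formation rate and the map from PSM position to developmental
time.

Because somites form at regular intervals and the PSM is spatiotemporally
ordered, the rostro-caudal position of an event can be rescaled to the
approximate time remaining before the cells at that position reach the
forming-somite border.  The rescaling comes from time-lapse tracks of a
labelled cell cohort entering the caudal PSM: the front-to-border
distance, normalized by the concurrent PSM length, is a trajectory of
position (%) against time that is slow at first and then advances at a
constant faster rate.  We fit a continuous two-segment piecewise-linear
model with the breakpoint chosen by exhaustive grid search, test it
against a single line with a nested F-test, and invert the fitted
trajectory to map position -> hours-before-segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .outline_io import TimepointRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SomiteRate:
    """Per-embryo somite-formation intervals and their cohort mean."""

    intervals_min: tuple[float, ...]
    mean_interval_min: float

    @property
    def mean_interval_rounded(self) -> int:
        return int(round(self.mean_interval_min))


def somite_interval(tracks: Sequence[tuple[int, float]]) -> SomiteRate:
    """Mean somite-formation interval from (somites_formed, duration_min).

    Each embryo contributes duration/somites; the cohort value is the
    arithmetic mean of the per-embryo intervals.  Embryos with zero
    somites are excluded with a warning.

    >>> somite_interval([(28, 2050.0), (27, 1690.0)]).mean_interval_rounded
    68
    """
    intervals = []
    for somites, duration in tracks:
        if somites < 1:
            logger.warning("embryo with %d somites excluded", somites)
            continue
        if duration <= 0:
            raise ValueError("duration must be > 0")
        intervals.append(duration / somites)
    if not intervals:
        raise ValueError("no usable embryos")
    return SomiteRate(
        intervals_min=tuple(intervals),
        mean_interval_min=float(np.mean(intervals)),
    )


class TimeEstimate(NamedTuple):
    hours_before_segmentation: float
    extrapolated: bool


@dataclass
class PositionTimeMap:
    """Fitted position-vs-time trajectory of the labelled-cell front.

    ``position(t) = c + r_slow * t`` for ``t <= breakpoint_h`` and
    continues with slope ``r_fast`` after it (rates in % PSM per hour).
    ``t100_h`` is the fitted time at which the front reaches the border
    (position 100%); remaining time at position p is ``t100_h - t(p)``.
    """

    breakpoint_h: float
    slow_phase_rate: float  # % PSM / h
    fast_phase_rate: float
    intercept: float  # position at t = 0
    t100_h: float
    observed_min_percent: float
    observed_max_percent: float
    biphasic: bool = True
    f_statistic: float = np.nan
    p_value: float = np.nan

    def position_at(self, t_h: float) -> float:
        t = np.asarray(t_h, dtype=float)
        return (
            self.intercept
            + self.slow_phase_rate * np.minimum(t, self.breakpoint_h)
            + self.fast_phase_rate * np.maximum(t - self.breakpoint_h, 0.0)
        )

    def time_at(self, position_percent: float) -> float:
        """Time (h since track start) at which the front passes a position."""
        p = float(position_percent)
        p_break = self.position_at(self.breakpoint_h)
        if p <= p_break:
            if self.slow_phase_rate <= 0:
                return 0.0
            return (p - self.intercept) / self.slow_phase_rate
        return self.breakpoint_h + (p - p_break) / self.fast_phase_rate


def _piecewise_design(t: np.ndarray, tb: float) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, np.maximum(t - tb, 0.0)])


def fit_position_time(
    records: Sequence[TimepointRecord],
    *,
    alpha: float = 0.05,
    normalize: bool = True,
) -> PositionTimeMap:
    """Fit the biphasic position-vs-time trajectory of a time-lapse track.

    The labelled-front position is ``100 * (1 - dii/psm_length)`` per
    timepoint (or the raw front-to-border distance when
    ``normalize=False``).  The continuous two-segment model is fitted by
    linear least squares at every candidate breakpoint (interior observed
    timepoints, at least three points per side); the breakpoint with the
    smallest RSS wins.  If the two-segment model does not beat a single
    line (nested F-test with 2 extra parameters at level ``alpha``), a
    single-phase map is returned flagged ``biphasic=False``.
    """
    if len(records) < 10:
        raise ValueError("need >= 10 timepoints spanning both phases")
    t = np.array([r.t_minutes for r in records], dtype=float) / 60.0
    if normalize:
        pos = np.array(
            [100.0 * (1.0 - r.dii_front_to_border_um / r.psm_length_um)
             for r in records]
        )
    else:
        pos = np.array([r.dii_front_to_border_um for r in records])

    n = len(t)
    one_seg = np.polyfit(t, pos, 1)
    rss1 = float(((pos - np.polyval(one_seg, t)) ** 2).sum())

    best = None  # (rss, tb, beta)
    for tb in t[3:-3]:
        X = _piecewise_design(t, tb)
        beta, *_ = np.linalg.lstsq(X, pos, rcond=None)
        rss = float(((pos - X @ beta) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, float(tb), beta)
    rss2, tb, beta = best
    tss = float(((pos - pos.mean()) ** 2).sum())
    if rss1 <= 1e-10 * max(tss, 1.0):
        # a single line already explains the track to working precision
        f, p = 0.0, 1.0
    else:
        # two-segment adds the breakpoint and a second slope over the line
        f = max(0.0, (rss1 - rss2) / 2.0 / max(rss2 / (n - 4), 1e-300))
        p = float(stats.f.sf(f, 2, n - 4))

    if p >= alpha:
        logger.info("two-segment fit not better than one segment (p=%.3g)", p)
        slope, intercept = float(one_seg[0]), float(one_seg[1])
        rate = max(slope, 1e-12)
        t100 = (100.0 - intercept) / rate
        return PositionTimeMap(
            breakpoint_h=float(t[len(t) // 2]),
            slow_phase_rate=slope, fast_phase_rate=slope,
            intercept=intercept, t100_h=t100,
            observed_min_percent=float(pos.min()),
            observed_max_percent=float(pos.max()),
            biphasic=False, f_statistic=f, p_value=p,
        )

    intercept, slow, dfast = (float(b) for b in beta)
    fast = slow + dfast
    p_break = intercept + slow * tb
    t100 = tb + (100.0 - p_break) / fast if fast > 0 else np.inf
    return PositionTimeMap(
        breakpoint_h=tb,
        slow_phase_rate=slow, fast_phase_rate=fast,
        intercept=intercept, t100_h=float(t100),
        observed_min_percent=float(pos.min()),
        observed_max_percent=float(pos.max()),
        biphasic=True, f_statistic=f, p_value=p,
    )


def position_to_time(
    ptmap: PositionTimeMap, position_percent: float
) -> TimeEstimate:
    """Hours remaining before material at a PSM position segments.

    Monotone in position: later (higher-%) positions have less time
    remaining; position 100% maps to 0 h.  Positions outside the range the
    track actually covered are still computed from the fitted model but
    flagged ``extrapolated``.
    """
    if not 0.0 <= position_percent <= 100.0:
        raise ValueError("position must be in [0, 100]%")
    remaining = ptmap.t100_h - ptmap.time_at(position_percent)
    extrapolated = not (
        ptmap.observed_min_percent <= position_percent <= ptmap.observed_max_percent
    )
    return TimeEstimate(max(0.0, float(remaining)), extrapolated)


def annotate_landmarks(
    landmark_table, ptmap: PositionTimeMap, position_column: str = "x_inflection"
):
    """Add an ``hours_before_segmentation`` column to a landmark table."""
    table = landmark_table.copy()
    hours, flags = [], []
    for p in table[position_column]:
        if np.isnan(p):
            hours.append(np.nan)
            flags.append(False)
            continue
        est = position_to_time(ptmap, float(np.clip(p, 0.0, 100.0)))
        hours.append(est.hours_before_segmentation)
        flags.append(est.extrapolated or not 0.0 <= p <= 100.0)
    table["hours_before_segmentation"] = hours
    table["time_extrapolated"] = flags
    return table
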