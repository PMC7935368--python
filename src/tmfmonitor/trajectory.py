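"""Per-pixel change-trajectory analysis.

This is the inference core of the package: given the dated sequence of
single-date labels of one pixel (potential moist forest / potential disruption
/ invalid), it

1. qualifies a *baseline* (initial reference period) that defines whether the
   pixel belonged to the initial tropical moist forest (TMF) extent,
2. groups disruption observations of the monitoring period into
   *disturbance events* (episodes separated by confirmed recovery gaps),
3. derives duration, intensity (number of disruption observations) and
   recurrence metrics, and
4. assigns the end-of-record *transition class* by a fixed rule sequence.

The rule thresholds live in :class:`Thresholds` and mirror the published
expert-system constants: disturbances whose impact is visible for more than
900 days are deforestation processes; shorter ones are degradation (short
subclass <= 365 days, long subclass 366-900 days); regrowth requires at least
three years (1095 days) of re-established forest cover; disturbances initiated
after 2016 follow dedicated "recent" rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .labels import (
    DecadeTag,
    ObservationLabel,
    SUBCLASS_DEGR_LONG,
    SUBCLASS_DEGR_SHORT,
    SUBCLASS_NONE,
    SUBCLASS_RECENT_DEFORESTATION,
    SUBCLASS_RECENT_DEGRADATION,
    SUBCLASS_REGROWTH_10_20,
    SUBCLASS_REGROWTH_3_10,
    TransitionClass,
    decade_of,
)

_EPOCH_YEAR = 1970


def as_day_numbers(dates: np.ndarray | Sequence) -> np.ndarray:
    """Convert datetime64 (or ISO strings) to integer days since 1970-01-01."""
    arr = np.asarray(dates)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return arr.astype("datetime64[D]").astype(np.int64)


def day_number(date: str | np.datetime64) -> int:
    return int(np.datetime64(date, "D").astype(np.int64))


def year_of_day(day: np.ndarray | int):
    """Calendar year of a day number (vectorized)."""
    d = np.asarray(day).astype("timedelta64[D]") + np.datetime64("1970-01-01")
    return d.astype("datetime64[Y]").astype(np.int64) + _EPOCH_YEAR


def month_of_day(day: np.ndarray | int):
    d = np.asarray(day).astype("timedelta64[D]") + np.datetime64("1970-01-01")
    return d.astype("datetime64[M]").astype(np.int64) % 12 + 1


def year_end_day(year: int) -> int:
    """Day number of 31 December of ``year``."""
    return day_number(f"{year}-12-31")


@dataclass(frozen=True)
class Thresholds:
    """Decision-rule constants of the trajectory classifier.

    All day-valued constants are kept verbatim as published (900 days for the
    deforestation duration threshold, 365/366/1095 for the one- and
    three-year limits) rather than being normalized to one year convention.
    """

    short_max_days: int = 365          # degradation short/long split
    defor_min_days: int = 900          # > 900 d of visible impact => deforestation
    recovery_gap_days: int = 365       # disruption-free, forest-confirmed gap splitting events
    regrowth_min_days: int = 1095      # >= 3 yr of forest cover to call regrowth
    predefor_clear_days: int = 900     # land must stay cleared >= 2.5 yr before regrowth counts
    recent_start_year: int = 2017      # events initiated after 2016 use the recent rules
    recent_duration_days: int = 366    # 2017-2018 onsets: >= 366 d => deforestation
    recent_disruption_count: int = 10  # final-year onsets: >= 10 disruptions => deforestation
    baseline_rule_a_years: int = 4
    baseline_rule_a_obs: int = 3
    baseline_rule_b_years: int = 5
    baseline_rule_b_obs: int = 2
    monitoring_end: str = "2019-12-31"

    def __post_init__(self) -> None:
        if not (0 < self.short_max_days < self.defor_min_days):
            raise ValueError("need 0 < short_max_days < defor_min_days")
        for name in (
            "recovery_gap_days",
            "regrowth_min_days",
            "recent_duration_days",
            "recent_disruption_count",
            "baseline_rule_a_years",
            "baseline_rule_a_obs",
            "baseline_rule_b_years",
            "baseline_rule_b_obs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def monitoring_end_day(self) -> int:
        return day_number(self.monitoring_end)

    @property
    def monitoring_end_year(self) -> int:
        return int(year_of_day(self.monitoring_end_day))


@dataclass
class PixelSeries:
    """Date-ordered single-date labels of one pixel."""

    dates: np.ndarray   # int64 day numbers, strictly increasing
    labels: np.ndarray  # ObservationLabel codes, same length
    row: int = 0
    col: int = 0

    def __post_init__(self) -> None:
        self.dates = as_day_numbers(self.dates)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.dates.shape != self.labels.shape:
            raise ValueError("dates and labels must have equal length")
        if self.dates.size and np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")

    def __len__(self) -> int:
        return int(self.dates.size)

    def valid_counts_per_year(self) -> dict[int, int]:
        valid = self.labels != ObservationLabel.INVALID
        if not valid.any():
            return {}
        years = year_of_day(self.dates[valid])
        uniq, counts = np.unique(years, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


@dataclass
class BaselineResult:
    qualifies: bool
    baseline_start: Optional[int] = None  # day number of first valid observation
    baseline_end: Optional[int] = None    # day number, 31 Dec of qualification-window end
    rule_used: str = "none"               # "A", "B" or "none"
    is_tmf: bool = False
    seasonal_nonforest: bool = False
    fail_reason: Optional[str] = None


@dataclass(frozen=True)
class DisturbanceEvent:
    """One disruption episode: first/last disruption date and intensity."""

    start_day: int
    end_day: int
    n_disruptions: int

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValueError("event end before start")
        if self.n_disruptions < 1:
            raise ValueError("event needs at least one disruption observation")

    @property
    def duration_days(self) -> int:
        return self.end_day - self.start_day

    @property
    def start_year(self) -> int:
        return int(year_of_day(self.start_day))

    @property
    def end_year(self) -> int:
        return int(year_of_day(self.end_day))


@dataclass
class TrajectoryRecord:
    """Per-pixel outcome of the trajectory classification."""

    transition_class: Optional[TransitionClass]
    subclass: int = SUBCLASS_NONE
    decade: DecadeTag = DecadeTag.NONE
    events: list[DisturbanceEvent] = field(default_factory=list)
    recurrence: Optional[float] = None
    defor_after_degradation: bool = False
    provisional: Optional[str] = None       # RECENT pixels: "degradation"/"deforestation"
    regrowth_start_day: Optional[int] = None
    baseline: Optional[BaselineResult] = None
    monitoring_start_day: Optional[int] = None

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def first_disruption_day(self) -> Optional[int]:
        return self.events[0].start_day if self.events else None

    @property
    def last_disruption_day(self) -> Optional[int]:
        return self.events[-1].end_day if self.events else None

    def deforestation_event(self, th: "Thresholds") -> Optional[DisturbanceEvent]:
        """Last event qualifying as a deforestation process, if any."""
        for ev in reversed(self.events):
            if ev.duration_days > th.defor_min_days:
                return ev
        return None


def determine_baseline(series: PixelSeries, th: Thresholds) -> BaselineResult:
    """Qualify the initial reference period of one pixel.

    Rule A requires 4 consecutive calendar years with >= 3 valid observations
    each; rule B requires 5 consecutive years with >= 2.  The earliest window
    (by end year; rule A wins ties) starting at or after the first valid
    observation is used.  The baseline runs from the first valid observation
    to 31 December of the window's final year.
    """
    valid = series.labels != ObservationLabel.INVALID
    if not valid.any():
        return BaselineResult(qualifies=False, fail_reason="no_valid_observations")
    vdates = series.dates[valid]
    vyears = year_of_day(vdates)
    first_year = int(vyears[0])
    last_year = th.monitoring_end_year
    n_years = last_year - first_year + 1
    if n_years < th.baseline_rule_a_years:
        return BaselineResult(qualifies=False, fail_reason="record_too_short")
    counts = np.bincount(vyears - first_year, minlength=n_years)

    def earliest_window(win: int, min_obs: int) -> Optional[int]:
        ok = counts >= min_obs
        for s in range(0, n_years - win + 1):
            if ok[s : s + win].all():
                return first_year + s + win - 1  # end year
        return None

    end_a = earliest_window(th.baseline_rule_a_years, th.baseline_rule_a_obs)
    end_b = earliest_window(th.baseline_rule_b_years, th.baseline_rule_b_obs)
    if end_a is None and end_b is None:
        return BaselineResult(qualifies=False, fail_reason="never_qualified")
    if end_b is None or (end_a is not None and end_a <= end_b):
        rule, end_year = "A", end_a
    else:
        rule, end_year = "B", end_b

    baseline_start = int(vdates[0])
    baseline_end = year_end_day(int(end_year))
    in_baseline = vdates <= baseline_end
    blabels = series.labels[valid][in_baseline]
    is_tmf = bool((blabels == ObservationLabel.FOREST).all())

    seasonal = False
    if not is_tmf:
        disr = blabels == ObservationLabel.DISRUPTION
        if disr.any():
            ddays = vdates[in_baseline][disr]
            months = month_of_day(ddays)
            years = year_of_day(ddays)
            for m in np.unique(months):
                if len(np.unique(years[months == m])) >= 2:
                    seasonal = True
                    break

    return BaselineResult(
        qualifies=True,
        baseline_start=baseline_start,
        baseline_end=baseline_end,
        rule_used=rule,
        is_tmf=is_tmf,
        seasonal_nonforest=seasonal,
    )


def segment_events(
    series: PixelSeries, monitoring_start: int, th: Thresholds
) -> list[DisturbanceEvent]:
    """Group monitoring-period disruptions into disturbance events.

    Two consecutive disruption observations belong to different events iff
    they are separated by at least ``recovery_gap_days`` *and* at least one
    valid forest observation lies strictly between them: an invalid-only gap
    carries no evidence of recovery and does not split an episode.
    """
    end_day = th.monitoring_end_day
    window = (series.dates >= monitoring_start) & (series.dates <= end_day)
    labels = series.labels[window]
    dates = series.dates[window]
    ddays = dates[labels == ObservationLabel.DISRUPTION]
    if ddays.size == 0:
        return []
    fdays = dates[labels == ObservationLabel.FOREST]

    events: list[DisturbanceEvent] = []
    start = prev = int(ddays[0])
    count = 1
    for d in ddays[1:]:
        d = int(d)
        gap = d - prev
        if gap >= th.recovery_gap_days and np.any((fdays > prev) & (fdays < d)):
            events.append(DisturbanceEvent(start, prev, count))
            start, count = d, 1
        else:
            count += 1
        prev = d
    events.append(DisturbanceEvent(start, prev, count))
    return events


def recurrence(events: Sequence[DisturbanceEvent], disruption_days: np.ndarray) -> float:
    """Ratio of years containing a disruption to the inclusive first-to-last
    disruption year span.  Undefined (raises) without any disruption."""
    if disruption_days.size == 0:
        raise ValueError("recurrence undefined without disruption observations")
    years = year_of_day(disruption_days)
    span = int(years.max()) - int(years.min()) + 1
    return float(len(np.unique(years)) / span)


def _monitoring_disruption_days(
    series: PixelSeries, monitoring_start: int, th: Thresholds
) -> np.ndarray:
    m = (
        (series.dates >= monitoring_start)
        & (series.dates <= th.monitoring_end_day)
        & (series.labels == ObservationLabel.DISRUPTION)
    )
    return series.dates[m]


def classify_trajectory(
    series: PixelSeries,
    baseline: BaselineResult,
    events: list[DisturbanceEvent],
    th: Thresholds,
) -> TrajectoryRecord:
    """Assign the transition class of a qualified pixel.

    Rule order (TMF baselines):

    1. no events -> UNDISTURBED;
    2. an event with impact visible > 900 days is a deforestation process:
       FOREST_REGROWTH when followed by >= 1095 days of uninterrupted forest
       observations, else DEFORESTED; tagged *after degradation* when an
       earlier, separate event exists;
    3. events initiated after 2016 -> RECENT, split provisionally into
       deforestation/degradation by the recent-year rules;
    4. otherwise DEGRADED (short <= 365 d, else long), tagged with the decade
       of the last disruption.

    Non-TMF baselines map to OTHER_LC, or to VEG_REGROWTH when followed by at
    least three years of sustained forest cover.
    """
    if not baseline.qualifies:
        raise ValueError("classify_trajectory requires a qualified baseline")
    monitoring_start = int(baseline.baseline_end) + 1
    end_day = th.monitoring_end_day

    if not baseline.is_tmf:
        return _classify_non_tmf(series, baseline, th)

    rec = TrajectoryRecord(
        transition_class=TransitionClass.UNDISTURBED,
        events=list(events),
        baseline=baseline,
        monitoring_start_day=monitoring_start,
    )
    if not events:
        return rec

    ddays = _monitoring_disruption_days(series, monitoring_start, th)
    rec.recurrence = recurrence(events, ddays)

    defor_idx = None
    for i in range(len(events) - 1, -1, -1):
        if events[i].duration_days > th.defor_min_days:
            defor_idx = i
            break

    if defor_idx is not None:
        defor = events[defor_idx]
        rec.defor_after_degradation = defor_idx > 0
        later_disruption = defor_idx < len(events) - 1
        regrowth_start = _first_forest_after(series, defor.end_day, end_day)
        if (
            not later_disruption
            and defor.duration_days >= th.predefor_clear_days
            and regrowth_start is not None
            and end_day - regrowth_start >= th.regrowth_min_days
        ):
            rec.transition_class = TransitionClass.FOREST_REGROWTH
            rec.regrowth_start_day = regrowth_start
            rec.decade = decade_of(int(year_of_day(regrowth_start)))
        else:
            rec.transition_class = TransitionClass.DEFORESTED
        return rec

    last = events[-1]
    if last.start_year >= th.recent_start_year:
        rec.transition_class = TransitionClass.RECENT
        if last.start_year >= th.monitoring_end_year:
            deforested = last.n_disruptions >= th.recent_disruption_count
        else:
            deforested = last.duration_days >= th.recent_duration_days
        rec.provisional = "deforestation" if deforested else "degradation"
        rec.subclass = (
            SUBCLASS_RECENT_DEFORESTATION if deforested else SUBCLASS_RECENT_DEGRADATION
        )
        return rec

    rec.transition_class = TransitionClass.DEGRADED
    max_duration = max(ev.duration_days for ev in events)
    rec.subclass = (
        SUBCLASS_DEGR_SHORT if max_duration <= th.short_max_days else SUBCLASS_DEGR_LONG
    )
    rec.decade = decade_of(events[-1].end_year)
    return rec


def _first_forest_after(
    series: PixelSeries, after_day: int, end_day: int
) -> Optional[int]:
    m = (
        (series.dates > after_day)
        & (series.dates <= end_day)
        & (series.labels == ObservationLabel.FOREST)
    )
    if not m.any():
        return None
    return int(series.dates[m][0])


def _classify_non_tmf(
    series: PixelSeries, baseline: BaselineResult, th: Thresholds
) -> TrajectoryRecord:
    """OTHER_LC, promoted to VEG_REGROWTH after sustained forest recovery."""
    end_day = th.monitoring_end_day
    valid = (series.labels != ObservationLabel.INVALID) & (series.dates <= end_day)
    disr = valid & (series.labels == ObservationLabel.DISRUPTION)
    rec = TrajectoryRecord(
        transition_class=TransitionClass.OTHER_LC,
        baseline=baseline,
        monitoring_start_day=int(baseline.baseline_end) + 1,
    )
    if not disr.any():
        return rec
    last_disr = int(series.dates[disr][-1])
    regrowth_start = _first_forest_after(series, last_disr, end_day)
    if regrowth_start is not None and end_day - regrowth_start >= th.regrowth_min_days:
        age_days = end_day - regrowth_start
        rec.transition_class = TransitionClass.VEG_REGROWTH
        rec.regrowth_start_day = regrowth_start
        rec.subclass = (
            SUBCLASS_REGROWTH_10_20 if age_days >= 3650 else SUBCLASS_REGROWTH_3_10
        )
        rec.decade = decade_of(int(year_of_day(regrowth_start)))
    return rec


def classify_series(series: PixelSeries, th: Thresholds) -> TrajectoryRecord:
    """Full per-pixel pipeline: baseline, event segmentation, classification."""
    baseline = determine_baseline(series, th)
    if not baseline.qualifies:
        return TrajectoryRecord(transition_class=None, baseline=baseline)
    if baseline.is_tmf:
        events = segment_events(series, int(baseline.baseline_end) + 1, th)
    else:
        events = []
    return classify_trajectory(series, baseline, events, th)


@dataclass
class TrajectoryGrid:
    """Grid of per-pixel trajectory records with raster views."""

    records: list[list[TrajectoryRecord]]
    thresholds: Thresholds

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.records), len(self.records[0]) if self.records else 0)

    def class_raster(self) -> np.ndarray:
        rows, cols = self.shape
        out = np.zeros((rows, cols), dtype=np.uint8)
        for r in range(rows):
            for c in range(cols):
                tc = self.records[r][c].transition_class
                out[r, c] = 0 if tc is None else int(tc)
        return out

    def metric_rasters(self) -> dict[str, np.ndarray]:
        """Subclass, timing, duration, intensity and recurrence rasters."""
        rows, cols = self.shape
        sub = np.zeros((rows, cols), dtype=np.int16)
        dec = np.zeros((rows, cols), dtype=np.int16)
        first_yr = np.zeros((rows, cols), dtype=np.int16)
        last_yr = np.zeros((rows, cols), dtype=np.int16)
        dur = np.zeros((rows, cols), dtype=np.int32)
        nd = np.zeros((rows, cols), dtype=np.int32)
        rec100 = np.full((rows, cols), -1, dtype=np.int16)
        nev = np.zeros((rows, cols), dtype=np.int16)
        for r in range(rows):
            for c in range(cols):
                rc = self.records[r][c]
                sub[r, c] = rc.subclass
                dec[r, c] = int(rc.decade)
                nev[r, c] = rc.n_events
                if rc.events:
                    first_yr[r, c] = rc.events[0].start_year
                    last_yr[r, c] = rc.events[-1].end_year
                    dur[r, c] = max(ev.duration_days for ev in rc.events)
                    nd[r, c] = sum(ev.n_disruptions for ev in rc.events)
                if rc.recurrence is not None:
                    rec100[r, c] = int(round(rc.recurrence * 100))
        return {
            "subclass": sub,
            "decade": dec,
            "first_disruption_year": first_yr,
            "last_disruption_year": last_yr,
            "max_event_duration_days": dur,
            "n_disruptions": nd,
            "recurrence_x100": rec100,
            "n_events": nev,
        }


def classify_grid(
    dates: np.ndarray, label_stack: np.ndarray, th: Thresholds
) -> TrajectoryGrid:
    """Classify every pixel of a (time, rows, cols) label stack.

    Acquisitions may be supplied in any order; they are sorted by date, so the
    result is invariant to ingestion order.
    """
    days = as_day_numbers(dates)
    order = np.argsort(days, kind="stable")
    days = days[order]
    label_stack = np.asarray(label_stack, dtype=np.int8)[order]
    if np.any(np.diff(days) == 0):
        # merge is not needed for distinct dates; duplicate dates are rejected
        raise ValueError("duplicate acquisition dates in stack")
    _, rows, cols = label_stack.shape
    records: list[list[TrajectoryRecord]] = []
    for r in range(rows):
        row_records = []
        for c in range(cols):
            series = PixelSeries(days, label_stack[:, r, c], row=r, col=c)
            row_records.append(classify_series(series, th))
        records.append(row_records)
    return TrajectoryGrid(records=records, thresholds=th)
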