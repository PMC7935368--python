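"""Independent straight-line re-implementation of the trajectory rules.

This interpreter is deliberately written without numpy and without reusing
any code from the production package: plain loops over (date, label) pairs,
datetime arithmetic, and literal transcriptions of the decision rules.  It
serves as the brute-force oracle for exhaustive and randomized agreement
tests against ``tmfmonitor.trajectory``.

Labels: 0 = invalid, 1 = forest, 2 = disruption (same codes as production).
"""

from __future__ import annotations

import datetime as dt

INVALID, FOREST, DISRUPTION = 0, 1, 2

# class names mirror the production enum values
UNDISTURBED, DEFORESTED, DEGRADED, RECENT, FOREST_REGROWTH, OTHER_LC, VEG_REGROWTH = (
    1, 2, 3, 4, 5, 6, 7,
)

SUB_NONE = 0
SUB_DEGR_SHORT = 31
SUB_DEGR_LONG = 32
SUB_RECENT_DEGR = 41
SUB_RECENT_DEFOR = 42
SUB_REGROWTH_3_10 = 71
SUB_REGROWTH_10_20 = 72


def _date(day_number: int) -> dt.date:
    return dt.date(1970, 1, 1) + dt.timedelta(days=day_number)


def classify_oracle(
    observations: list[tuple[int, int]],
    monitoring_end: str = "2019-12-31",
    short_max: int = 365,
    defor_min: int = 900,
    gap_days: int = 365,
    regrowth_min: int = 1095,
    recent_start_year: int = 2017,
    recent_duration: int = 366,
    recent_count: int = 10,
):
    """Classify one series; returns a dict or None when never qualified.

    ``observations`` is a list of (day_number, label) sorted by day.
    """
    end_day = (dt.date.fromisoformat(monitoring_end) - dt.date(1970, 1, 1)).days
    end_year = dt.date.fromisoformat(monitoring_end).year

    valid = [(d, l) for d, l in observations if l != INVALID]
    if not valid:
        return None

    # --- baseline qualification -------------------------------------------
    counts: dict[int, int] = {}
    for d, _ in valid:
        counts[_date(d).year] = counts.get(_date(d).year, 0) + 1
    first_year = _date(valid[0][0]).year

    def window_end(win: int, need: int):
        year = first_year
        while year + win - 1 <= end_year:
            if all(counts.get(y, 0) >= need for y in range(year, year + win)):
                return year + win - 1
            year += 1
        return None

    end_a = window_end(4, 3)
    end_b = window_end(5, 2)
    if end_a is None and end_b is None:
        return None
    if end_b is None or (end_a is not None and end_a <= end_b):
        baseline_end_year = end_a
    else:
        baseline_end_year = end_b
    baseline_end = (dt.date(baseline_end_year, 12, 31) - dt.date(1970, 1, 1)).days

    baseline_obs = [(d, l) for d, l in valid if d <= baseline_end]
    is_tmf = all(l == FOREST for _, l in baseline_obs)

    result = {
        "class": None,
        "subclass": SUB_NONE,
        "after_degradation": False,
        "provisional": None,
        "n_events": 0,
    }

    if not is_tmf:
        # other land cover; promoted to vegetation regrowth after sustained
        # forest recovery
        disr = [d for d, l in valid if l == DISRUPTION and d <= end_day]
        result["class"] = OTHER_LC
        if disr:
            last = disr[-1]
            later_forest = [d for d, l in valid if l == FOREST and last < d <= end_day]
            if later_forest and end_day - later_forest[0] >= regrowth_min:
                result["class"] = VEG_REGROWTH
                age = end_day - later_forest[0]
                result["subclass"] = (
                    SUB_REGROWTH_10_20 if age >= 3650 else SUB_REGROWTH_3_10
                )
        return result

    # --- event segmentation -----------------------------------------------
    monitoring_start = baseline_end + 1
    window = [(d, l) for d, l in valid if monitoring_start <= d <= end_day]
    disr = [d for d, l in window if l == DISRUPTION]
    forest = [d for d, l in window if l == FOREST]

    events = []  # (start, end, n)
    if disr:
        start, prev, n = disr[0], disr[0], 1
        for d in disr[1:]:
            has_forest_between = any(prev < f < d for f in forest)
            if d - prev >= gap_days and has_forest_between:
                events.append((start, prev, n))
                start, n = d, 1
            else:
                n += 1
            prev = d
        events.append((start, prev, n))
    result["n_events"] = len(events)

    if not events:
        result["class"] = UNDISTURBED
        return result

    # --- decision rules ----------------------------------------------------
    defor_index = None
    for i in range(len(events) - 1, -1, -1):
        if events[i][1] - events[i][0] > defor_min:
            defor_index = i
            break

    if defor_index is not None:
        start, end, _ = events[defor_index]
        result["after_degradation"] = defor_index > 0
        later_disruption = defor_index < len(events) - 1
        regrowth_candidates = [d for d in forest if d > end]
        regrowth_ok = (
            not later_disruption
            and regrowth_candidates
            and end_day - regrowth_candidates[0] >= regrowth_min
        )
        result["class"] = FOREST_REGROWTH if regrowth_ok else DEFORESTED
        return result

    last_start, last_end, last_n = events[-1]
    if _date(last_start).year >= recent_start_year:
        result["class"] = RECENT
        if _date(last_start).year >= end_year:
            deforested = last_n >= recent_count
        else:
            deforested = last_end - last_start >= recent_duration
        result["provisional"] = "deforestation" if deforested else "degradation"
        result["subclass"] = SUB_RECENT_DEFOR if deforested else SUB_RECENT_DEGR
        return result

    result["class"] = DEGRADED
    longest = max(e - s for s, e, _ in events)
    result["subclass"] = SUB_DEGR_SHORT if longest <= short_max else SUB_DEGR_LONG
    return result


def record_to_tuple(record):
    """Production TrajectoryRecord -> comparable tuple."""
    if record.transition_class is None:
        return None
    return (
        int(record.transition_class),
        int(record.subclass),
        bool(record.defor_after_degradation),
        record.provisional,
        record.n_events,
    )


def oracle_to_tuple(result):
    if result is None:
        return None
    return (
        result["class"],
        result["subclass"],
        result["after_degradation"],
        result["provisional"],
        result["n_events"],
    )
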