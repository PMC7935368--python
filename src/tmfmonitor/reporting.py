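"""Territory and period aggregation: area tables, declines, rates, ratios.

All area statistics are pure functions of the annual class rasters (pixel
counts x 0.09 ha); percentages follow the reporting conventions of the
product tables (one decimal for tables, both raw and rounded values exposed).
Cells whose observation record is poor (mean invalid fraction above 40%) are
flagged and the flag is propagated, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labels import AnnualState, PIXEL_AREA_HA

HA_PER_MHA = 1e6

#: Annual-change disturbance type keys used by the recent-year calibration.
CALIBRATION_TYPES = (
    "degradation_to_deforestation",
    "degradation_only",
    "direct_deforestation",
)


def aggregate_areas(
    annual_states: dict[int, np.ndarray],
    territory: np.ndarray,
    years: Optional[Sequence[int]] = None,
    invalid_flag: Optional[dict[int, bool]] = None,
) -> pd.DataFrame:
    """Per-territory, per-year class areas in hectares.

    ``territory`` is an integer raster of territory ids (0 = outside).
    Returns a tidy frame (territory, year, state, area_ha, flagged).
    """
    territory = np.asarray(territory)
    years = sorted(annual_states) if years is None else list(years)
    n_states = max(int(s) for s in AnnualState) + 1
    terr_ids = np.unique(territory)
    terr_ids = terr_ids[terr_ids > 0]
    rows = []
    for year in years:
        raster = annual_states[year]
        if raster.shape != territory.shape:
            raise ValueError("territory raster does not match the product grid")
        flagged = bool(invalid_flag.get(year, False)) if invalid_flag else False
        for tid in terr_ids:
            sel = territory == tid
            counts = np.bincount(raster[sel].ravel(), minlength=n_states)
            for state in AnnualState:
                if state == AnnualState.NODATA:
                    continue
                rows.append(
                    {
                        "territory": int(tid),
                        "year": int(year),
                        "state": state.name.lower(),
                        "area_ha": counts[int(state)] * PIXEL_AREA_HA,
                        "flagged": flagged,
                    }
                )
    return pd.DataFrame(rows)


def interval_means(
    table: pd.DataFrame, intervals: Sequence[tuple[int, int]]
) -> pd.DataFrame:
    """Mean annual areas over closed year intervals (e.g. [1990-1994])."""
    rows = []
    for start, end in intervals:
        sel = table[(table["year"] >= start) & (table["year"] <= end)]
        grp = sel.groupby(["territory", "state"], as_index=False).agg(
            area_ha=("area_ha", "mean"), flagged=("flagged", "any")
        )
        grp["period"] = f"[{start}-{end}]"
        rows.append(grp)
    return pd.concat(rows, ignore_index=True)


def decline_pct(area_start: float, area_end: float) -> float:
    """Relative decline in percent between two areas."""
    if area_start <= 0:
        raise ValueError("start area must be positive")
    return 100.0 * (area_start - area_end) / area_start


def annual_loss_rate(area_start: float, area_end: float, n_years: int) -> float:
    """Average annual loss (same unit as the areas, per year)."""
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    return (area_start - area_end) / n_years


def calibrate_recent_proportions(
    annual_types: pd.DataFrame,
    reference_window: tuple[int, int] = (2005, 2014),
    target_years: Sequence[int] = (2017, 2018, 2019),
) -> pd.DataFrame:
    """Redistribute recent-year disturbance totals by historical proportions.

    ``annual_types`` columns: year plus one column per disturbance type
    (:data:`CALIBRATION_TYPES`), areas in any consistent unit.  For each
    target year the year's total is preserved and split according to the mean
    annual shares over the reference window.
    """
    for col in CALIBRATION_TYPES:
        if col not in annual_types.columns:
            raise ValueError(f"missing disturbance type column {col!r}")
    frame = annual_types.set_index("year").sort_index()
    ref = frame.loc[reference_window[0] : reference_window[1], list(CALIBRATION_TYPES)]
    if len(ref) < (reference_window[1] - reference_window[0] + 1):
        raise ValueError("reference window not fully covered")
    totals = ref.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("reference window contains a zero-disturbance year")
    shares = (ref.div(totals, axis=0)).mean(axis=0)
    shares = shares / shares.sum()
    out = frame.copy()
    for year in target_years:
        total = frame.loc[year, list(CALIBRATION_TYPES)].sum()
        out.loc[year, list(CALIBRATION_TYPES)] = (shares * total).to_numpy()
    return out.reset_index()


@dataclass
class Ratio:
    """A named headline statistic with its inputs kept for audit."""

    name: str
    value_pct: float
    numerator: float
    denominator: float

    @property
    def printed(self) -> float:
        return round(self.value_pct, 1)


def _ratio(name: str, num: float, den: float) -> Ratio:
    if den == 0:
        raise ZeroDivisionError(f"ratio {name!r} has zero denominator")
    return Ratio(name=name, value_pct=100.0 * num / den, numerator=num, denominator=den)


def headline_ratios(totals: dict[str, float]) -> dict[str, Ratio]:
    """Headline statistics from a totals dictionary (areas in Mha).

    Expected keys: ``degraded``, ``remaining_tmf``, ``deforested``,
    ``regrowth``, ``degraded_short``, ``degradation_before_deforestation``;
    optional per-continent degraded areas under ``degraded_<name>``.
    """
    out: dict[str, Ratio] = {}
    if {"degraded", "remaining_tmf"} <= totals.keys():
        out["degraded_share_of_remaining"] = _ratio(
            "degraded_share_of_remaining", totals["degraded"], totals["remaining_tmf"]
        )
    if {"degraded", "deforested", "regrowth"} <= totals.keys():
        changes = totals["degraded"] + totals["deforested"] + totals["regrowth"]
        out["degraded_share_of_changes"] = _ratio(
            "degraded_share_of_changes", totals["degraded"], changes
        )
        out["regrowth_share_of_deforested"] = _ratio(
            "regrowth_share_of_deforested",
            totals["regrowth"],
            totals["deforested"] + totals["regrowth"],
        )
    if {"degraded_short", "degraded"} <= totals.keys():
        out["short_share_of_degraded"] = _ratio(
            "short_share_of_degraded", totals["degraded_short"], totals["degraded"]
        )
    if {"degradation_before_deforestation", "degraded"} <= totals.keys():
        degr_total = totals["degradation_before_deforestation"] + totals["degraded"]
        out["degradation_precursor_share"] = _ratio(
            "degradation_precursor_share",
            totals["degradation_before_deforestation"],
            degr_total,
        )
    continents = {
        k.removeprefix("degraded_"): v
        for k, v in totals.items()
        if k.startswith("degraded_") and k != "degraded_short"
    }
    if continents and "degraded" in totals:
        for name, area in continents.items():
            out[f"degraded_share_{name}"] = _ratio(
                f"degraded_share_{name}", area, totals["degraded"]
            )
    return out


def crosstab_change_maps(
    map_a: np.ndarray,
    map_b: np.ndarray,
    pixel_area_ha: float = PIXEL_AREA_HA,
) -> pd.DataFrame:
    """Correspondence matrix (hectares) between two category rasters."""
    map_a = np.asarray(map_a)
    map_b = np.asarray(map_b)
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share the same grid")
    frame = pd.crosstab(
        pd.Series(map_a.ravel(), name="map_a"),
        pd.Series(map_b.ravel(), name="map_b"),
    )
    return frame * pixel_area_ha
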