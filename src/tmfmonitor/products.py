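"""Map products: transition map, annual change layers, edge buffer, hotspots.

The transition map resolves each qualified pixel into one of the seven main
transition classes plus ancillary-mask-driven subclasses (plantation, water,
mangrove, bamboo).  The annual collection replays each pixel's event timeline
into a per-year state for 1990-2019, attributing every disturbance to the
year of its first disruption observation, and labels disturbed pixel-years
with one of ten annual change categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GridGeometry
from .labels import (
    AnnualChangeClass,
    AnnualState,
    PIXEL_AREA_HA,
    SUBCLASS_BAMBOO,
    SUBCLASS_MANGROVE,
    SUBCLASS_OTHER_CONVERSION,
    SUBCLASS_PLANTATION,
    SUBCLASS_WATER,
    TransitionClass,
)
from .trajectory import (
    Thresholds,
    TrajectoryGrid,
    TrajectoryRecord,
    year_of_day,
)

ANNUAL_YEARS = tuple(range(1990, 2020))


@dataclass
class AncillaryMasks:
    """Optional category masks on the product grid (True where the theme holds)."""

    plantation: Optional[np.ndarray] = None
    water: Optional[np.ndarray] = None
    mangrove: Optional[np.ndarray] = None
    bamboo: Optional[np.ndarray] = None
    semi_deciduous: Optional[np.ndarray] = None

    def check_shape(self, shape: tuple[int, int]) -> None:
        for name in ("plantation", "water", "mangrove", "bamboo", "semi_deciduous"):
            mask = getattr(self, name)
            if mask is not None and mask.shape != shape:
                raise ValueError(f"{name} mask shape {mask.shape} != grid {shape}")


@dataclass
class TransitionMap:
    """Main-class, subclass and decade rasters of the transition product."""

    main: np.ndarray      # TransitionClass codes (0 = never qualified)
    subclass: np.ndarray  # subclass codes (0 = none)
    decade: np.ndarray    # DecadeTag codes
    geometry: Optional[GridGeometry] = None


def build_transition_map(
    grid: TrajectoryGrid,
    masks: Optional[AncillaryMasks] = None,
    geometry: Optional[GridGeometry] = None,
) -> TransitionMap:
    """Assemble the transition map from classified records and masks.

    Deforested pixels under a plantation/water mask become subclasses 2a/2b
    (else 2c); undisturbed pixels under mangrove/bamboo masks become 1b/1a.
    """
    main = grid.class_raster()
    metrics = grid.metric_rasters()
    subclass = metrics["subclass"].copy()
    decade = metrics["decade"].copy()
    if masks is not None:
        masks.check_shape(main.shape)
        defor = main == int(TransitionClass.DEFORESTED)
        subclass[defor] = SUBCLASS_OTHER_CONVERSION
        if masks.water is not None:
            subclass[defor & masks.water] = SUBCLASS_WATER
        if masks.plantation is not None:
            subclass[defor & masks.plantation] = SUBCLASS_PLANTATION
        undisturbed = main == int(TransitionClass.UNDISTURBED)
        if masks.mangrove is not None:
            subclass[undisturbed & masks.mangrove] = SUBCLASS_MANGROVE
        if masks.bamboo is not None:
            subclass[undisturbed & masks.bamboo] = SUBCLASS_BAMBOO
    else:
        defor = main == int(TransitionClass.DEFORESTED)
        subclass[defor] = SUBCLASS_OTHER_CONVERSION
    return TransitionMap(main=main, subclass=subclass, decade=decade, geometry=geometry)


def _timeline_years(record: TrajectoryRecord, th: Thresholds):
    """(first_event_year, defor_year, regrowth_year) of a record, None-padded.

    ``defor_year`` is the onset year of the (provisionally) deforesting event;
    for RECENT pixels the provisional split decides whether the recent event
    deforests.
    """
    if not record.events:
        return None, None, None
    first_year = record.events[0].start_year
    defor_year = None
    regrowth_year = None
    defor_event = record.deforestation_event(th)
    if defor_event is not None:
        defor_year = defor_event.start_year
    elif record.transition_class == TransitionClass.RECENT and record.provisional == "deforestation":
        defor_year = record.events[-1].start_year
    if record.regrowth_start_day is not None and record.transition_class == TransitionClass.FOREST_REGROWTH:
        regrowth_year = int(year_of_day(record.regrowth_start_day))
    return first_year, defor_year, regrowth_year


def annual_state(record: TrajectoryRecord, year: int, th: Thresholds) -> AnnualState:
    """State of the pixel at the end of ``year``.

    A disturbance is attributed to the year of its first disruption
    observation, so a pixel disturbed in November is already counted as
    disturbed for that year.  Once degraded, a pixel never returns to the
    undisturbed pool.
    """
    if not (ANNUAL_YEARS[0] <= year <= ANNUAL_YEARS[-1]):
        raise ValueError(f"year {year} outside {ANNUAL_YEARS[0]}-{ANNUAL_YEARS[-1]}")
    tc = record.transition_class
    if tc is None:
        return AnnualState.NODATA
    if tc == TransitionClass.OTHER_LC:
        return AnnualState.OTHER
    if tc == TransitionClass.VEG_REGROWTH:
        if record.regrowth_start_day is not None and year >= int(
            year_of_day(record.regrowth_start_day)
        ):
            return AnnualState.REGROWTH
        return AnnualState.OTHER
    first_year, defor_year, regrowth_year = _timeline_years(record, th)
    if first_year is None or year < first_year:
        return AnnualState.UNDISTURBED
    if defor_year is not None and year >= defor_year:
        if regrowth_year is not None and year >= regrowth_year:
            return AnnualState.REGROWTH
        return AnnualState.DEFORESTED
    return AnnualState.DEGRADED


def annual_state_stack(
    grid: TrajectoryGrid, years=ANNUAL_YEARS
) -> dict[int, np.ndarray]:
    """Annual state rasters for every requested year."""
    th = grid.thresholds
    rows, cols = grid.shape
    out = {y: np.zeros((rows, cols), dtype=np.uint8) for y in years}
    for r in range(rows):
        for c in range(cols):
            record = grid.records[r][c]
            for y in years:
                out[y][r, c] = int(annual_state(record, y, th))
    return out


def _record_change_class(
    record: TrajectoryRecord, th: Thresholds, masks: Optional[AncillaryMasks],
    r: int, c: int,
) -> list[tuple[int, AnnualChangeClass]]:
    """(year, annual change class) attributions of one record."""
    tc = record.transition_class
    if tc is None or not record.events:
        return []
    if tc in (TransitionClass.OTHER_LC, TransitionClass.VEG_REGROWTH):
        return []
    out = []
    defor_event = record.deforestation_event(th)
    recent_defor = (
        tc == TransitionClass.RECENT and record.provisional == "deforestation"
    )
    regrown = tc == TransitionClass.FOREST_REGROWTH
    water = masks is not None and masks.water is not None and masks.water[r, c]
    plantation = (
        masks is not None and masks.plantation is not None and masks.plantation[r, c]
    )
    for event in record.events:
        is_defor = event is defor_event or (
            recent_defor and event is record.events[-1]
        )
        if is_defor:
            if water:
                cls = AnnualChangeClass.DEFOR_TO_WATER
            elif plantation:
                cls = AnnualChangeClass.DEFOR_TO_COMMODITIES
            elif record.defor_after_degradation:
                cls = (
                    AnnualChangeClass.DEFOR_OF_DEGRADED_REGROWTH
                    if regrown
                    else AnnualChangeClass.DEFOR_OF_DEGRADED
                )
            else:
                cls = (
                    AnnualChangeClass.DIRECT_DEFOR_REGROWTH
                    if regrown
                    else AnnualChangeClass.DIRECT_DEFOR
                )
        else:
            followed_by_defor = defor_event is not None or recent_defor
            if followed_by_defor:
                cls = (
                    AnnualChangeClass.DEGR_BEFORE_DEFOR_REGROWTH
                    if regrown
                    else AnnualChangeClass.DEGR_BEFORE_DEFOR
                )
            elif event.duration_days <= th.short_max_days:
                cls = AnnualChangeClass.DEGR_SHORT
            else:
                cls = AnnualChangeClass.DEGR_LONG
        out.append((event.start_year, cls))
    return out


def annual_change_classes(
    grid: TrajectoryGrid,
    years=ANNUAL_YEARS,
    masks: Optional[AncillaryMasks] = None,
) -> dict[int, np.ndarray]:
    """Per-year rasters over the ten-class annual change taxonomy.

    Each disturbed pixel-year carries exactly one category, attributed to the
    event's onset year.
    """
    th = grid.thresholds
    rows, cols = grid.shape
    out = {y: np.zeros((rows, cols), dtype=np.uint8) for y in years}
    yearset = set(years)
    for r in range(rows):
        for c in range(cols):
            for year, cls in _record_change_class(grid.records[r][c], th, masks, r, c):
                if year in yearset:
                    out[year][r, c] = int(cls)
    return out


def edge_buffer(
    disturbed: np.ndarray, distance_m: float = 120.0, pixel_m: float = 30.0
) -> np.ndarray:
    """Pixels whose center lies within ``distance_m`` of a disturbed pixel center.

    Euclidean center-to-center distance (disc, not Chebyshev square).  The
    disturbed pixels themselves are part of the returned mask; the
    edge-affected forest is ``buffer & ~disturbed``.
    """
    if distance_m < 0:
        raise ValueError("distance must be >= 0")
    disturbed = np.asarray(disturbed, dtype=bool)
    radius = int(np.floor(distance_m / pixel_m))
    if radius == 0 or not disturbed.any():
        return disturbed.copy()
    offsets = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(offsets, offsets)
    disc = (dx * dx + dy * dy) * pixel_m * pixel_m <= distance_m * distance_m
    return ndimage.binary_dilation(disturbed, structure=disc)


def hotspot_grid(
    annual_changes: dict[int, np.ndarray],
    geometry: GridGeometry,
    periods=((1990, 1999), (2000, 2009), (2010, 2019)),
) -> pd.DataFrame:
    """Deforested/degraded area per 1-degree cell and period.

    Requires a geographic grid; a pixel on a cell boundary belongs to the
    cell containing its center.  Returns columns lat, lon, period,
    defor_ha, degr_ha.
    """
    if not geometry.geographic:
        raise ValueError("hotspot aggregation requires geographic coordinates")
    lon, lat = geometry.pixel_centers()
    cell_lon = np.floor(lon).astype(int).ravel()
    cell_lat = np.floor(lat).astype(int).ravel()
    defor_classes = {
        int(AnnualChangeClass.DIRECT_DEFOR),
        int(AnnualChangeClass.DIRECT_DEFOR_REGROWTH),
        int(AnnualChangeClass.DEFOR_OF_DEGRADED),
        int(AnnualChangeClass.DEFOR_OF_DEGRADED_REGROWTH),
        int(AnnualChangeClass.DEFOR_TO_WATER),
        int(AnnualChangeClass.DEFOR_TO_COMMODITIES),
    }
    rows = []
    for start, end in periods:
        defor = np.zeros(geometry.shape, dtype=bool)
        degr = np.zeros(geometry.shape, dtype=bool)
        for year, raster in annual_changes.items():
            if start <= year <= end:
                isdef = np.isin(raster, list(defor_classes))
                defor |= isdef
                degr |= (raster > 0) & ~isdef
        frame = pd.DataFrame(
            {
                "lat": cell_lat,
                "lon": cell_lon,
                "defor": defor.ravel().astype(float) * PIXEL_AREA_HA,
                "degr": degr.ravel().astype(float) * PIXEL_AREA_HA,
            }
        )
        agg = frame.groupby(["lat", "lon"], as_index=False).sum()
        agg = agg[(agg["defor"] > 0) | (agg["degr"] > 0)]
        agg["period"] = f"{start}-{end}"
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["lat", "lon", "defor", "degr", "period"]
    )
    return out.rename(columns={"defor": "defor_ha", "degr": "degr_ha"})[
        ["lat", "lon", "period", "defor_ha", "degr_ha"]
    ]
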