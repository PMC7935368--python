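"""Business-as-usual projection of forest area.

Annual disturbed areas of a territory are modeled as independent log-normal
draws; the mean annual loss and its 95% confidence interval come from the
modified Cox method (t-quantile form), and area is depleted linearly at the
estimated rate from the end of 2019 to the projection horizon (2050 by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RateSeries:
    """Annual disturbed-area series of one territory (log-normal support)."""

    territory: str
    years: np.ndarray
    losses: np.ndarray  # annual disturbed areas, > 0

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.losses = np.asarray(self.losses, dtype=float)
        if self.years.size != self.losses.size:
            raise ValueError("years and losses must have equal length")
        if self.years.size < 2:
            raise ValueError("need at least two annual values")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        if np.any(self.losses <= 0):
            raise ValueError("losses must be positive (log-normal support)")

    @property
    def n(self) -> int:
        return int(self.losses.size)

    @property
    def log_mean(self) -> float:
        return float(np.mean(np.log(self.losses)))

    @property
    def log_var(self) -> float:
        return float(np.var(np.log(self.losses), ddof=1))

    @classmethod
    def from_losses(
        cls, territory: str, years, losses, zero_floor_factor: float = 1e-3
    ) -> "RateSeries":
        """Build a series, flooring non-positive values.

        Zero annual losses break log-normal support; they are replaced by the
        smallest positive observed loss times ``zero_floor_factor`` (with a
        warning).  A series of all zeros is rejected.
        """
        losses = np.asarray(losses, dtype=float)
        if np.all(losses <= 0):
            raise ValueError(f"territory {territory!r} has no positive annual loss")
        if np.any(losses <= 0):
            floor = losses[losses > 0].min() * zero_floor_factor
            warnings.warn(
                f"territory {territory!r}: {int(np.sum(losses <= 0))} non-positive "
                f"annual losses floored at {floor:g}",
                stacklevel=2,
            )
            losses = np.where(losses <= 0, floor, losses)
        return cls(territory, np.asarray(years, dtype=int), losses)


def lognormal_mean_ci(
    series: RateSeries, level: float = 0.95, use_t: bool = True
) -> tuple[float, float, float]:
    """Modified-Cox estimate of the log-normal mean with confidence interval.

    point = exp(ybar + s^2/2); the interval exponentiates
    ybar + s^2/2 -/+ q * sqrt(s^2/n + s^4 / (2 (n - 1))), with q the
    t_{n-1} quantile (modified form) or the normal quantile (``use_t=False``).
    """
    n = series.n
    ybar = series.log_mean
    s2 = series.log_var
    alpha = 1.0 - level
    q = (
        stats.t.ppf(1 - alpha / 2, df=n - 1)
        if use_t
        else stats.norm.ppf(1 - alpha / 2)
    )
    center = ybar + s2 / 2.0
    half = q * np.sqrt(s2 / n + s2**2 / (2.0 * (n - 1)))
    return float(np.exp(center)), float(np.exp(center - half)), float(np.exp(center + half))


@dataclass
class ProjectionResult:
    territory: str
    definition: str                      # "undisturbed" or "total_tmf"
    rate_mean: float
    rate_low: float
    rate_high: float
    area_2050: tuple[float, float, float]       # (point, low, high)
    pct_remaining: tuple[float, float, float]
    disappearance_year: tuple[Optional[int], Optional[int], Optional[int]]
    horizon: int = 2050


def _deplete(area0: float, rate: float, start_year: int, horizon: int):
    """Linear depletion; returns (area at horizon end, disappearance year)."""
    if rate <= 0:
        return area0, None
    years_to_zero = area0 / rate
    disappearance = int(np.ceil(start_year + years_to_zero))
    area_h = max(0.0, area0 - rate * (horizon - start_year))
    if disappearance > horizon:
        return area_h, None
    return area_h, disappearance


def project_bau(
    area_end2019: float,
    rate_ci: tuple[float, float, float],
    horizon: int = 2050,
    territory: str = "",
    definition: str = "undisturbed",
) -> ProjectionResult:
    """Constant-rate depletion from end-2019 for (point, low, high) rates.

    The *high* rate gives the low area bound and the earliest disappearance.
    ``disappearance_year`` is the first year whose end has area <= 0, or
    None when the forest outlasts the horizon.
    """
    if area_end2019 < 0:
        raise ValueError("area must be >= 0")
    point, low, high = rate_ci
    if min(point, low, high) < 0:
        raise ValueError("rates must be >= 0")
    areas = {}
    years = {}
    for tag, rate in (("point", point), ("low_rate", low), ("high_rate", high)):
        areas[tag], years[tag] = _deplete(area_end2019, rate, 2019, horizon)
    pct = {
        tag: (100.0 * a / area_end2019 if area_end2019 > 0 else 0.0)
        for tag, a in areas.items()
    }
    return ProjectionResult(
        territory=territory,
        definition=definition,
        rate_mean=point,
        rate_low=low,
        rate_high=high,
        # low area bound comes from the high rate and vice versa
        area_2050=(areas["point"], areas["high_rate"], areas["low_rate"]),
        pct_remaining=(pct["point"], pct["high_rate"], pct["low_rate"]),
        disappearance_year=(years["point"], years["high_rate"], years["low_rate"]),
        horizon=horizon,
    )


def project_all(
    losses: pd.DataFrame,
    areas_2019: dict[tuple[str, str], float],
    window: tuple[int, int] = (2010, 2019),
    horizon: int = 2050,
    level: float = 0.95,
) -> pd.DataFrame:
    """Project every territory and forest definition.

    ``losses`` columns: territory, definition, year, loss (Mha);
    ``areas_2019`` maps (territory, definition) -> end-2019 area (Mha).
    Returns one row per (territory, definition) with rate and projection
    metrics (area_2050, pct_remaining, disappearance_year, each with bounds).
    """
    start, end = window
    if end - start + 1 < 2:
        raise ValueError("projection window must span at least two years")
    rows = []
    for (territory, definition), grp in losses.groupby(["territory", "definition"]):
        sel = grp[(grp["year"] >= start) & (grp["year"] <= end)].sort_values("year")
        if sel["year"].nunique() < (end - start + 1):
            raise ValueError(
                f"territory {territory!r}/{definition!r} does not cover {start}-{end}"
            )
        series = RateSeries.from_losses(
            str(territory), sel["year"].to_numpy(), sel["loss"].to_numpy()
        )
        rate_ci = lognormal_mean_ci(series, level=level)
        area0 = areas_2019[(territory, definition)]
        res = project_bau(
            area0, rate_ci, horizon=horizon, territory=str(territory),
            definition=str(definition),
        )
        rows.append(
            {
                "territory": territory,
                "definition": definition,
                "area_2019": area0,
                "rate_mean": res.rate_mean,
                "rate_low": res.rate_low,
                "rate_high": res.rate_high,
                "area_2050": res.area_2050[0],
                "area_2050_low": res.area_2050[1],
                "area_2050_high": res.area_2050[2],
                "pct_remaining": res.pct_remaining[0],
                "pct_remaining_low": res.pct_remaining[1],
                "pct_remaining_high": res.pct_remaining[2],
                "disappearance_year": res.disappearance_year[0],
                "disappearance_year_early": res.disappearance_year[1],
                "disappearance_year_late": res.disappearance_year[2],
            }
        )
    return pd.DataFrame(rows)
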