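"""Synthetic observation-series and scene generator with known ground truth.

The generator emulates the structural properties of a long optical satellite
archive over the humid tropics: an acquisition density that grows over
1982-2019 (sparse before 2000, dense after 2013), per-observation invalidity
(cloud / shadow / sensor loss), forest vs disruption spectral signatures, and
disturbance events with controllable onset, duration, intensity and
post-event regrowth.

Ground truth is defined at the level of *observable* events: each simulated
disturbance episode is anchored to the acquisitions that actually fall inside
its window (the first and, for bounded episodes, last acquisition in the
window are made valid disruption observations), and the recorded truth
duration is the realized span between those acquisitions.  An event that no
acquisition could ever witness is not a meaningful ground-truth item for an
observation-driven classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import GridGeometry
from .labels import (
    ObservationLabel,
    SUBCLASS_DEGR_LONG,
    SUBCLASS_DEGR_SHORT,
    SUBCLASS_NONE,
    TransitionClass,
)
from .trajectory import PixelSeries, day_number, year_of_day

EVENT_KINDS = (
    "degradation",
    "deforestation",
    "deforestation_after_degradation",
    "regrowth_after_deforestation",
)

#: Band means of the synthetic signature library (reflectance in [0, 1],
#: thermal brightness temperature in Kelvin).
DEFAULT_SIGNATURES: dict[str, dict[str, float]] = {
    "forest": {"red": 0.03, "nir": 0.30, "swir2": 0.06, "green": 0.05,
               "swir1": 0.15, "thermal": 295.0},
    "disruption": {"red": 0.12, "nir": 0.25, "swir2": 0.22, "green": 0.10,
                   "swir1": 0.28, "thermal": 302.0},
    "cloud": {"red": 0.50, "nir": 0.55, "swir2": 0.35, "green": 0.50,
              "swir1": 0.40, "thermal": 272.0},
    "shadow": {"red": 0.015, "nir": 0.04, "swir2": 0.02, "green": 0.02,
               "swir1": 0.03, "thermal": 290.0},
}


@dataclass(frozen=True)
class ArchiveModel:
    """Acquisition-density model of the observation archive.

    ``expected_valid`` gives, for each year from ``first_year`` to
    ``last_year``, the expected number of *valid* observations; acquisitions
    are drawn as a Poisson process within each year and each acquisition is
    invalid with probability ``invalid_fraction`` (scalar or per-year).
    """

    first_year: int = 1982
    last_year: int = 2019
    expected_valid: tuple[float, ...] = ()
    invalid_fraction: float | tuple[float, ...] = 0.0

    def __post_init__(self) -> None:
        n = self.last_year - self.first_year + 1
        if len(self.expected_valid) != n:
            raise ValueError("expected_valid must have one entry per year")
        if any(not np.isfinite(v) or v < 0 for v in self.expected_valid):
            raise ValueError("expected counts must be finite and >= 0")
        fr = self.invalid_fractions()
        if np.any((fr < 0) | (fr > 1)):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if np.any((fr >= 1.0) & (np.asarray(self.expected_valid) > 0)):
            raise ValueError("invalid_fraction must be < 1 where observations are expected")

    def invalid_fractions(self) -> np.ndarray:
        n = self.last_year - self.first_year + 1
        if np.isscalar(self.invalid_fraction):
            return np.full(n, float(self.invalid_fraction))
        return np.asarray(self.invalid_fraction, dtype=float)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def end_day(self) -> int:
        return day_number(f"{self.last_year}-12-31")

    def valid_rate_of_year(self, year: int) -> float:
        year = int(np.clip(year, self.first_year, self.last_year))
        return float(self.expected_valid[year - self.first_year])

    @classmethod
    def dense(
        cls,
        obs_per_year: float = 12.0,
        invalid_fraction: float = 0.0,
        first_year: int = 1990,
        last_year: int = 2019,
    ) -> "ArchiveModel":
        """Uniformly dense archive, the reference condition for round-trips."""
        n = last_year - first_year + 1
        return cls(first_year, last_year, tuple([obs_per_year] * n), invalid_fraction)

    @classmethod
    def landsat_like(cls, invalid_fraction: float = 0.25) -> "ArchiveModel":
        """Uneven 1982-2019 archive: sparse start, jumps in 1999 and 2013,
        and a small dip in 2003 (scan-line-corrector failure era)."""
        expected = []
        for year in range(1982, 2020):
            if year < 1990:
                expected.append(1.0)
            elif year < 1999:
                expected.append(2.5)
            elif year < 2003:
                expected.append(7.0)
            elif year < 2013:
                expected.append(6.0)
            else:
                expected.append(14.0)
        return cls(1982, 2019, tuple(expected), invalid_fraction)

    def draw_calendar(self, rng: np.random.Generator) -> np.ndarray:
        """Draw acquisition day numbers (sorted, unique) for the archive."""
        days: list[int] = []
        fractions = self.invalid_fractions()
        for i, year in enumerate(self.years):
            lam = self.expected_valid[i]
            f = fractions[i]
            if lam <= 0:
                continue
            n_acq = rng.poisson(lam / (1.0 - f))
            if n_acq == 0:
                continue
            start = day_number(f"{year}-01-01")
            end = day_number(f"{int(year) + 1}-01-01")
            days.extend(rng.integers(start, end, size=n_acq).tolist())
        return np.unique(np.asarray(sorted(days), dtype=np.int64))


@dataclass(frozen=True)
class EventSpec:
    """Specification of one disturbance event for the generator.

    ``intensity`` is the expected number of disruption observations per year
    while the event is active.  For ``deforestation_after_degradation`` the
    onset refers to the deforestation stage; the degradation precursor is
    placed ``precursor_gap_days`` before it and lasts
    ``precursor_duration_days`` (the definitional gap of at least 366 days
    between degradation end and deforestation onset is enforced).
    """

    kind: str
    onset: str | np.datetime64
    duration_days: int = 0
    intensity: float = 12.0
    precursor_duration_days: int = 180
    precursor_gap_days: int = 730

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_days < 0:
            raise ValueError("duration_days must be >= 0")
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")
        if self.kind == "deforestation_after_degradation":
            if self.precursor_gap_days < 366:
                raise ValueError(
                    "degradation-to-deforestation gap must be >= 366 days"
                )
            if self.precursor_duration_days < 0:
                raise ValueError("precursor duration must be >= 0")

    @property
    def onset_day(self) -> int:
        return day_number(self.onset)

    def episodes(self, archive_end_day: int) -> list[tuple[int, int, bool]]:
        """Expand into disruption episodes (start_day, end_day, bounded)."""
        onset = self.onset_day
        if self.kind == "degradation":
            return [(onset, onset + self.duration_days, True)]
        if self.kind == "deforestation":
            return [(onset, archive_end_day, False)]
        if self.kind == "regrowth_after_deforestation":
            return [(onset, onset + self.duration_days, True)]
        # deforestation after degradation
        pre_end = onset - self.precursor_gap_days
        pre_start = pre_end - self.precursor_duration_days
        return [(pre_start, pre_end, True), (onset, archive_end_day, False)]

    def truth_class(self, realized_duration: int) -> tuple[TransitionClass, int]:
        if self.kind == "degradation":
            sub = (
                SUBCLASS_DEGR_SHORT if realized_duration <= 365 else SUBCLASS_DEGR_LONG
            )
            return TransitionClass.DEGRADED, sub
        if self.kind == "regrowth_after_deforestation":
            return TransitionClass.FOREST_REGROWTH, SUBCLASS_NONE
        return TransitionClass.DEFORESTED, SUBCLASS_NONE


def _validate_events(events: Sequence[EventSpec], archive: ArchiveModel) -> None:
    episodes: list[tuple[int, int]] = []
    for spec in events:
        if not (
            day_number(f"{archive.first_year}-01-01")
            <= spec.onset_day
            <= archive.end_day
        ):
            raise ValueError(f"event onset {spec.onset} outside the archive span")
        episodes.extend((s, e) for s, e, _ in spec.episodes(archive.end_day))
    episodes.sort()
    for (s1, e1), (s2, e2) in zip(episodes, episodes[1:]):
        if s2 <= e1:
            raise ValueError("events overlap; episodes must be disjoint")


@dataclass
class PixelTruth:
    """Ground truth for one simulated pixel."""

    transition_class: TransitionClass
    subclass: int
    kind: Optional[str]
    events: list[dict] = field(default_factory=list)


def _place_episodes(
    days: np.ndarray,
    valid: np.ndarray,
    labels: np.ndarray,
    specs: Sequence[EventSpec],
    archive: ArchiveModel,
    rng: np.random.Generator,
    allow_insert: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[dict]]:
    """Assign disruption labels for the episodes of one pixel.

    Returns possibly extended (days, valid, labels) plus realized event
    records.  The first (and, for bounded episodes, last) acquisition inside
    each episode window is forced to a valid disruption observation so that
    every truth event is observable.
    """
    realized: list[dict] = []
    fractions = archive.invalid_fractions()
    for spec in specs:
        for start, end, bounded in spec.episodes(archive.end_day):
            inside = (days >= start) & (days <= end)
            if not inside.any():
                if not allow_insert:
                    continue
                insert_day = min(max((start + end) // 2, start), end)
                idx = int(np.searchsorted(days, insert_day))
                days = np.insert(days, idx, insert_day)
                valid = np.insert(valid, idx, True)
                labels = np.insert(labels, idx, int(ObservationLabel.FOREST))
                inside = (days >= start) & (days <= end)
            idxs = np.flatnonzero(inside)
            # disruption probability per valid observation from the intensity
            years = year_of_day(days[idxs])
            rates = np.array([archive.valid_rate_of_year(int(y)) for y in years])
            p = np.minimum(1.0, spec.intensity / np.maximum(rates, 1e-9))
            is_disr = rng.random(idxs.size) < p
            is_disr[0] = True
            if bounded:
                is_disr[-1] = True
            valid_here = valid[idxs].copy()
            valid_here[0] = True
            if bounded:
                valid_here[-1] = True
            valid[idxs] = valid_here
            sel = idxs[valid_here & is_disr]
            labels[sel] = int(ObservationLabel.DISRUPTION)
            # valid forest observations inside the episode stay forest
            if sel.size:
                realized.append(
                    {
                        "kind": spec.kind,
                        "start_day": int(days[sel[0]]),
                        "end_day": int(days[sel[-1]]),
                        "n_disruptions": int(sel.size),
                        "bounded": bounded,
                    }
                )
    return days, valid, labels, realized


def _truth_from_spec(spec: Optional[EventSpec], realized: list[dict]) -> PixelTruth:
    if spec is None:
        return PixelTruth(TransitionClass.UNDISTURBED, SUBCLASS_NONE, None, [])
    if realized:
        # realized duration of the first bounded episode (degradation kinds)
        first = realized[0]
        duration = first["end_day"] - first["start_day"]
    else:
        duration = spec.duration_days
    cls, sub = spec.truth_class(duration)
    return PixelTruth(cls, sub, spec.kind, realized)


def simulate_pixel(
    archive: ArchiveModel,
    events: Sequence[EventSpec],
    seed: int | np.random.Generator,
) -> tuple[PixelSeries, PixelTruth]:
    """Simulate the dated label series of one pixel.

    Outside events, valid observations are potential forest; inside an event,
    valid observations are potential disruption at a rate set by the event
    intensity.  Identical seeds yield identical output.
    """
    _validate_events(events, archive)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    days = archive.draw_calendar(rng)
    fractions = archive.invalid_fractions()
    years = year_of_day(days) if days.size else np.array([], dtype=int)
    f_per_obs = (
        fractions[np.clip(years - archive.first_year, 0, len(fractions) - 1)]
        if days.size
        else np.array([])
    )
    valid = rng.random(days.size) >= f_per_obs
    labels = np.full(days.size, int(ObservationLabel.FOREST), dtype=np.int8)

    spec0 = events[0] if events else None
    days, valid, labels, realized = _place_episodes(
        days, valid, labels, events, archive, rng, allow_insert=True
    )
    labels[~valid] = int(ObservationLabel.INVALID)
    truth = _truth_from_spec(spec0, realized)
    if len(events) > 1:
        truth.events = realized
    return PixelSeries(days, labels), truth


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene."""

    class_raster: np.ndarray     # TransitionClass codes, uint8
    subclass_raster: np.ndarray  # subclass codes, int16
    kinds: np.ndarray            # event-kind index per pixel (-1 = none)
    geometry: GridGeometry
    event_catalog: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "geometry": {
                    "rows": self.geometry.rows,
                    "cols": self.geometry.cols,
                    "cell_size": self.geometry.cell_size,
                },
                "events": self.event_catalog,
            },
            indent=1,
        )


#: Fixed study conditions of the scene generator: onset windows and duration
#: ranges (days) per event kind.  Durations keep short degradation below one
#: year and give deforestation processes a comfortably >900-day footprint.
SCENE_EVENT_PARAMS = {
    "degradation": {"onset": ("1997-01-01", "2004-12-31"), "duration": (30, 300),
                    "intensity": 8.0},
    "deforestation": {"onset": ("1997-01-01", "2004-12-31"), "duration": None,
                      "intensity": 365.0},
    "deforestation_after_degradation": {
        "onset": ("2000-01-01", "2006-12-31"), "duration": None,
        "intensity": 365.0, "precursor_duration": (60, 240),
        "precursor_gap": (730, 1095),
    },
    "regrowth_after_deforestation": {
        "onset": ("1997-01-01", "2004-12-31"), "duration": (1400, 1700),
        "intensity": 365.0,
    },
}


def _draw_event_spec(kind: str, rng: np.random.Generator) -> EventSpec:
    params = SCENE_EVENT_PARAMS[kind]
    o0, o1 = (day_number(d) for d in params["onset"])
    onset_day = int(rng.integers(o0, o1 + 1))
    onset = np.datetime64(int(onset_day), "D")
    duration = 0
    if params["duration"] is not None:
        duration = int(rng.integers(params["duration"][0], params["duration"][1] + 1))
    kwargs = {}
    if kind == "deforestation_after_degradation":
        kwargs["precursor_duration_days"] = int(
            rng.integers(params["precursor_duration"][0], params["precursor_duration"][1] + 1)
        )
        kwargs["precursor_gap_days"] = int(
            rng.integers(params["precursor_gap"][0], params["precursor_gap"][1] + 1)
        )
    return EventSpec(
        kind=kind,
        onset=str(onset),
        duration_days=duration,
        intensity=params["intensity"],
        **kwargs,
    )


def simulate_scene(
    n_rows: int,
    n_cols: int,
    event_rate_map: dict[str, float],
    archive: ArchiveModel,
    seed: int,
    geometry: Optional[GridGeometry] = None,
):
    """Simulate a whole scene sharing one acquisition calendar.

    Returns ``(dates, label_stack, truth)`` where ``label_stack`` has shape
    (time, rows, cols) with ObservationLabel codes and ``truth`` is a
    :class:`SceneTruth` consistent with the generated series.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    for kind in event_rate_map:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
    probs = np.array([event_rate_map.get(k, 0.0) for k in EVENT_KINDS])
    if np.any(probs < 0) or probs.sum() > 1.0 + 1e-12:
        raise ValueError("event probabilities must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = GridGeometry(rows=n_rows, cols=n_cols)

    days = archive.draw_calendar(rng)
    n_t = days.size
    fractions = archive.invalid_fractions()
    years = year_of_day(days)
    f_per_obs = fractions[np.clip(years - archive.first_year, 0, len(fractions) - 1)]
    valid = rng.random((n_t, n_rows, n_cols)) >= f_per_obs[:, None, None]

    kind_idx = rng.choice(
        len(EVENT_KINDS) + 1,
        size=(n_rows, n_cols),
        p=np.append(probs, 1.0 - probs.sum()),
    )
    kind_idx = np.where(kind_idx == len(EVENT_KINDS), -1, kind_idx).astype(np.int8)

    labels = np.where(valid, int(ObservationLabel.FOREST), int(ObservationLabel.INVALID)).astype(np.int8)
    class_raster = np.full((n_rows, n_cols), int(TransitionClass.UNDISTURBED), np.uint8)
    subclass_raster = np.zeros((n_rows, n_cols), dtype=np.int16)
    catalog: dict[str, list[dict]] = {}

    for r in range(n_rows):
        for c in range(n_cols):
            ki = int(kind_idx[r, c])
            if ki < 0:
                continue
            kind = EVENT_KINDS[ki]
            spec = _draw_event_spec(kind, rng)
            pvalid = valid[:, r, c]
            plabels = np.where(pvalid, int(ObservationLabel.FOREST), int(ObservationLabel.FOREST)).astype(np.int8)
            # labels start as forest; invalidity is applied afterwards
            _, pvalid, plabels, realized = _place_episodes(
                days, pvalid.copy(), plabels, [spec], archive, rng, allow_insert=False
            )
            plabels[~pvalid] = int(ObservationLabel.INVALID)
            labels[:, r, c] = plabels
            valid[:, r, c] = pvalid
            truth = _truth_from_spec(spec, realized)
            if not realized:
                # the calendar never sampled the event window: the pixel is
                # unobservable as disturbed and its truth is undisturbed
                truth = PixelTruth(TransitionClass.UNDISTURBED, SUBCLASS_NONE, None, [])
                kind_idx[r, c] = -1
            class_raster[r, c] = int(truth.transition_class)
            subclass_raster[r, c] = truth.subclass
            if truth.events:
                catalog[f"{r},{c}"] = truth.events

    truth = SceneTruth(
        class_raster=class_raster,
        subclass_raster=subclass_raster,
        kinds=kind_idx,
        geometry=geometry,
        event_catalog=catalog,
    )
    return np.asarray(days), labels, truth


def simulate_spectra(
    labels: np.ndarray,
    signatures: Optional[dict[str, dict[str, float]]] = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    bands: Sequence[str] = ("red", "nir", "swir2", "green", "swir1", "thermal"),
    thermal_noise_sd: Optional[float] = None,
) -> dict[str, np.ndarray]:
    """Generate multispectral observations for a label array of any shape.

    Forest and disruption labels draw from the corresponding signatures;
    invalid labels draw from the cloud or shadow signature with equal
    probability.  Gaussian noise of standard deviation ``noise_sd`` is added
    to reflectance bands (clipped to [0, 1]); thermal noise defaults to
    ``noise_sd * 100`` Kelvin.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    sig = signatures or DEFAULT_SIGNATURES
    for key in ("forest", "disruption", "cloud", "shadow"):
        if key not in sig:
            raise ValueError(f"signature config must provide {key!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = np.asarray(labels)
    shadow = (labels == int(ObservationLabel.INVALID)) & (
        rng.random(labels.shape) < 0.5
    )
    # signature index per observation: forest/disruption/cloud/shadow
    names = ("cloud", "forest", "disruption")
    out: dict[str, np.ndarray] = {}
    t_sd = noise_sd * 100.0 if thermal_noise_sd is None else thermal_noise_sd
    for band in bands:
        means = np.choose(
            np.clip(labels, 0, 2), [sig[n][band] for n in names]
        ).astype(float)
        means = np.where(shadow, sig["shadow"][band], means)
        if band == "thermal":
            vals = means + (rng.standard_normal(labels.shape) * t_sd if t_sd else 0.0)
        else:
            vals = means + (
                rng.standard_normal(labels.shape) * noise_sd if noise_sd else 0.0
            )
            vals = np.clip(vals, 0.0, 1.0)
        out[band] = vals
    return out
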