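"""Single-date multispectral classification.

Every observation is assigned exactly one of three labels: potential moist
forest, potential disruption, or invalid (cloud / shadow / haze / sensor
issue).  The decision works on an HSV transform of the (SWIR2, NIR, red)
band triple — with SWIR2, NIR and red mapped to the R, G and B channel roles
in that order — complemented by brightness temperature and the normalized
difference water index NDWI = (green - NIR)/(green + NIR).

The published system derives its class boundaries from a large interpreted
spectral library; those exact cluster-hull equations are not part of this
package.  Instead the module ships a documented, fully overridable
:class:`RuleConfig` whose default thresholds are calibrated against the
synthetic signatures bundled in :mod:`tmfmonitor.simulate`:

* hue separates moist forest (high hue, strong NIR dominance) from disrupted
  surfaces, and is stable under multiplicative (atmospheric) effects;
* value catches cloud shadows (dark) and bright clouds;
* brightness temperature catches cold clouds and haze;
* NDWI > 0 flags open water / irrigated surfaces as disruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import GridGeometry
from .labels import ObservationLabel

_LABEL_BY_NAME = {
    "FOREST": ObservationLabel.FOREST,
    "DISRUPTION": ObservationLabel.DISRUPTION,
    "INVALID": ObservationLabel.INVALID,
}

_OPS = {
    "lt": np.less,
    "le": np.less_equal,
    "gt": np.greater,
    "ge": np.greater_equal,
}

FEATURES = ("hue", "saturation", "value", "thermal", "ndwi", "red", "nir", "swir2")


def hsv_transform(swir2, nir, red):
    """Standard HSV transform of the (SWIR2, NIR, red) triple.

    The three inputs play the R, G, B channel roles in that order.  Returns
    (hue in degrees [0, 360), saturation in [0, 1], value in [0, 1]).
    Accepts scalars or broadcastable arrays; inputs must lie in [0, 1].
    """
    r = np.asarray(swir2, dtype=float)
    g = np.asarray(nir, dtype=float)
    b = np.asarray(red, dtype=float)
    for band in (r, g, b):
        if np.any((band < 0) | (band > 1)):
            raise ValueError("reflectance inputs must lie in [0, 1]")
    v = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    c = v - mn
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(v > 0, c / np.where(v > 0, v, 1.0), 0.0)
        safe_c = np.where(c > 0, c, 1.0)
        hr = np.mod((g - b) / safe_c, 6.0)
        hg = (b - r) / safe_c + 2.0
        hb = (r - g) / safe_c + 4.0
    h = np.where(v == r, hr, np.where(v == g, hg, hb))
    h = np.where(c > 0, h * 60.0, 0.0)
    h = np.mod(h, 360.0)
    if h.ndim == 0:
        return float(h), float(s), float(v)
    return h, s, v


@dataclass(frozen=True)
class SpectralObservation:
    """One dated multispectral observation of a pixel."""

    date: str | np.datetime64
    red: float
    nir: float
    swir2: float
    thermal: Optional[float] = None   # brightness temperature, Kelvin
    green: Optional[float] = None
    swir1: Optional[float] = None
    band_complete: bool = True

    def __post_init__(self) -> None:
        for name in ("red", "nir", "swir2", "green", "swir1"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} reflectance {val} outside [0, 1]")


@dataclass(frozen=True)
class Rule:
    """One inequality rule: all conditions must hold for the rule to fire."""

    name: str
    label: ObservationLabel
    conditions: tuple[tuple[str, str, float], ...]  # (feature, op, threshold)

    def __post_init__(self) -> None:
        for feature, op, _ in self.conditions:
            if feature not in FEATURES:
                raise ValueError(f"unknown feature {feature!r}")
            if op not in _OPS:
                raise ValueError(f"unknown operator {op!r}")


@dataclass
class RuleConfig:
    """Ordered, total rule set for single-date classification.

    Rules are evaluated in sequence; the first whose conditions all hold
    assigns the label.  INVALID rules must come first (observations that
    cannot be trusted must be removed before any thematic call), and the
    final rule must be unconditional so that every observation receives
    exactly one label.
    """

    rules: list[Rule] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rules:
            return
        if self.rules[-1].conditions:
            raise ValueError("last rule must be an unconditional fallback")
        seen_thematic = False
        for rule in self.rules:
            if rule.label != ObservationLabel.INVALID:
                seen_thematic = True
            elif seen_thematic:
                raise ValueError("INVALID rules must precede thematic rules")

    @classmethod
    def from_dict(cls, payload: dict) -> "RuleConfig":
        rules = [
            Rule(
                name=item["name"],
                label=_LABEL_BY_NAME[item["label"]],
                conditions=tuple(
                    (c["feature"], c["op"], float(c["threshold"]))
                    for c in item.get("conditions", [])
                ),
            )
            for item in payload["rules"]
        ]
        return cls(rules=rules, metadata=dict(payload.get("metadata", {})))

    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "name": r.name,
                    "label": r.label.name,
                    "conditions": [
                        {"feature": f, "op": o, "threshold": t}
                        for f, o, t in r.conditions
                    ],
                }
                for r in self.rules
            ],
            "metadata": dict(self.metadata),
        }


def default_rules() -> RuleConfig:
    """Default rule set, calibrated against the bundled synthetic signatures."""
    mk = Rule
    inv = ObservationLabel.INVALID
    forest = ObservationLabel.FOREST
    disruption = ObservationLabel.DISRUPTION
    return RuleConfig(
        rules=[
            mk("cloud_shadow_dark", inv, (("value", "lt", 0.055),)),
            mk("cold_cloud", inv, (("thermal", "lt", 283.0),)),
            mk("bright_cloud_haze", inv, (("value", "gt", 0.45),)),
            mk("water_irrigated", disruption, (("ndwi", "gt", 0.0),)),
            mk("strong_swir_disruption", disruption, (("swir2", "ge", 0.17),)),
            mk("moist_forest_hue", forest, (("hue", "ge", 90.0), ("saturation", "ge", 0.6))),
            mk(
                "moist_forest_bands",
                forest,
                (("nir", "ge", 0.24), ("red", "le", 0.075), ("swir2", "le", 0.14)),
            ),
            mk("disruption_fallback", disruption, ()),
        ],
        metadata={
            "hsv_channel_order": "(swir2, nir, red) -> (R, G, B)",
            "ndwi": "(green - nir) / (green + nir)",
            "calibration": "synthetic signature library bundled with the simulator",
        },
    )


def _features_from_arrays(
    red: np.ndarray,
    nir: np.ndarray,
    swir2: np.ndarray,
    thermal: Optional[np.ndarray],
    green: Optional[np.ndarray],
) -> dict[str, Optional[np.ndarray]]:
    hue, sat, val = hsv_transform(swir2, nir, red)
    ndwi = None
    if green is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = green + nir
            ndwi = np.where(denom > 0, (green - nir) / np.where(denom > 0, denom, 1.0), 0.0)
    return {
        "hue": np.asarray(hue),
        "saturation": np.asarray(sat),
        "value": np.asarray(val),
        "thermal": thermal,
        "ndwi": ndwi,
        "red": red,
        "nir": nir,
        "swir2": swir2,
    }


def _apply_rules(
    features: dict[str, Optional[np.ndarray]],
    rules: RuleConfig,
    shape: tuple[int, ...],
) -> np.ndarray:
    labels = np.full(shape, -1, dtype=np.int8)
    unassigned = np.ones(shape, dtype=bool)
    for rule in rules.rules:
        if not unassigned.any():
            break
        match = unassigned.copy()
        for feature, op, threshold in rule.conditions:
            values = features.get(feature)
            if values is None:
                # a rule on an absent optional band can never fire
                match[:] = False
                break
            match &= _OPS[op](values, threshold)
        labels[match] = int(rule.label)
        unassigned &= ~match
    return labels


def classify_observation(obs: SpectralObservation, rules: RuleConfig) -> ObservationLabel:
    """Label one observation; observations with missing required bands are INVALID."""
    if not obs.band_complete:
        return ObservationLabel.INVALID
    features = _features_from_arrays(
        np.array([obs.red], dtype=float),
        np.array([obs.nir], dtype=float),
        np.array([obs.swir2], dtype=float),
        None if obs.thermal is None else np.array([obs.thermal], dtype=float),
        None if obs.green is None else np.array([obs.green], dtype=float),
    )
    label = _apply_rules(features, rules, shape=(1,))
    return ObservationLabel(int(label[0]))


@dataclass
class ObservationStack:
    """Dated multi-band acquisitions on a shared grid.

    ``bands`` maps band name -> float array of shape (time, rows, cols);
    ``band_complete`` flags per-observation band completeness.
    """

    dates: np.ndarray                       # datetime64[D] or day numbers, per acquisition
    bands: dict[str, np.ndarray]
    geometry: GridGeometry
    band_complete: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shapes = {name: arr.shape for name, arr in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"band arrays disagree in shape: {shapes}")
        t, rows, cols = next(iter(shapes.values()))
        if (rows, cols) != self.geometry.shape:
            raise ValueError("band grids do not match the stack geometry")
        if len(np.asarray(self.dates)) != t:
            raise ValueError("date index length does not match the time axis")

    @property
    def n_dates(self) -> int:
        return len(np.asarray(self.dates))


def classify_stack(stack: ObservationStack, rules: RuleConfig):
    """Classify every acquisition of a stack.

    Returns ``(dates, labels)`` where labels has shape (time, rows, cols) and
    acquisitions are sorted into strict date order regardless of input order.
    """
    from .trajectory import as_day_numbers  # local import to avoid a cycle

    days = as_day_numbers(stack.dates)
    order = np.argsort(days, kind="stable")
    days = days[order]

    required = ("red", "nir", "swir2")
    for band in required:
        if band not in stack.bands:
            raise ValueError(f"stack is missing required band {band!r}")
    red = stack.bands["red"][order]
    nir = stack.bands["nir"][order]
    swir2 = stack.bands["swir2"][order]
    thermal = stack.bands.get("thermal")
    green = stack.bands.get("green")
    features = _features_from_arrays(
        red,
        nir,
        swir2,
        None if thermal is None else thermal[order],
        None if green is None else green[order],
    )
    labels = _apply_rules(features, rules, shape=red.shape)
    if stack.band_complete is not None:
        labels[~stack.band_complete[order]] = int(ObservationLabel.INVALID)
    return days, labels
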