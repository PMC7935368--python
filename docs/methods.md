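# Methods

This note documents the models, rules and numerical choices behind
`tmfmonitor`, what the synthetic data generator does and does not emulate,
and the known limitations.

## Observation model

The unit of evidence is a dated, single-pixel, single-date observation
labeled *potential moist forest*, *potential disruption* (absence of tree
foliage cover), or *invalid*. All change inference is driven by the temporal
sequence of these labels; no composite or annual synthesis is formed. A
*disruption observation* is the atom of disturbance evidence, and the count
of disruption observations within an event is the proxy of disturbance
intensity; the span between the first and last disruption observation of an
event is the proxy of disturbance impact.

## Single-date classification

Features: hue/saturation/value of the (SWIR2, NIR, red) triple — with SWIR2,
NIR and red mapped to the R, G and B channel roles *in that order* (the
published band combination lists the bands in this order without stating
channel roles; the mapping is documented prominently because hue values
depend on it) — plus thermal brightness temperature and NDWI = (green − NIR)/(green +
NIR). The published description names NDWI without giving a formula; the
green/NIR form used here is recorded in the rule-config metadata.

The original expert system derives its class boundaries from a ~38k-pixel
interpreted spectral library; those cluster-hull equations are not public.
This package instead ships a small, fully user-overridable ordered rule set
(`RuleConfig`), whose defaults are calibrated once against the synthetic
signature library bundled with the simulator:

| rule | condition | label |
|---|---|---|
| cloud_shadow_dark | value < 0.055 | invalid |
| cold_cloud | thermal < 283 K | invalid |
| bright_cloud_haze | value > 0.45 | invalid |
| water_irrigated | NDWI > 0 | disruption |
| strong_swir_disruption | SWIR2 ≥ 0.17 | disruption |
| moist_forest_hue | hue ≥ 90° ∧ saturation ≥ 0.6 | forest |
| moist_forest_bands | NIR ≥ 0.24 ∧ red ≤ 0.075 ∧ SWIR2 ≤ 0.14 | forest |
| fallback | — | disruption |

Invalid rules are evaluated first (untrustworthy observations must be
removed before any thematic call); the last rule is unconditional, so the
rule set is total. Thresholds sit at class-boundary midpoints of the
bundled signatures; hue is used because it is stable under multiplicative
(atmospheric) effects — a property the test suite asserts. Reflectances are
fixed to [0, 1]; whether the original hulls operate on TOA reflectance or
digital numbers per sensor is unstated, so the package standardizes on
reflectance.

## Baseline qualification

A pixel enters the initial TMF extent only after a qualification window
starting at its first valid observation: 4 consecutive calendar years with
≥ 3 valid observations each (rule A) or 5 consecutive years with ≥ 2
(rule B). The earliest window by end year wins; rule A wins ties. The
baseline runs to 31 December of the window's last year; the monitoring
period starts the next day. The pixel is TMF iff *every* valid baseline
observation is forest. Baseline disruptions recurring in the same calendar
months across ≥ 2 years set a `seasonal_nonforest` flag (deciduous
forest/agriculture signature); non-TMF baselines map to *other land cover*.

## Event segmentation and transition rules

Monitoring-period disruption observations are grouped into maximal episodes:
two consecutive disruptions belong to different events iff they are ≥ 365
days apart **and** at least one valid forest observation lies between them.
An invalid-only gap carries no evidence of recovery and never splits an
event (design choice: the recovery notion presupposes observed forest).
Durations run between disruption observations only; invalid observations
never contribute.

Decision sequence for qualified TMF pixels:

1. no events → **undisturbed**;
2. an event with duration > 900 days is a deforestation process. If no
   disruption follows it and the first forest observation after it is ≥ 1095
   days before the monitoring end → **forest regrowth**, else
   **deforested**. The record is tagged *deforestation of degraded forest*
   when an earlier, separate event exists (events are ≥ 1 year apart by
   construction, matching the definitional gap);
3. a last event initiated after 2016 → **recent**, provisionally split into
   deforestation (2017–2018 onsets with duration ≥ 366 days; final-year
   onsets with ≥ 10 disruption observations) vs degradation; the class stays
   explicit in the transition map and the provisional split is exported;
4. otherwise **degraded**: short subclass if the longest event lasted ≤ 365
   days, long subclass for 366–900 days; tagged with the decade of the last
   disruption. Multiple degradation events in one record are kept as
   separate events and their count exported (degradation multiplicity).

Non-TMF pixels whose last disruption is followed by ≥ 1095 days of sustained
forest become **vegetation regrowth**, with age subclasses (3–10 / 10–20
years).

Day-valued constants are honored verbatim (900, 365/366, 1095 days) rather
than normalized to a single year convention, since the published constants
themselves mix conventions (2.5 years ↔ 900 days). Recurrence divides the
number of calendar years containing a disruption by the inclusive span of
years between the first and last disruption (2000→2005 spans 6 years); the
inclusive convention is a documented choice. The minimum number of
disruption observations to confirm a non-recent event is 1 (configurable);
a stricter minimum would trade omission for commission errors.

Censoring behaves monotonically on the undisturbed → degraded/recent →
deforested chain: truncating a record earlier can only move a pixel down
that chain, never up. Regrowth classes are excluded from this guarantee — a
record truncated before its regrowth window legitimately reads deforested.

## Products

Annual states replay each pixel's event timeline; a disturbance is
attributed to the year of its *first* disruption observation (a November
onset counts for that year), and a degraded pixel never re-enters the
undisturbed pool. The published system derives annual maps from dedicated
supplementary decision rules that are not public; this reconstruction
derives them directly from the event timelines with the same thresholds.
The 120 m edge buffer uses Euclidean center-to-center distance (disc of
radius 4 pixels at 30 m, 49 pixels for an isolated disturbance), not a
Chebyshev square, because the threshold is metric. Hotspot cells are 1°×1°;
a pixel on a cell boundary belongs to the cell containing its center.
Plantation/water/mangrove/bamboo subclasses come exclusively from caller
supplied masks; the package performs no spectral commodity or mangrove
detection.

## Area statistics

Areas are pixel counts × 0.09 ha. Both raw and rounded percentages are
exposed because printed tables round independently of prose (e.g. the same
areas yield 16.96% ≈ 17.0% in a table and are quoted as 17.2% in text; the
package always computes from areas). Periods are closed calendar-year
intervals. Territory cells whose mean invalid fraction exceeds 40% carry a
provenance flag that propagates through derived statistics. Recent-year
(2017–2019) disturbance-type proportions can be recalibrated to mean
2005–2014 shares with year totals preserved.

## Validation estimators

Stratified design-based estimators: p̂ᵢⱼ = Wᵢnᵢⱼ/nᵢ; OA = Σp̂ᵢᵢ; UAᵢ =
p̂ᵢᵢ/Σⱼp̂ᵢⱼ; PAⱼ = p̂ⱼⱼ/Σᵢp̂ᵢⱼ; Âⱼ = AΣᵢWᵢnᵢⱼ/nᵢ with
SE(Âⱼ) = A√(ΣᵢWᵢ²(nᵢⱼ/nᵢ)(1−nᵢⱼ/nᵢ)/(nᵢ−1)); intervals use 1.96 (a
t-quantile switch exists for small strata). The producer's-accuracy variance
uses stratum weights in place of pixel totals — the expression is scale
invariant. Sample allocation is proportional with a floor of two plots per
stratum and systematic placement with a seeded random start (the original
design states stratified systematic sampling but not the allocation rule).
Plot-level (3×3 pixel) labels reduce by majority, ties to the disturbed
class; the same reduction is applied to both the map and the reference side.
These Wald-type intervals reach nominal coverage for per-stratum sample
sizes in the hundreds — the scale of the real validation design (5250
plots), and the scale at which the coverage checks run.

## Projection

Annual disturbed areas dₜ are treated as i.i.d. log-normal per territory;
with yₜ = ln dₜ, the mean annual loss is exp(ȳ + s²/2) and its 95% interval
the modified Cox form exp(ȳ + s²/2 ± t₍ₙ₋₁₎√(s²/n + s⁴/(2(n−1)))) — the
t-quantile is what makes the method "modified"; a plain-z switch exists for
comparison. Area depletes linearly at the estimated 2010–2019 mean rate
from end-2019 (constant-rate business-as-usual, no compounding), floored at
zero; the disappearance year is the first year whose end-of-year area
reaches zero. Zero annual losses break log-normal support and are floored
at 10⁻³ × the smallest positive loss, with a warning; an all-zero series is
rejected. Projections default to the total disturbance of undisturbed
forest (degradation + deforestation), with the deforestation-only series
equally available.

## Synthetic data generator

The generator emulates: uneven acquisition density over 1982–2019 (the
`landsat_like` preset is sparse before 1999, has jumps in 1999 and 2013 and
a small 2003 dip; the `dense` preset is uniform and is the reference
condition for round-trip tests), per-observation invalidity, four event
kinds (degradation; deforestation; deforestation after degradation with a
≥ 366-day definitional gap; deforestation followed by regrowth), and
forest/disruption/cloud/shadow spectral signatures with Gaussian band noise.
Acquisition dates are drawn as a Poisson process within each year; during a
degradation event, valid observations alternate between disruption and
forest at a rate set by the event intensity; after the event end only forest
occurs. For the `deforestation` kind, disruptions persist to the archive
end, since deforested land stays non-forest.

Ground truth is defined at the level of *observable* events: each episode is
anchored to the acquisitions falling inside its window (the first — and for
bounded episodes the last — acquisition in the window is made a valid
disruption observation), and the truth duration is the realized span between
those acquisitions. An event that no acquisition samples is recorded as
undisturbed truth. This conditioning is what makes exact round-trip
statements meaningful for arbitrarily short events.

Scene defaults (fixed study conditions): onsets uniform in 1997–2004
(2000–2006 for deforestation after degradation), short degradation durations
30–300 days at intensity 8/yr, deforestation intensities high enough that
every valid in-event observation is a disruption, regrowth-kind clearance
durations 1400–1700 days.

Not emulated: spatial autocorrelation of disturbances (events are i.i.d.
per pixel, so simulated scenes are salt-and-pepper rather than patchy —
plot-majority validation behaves differently than on real, clustered
landscapes), radiative transfer, phenology, topography, BRDF, cross-sensor
differences, and geolocation error. Passing round-trip tests therefore
demonstrates the correctness of the rule logic and estimators, not
real-data accuracy.

## Problem sizes and numerics

Round-trip scenes are 100×100 pixels (10⁴ trajectories) with 12 expected
valid observations/year; exhaustive oracle agreement enumerates all 3-label
sequences of length ≤ 12 on a 120-day lattice behind a fixed qualifying
baseline (~800k series), plus a prefix-free lattice that exercises baseline
qualification itself; coverage checks use 2000 Monte-Carlo replicates.
Deterministic seeding covers every random draw (acquisition calendars,
validity, event placement, noise, sampling designs). Raster I/O is
plain-text ESRI ASCII grid; GeoTIFF is intentionally not produced, keeping
the package free of binary format dependencies.

## Known limitations

Sub-pixel disturbances are out of scope (a pixel is the atomic unit).
Seasonal-water vs permanent-water and commodity subclasses depend entirely
on input mask quality. The recent-rules window is keyed to calendar year
2017 by default and must be moved along with a different monitoring end.
Transition classes for pixels whose record ends during an ambiguous stage
(recent class) remain provisional by design.
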