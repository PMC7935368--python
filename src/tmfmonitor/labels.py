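"""Label and class vocabularies shared across the pipeline.

Single-date observation labels and end-of-record transition classes use small
integer codes so that grids can be stored as compact category rasters.
"""

from __future__ import annotations

from enum import IntEnum


class ObservationLabel(IntEnum):
    """Single-date classification of one pixel observation."""

    INVALID = 0          # cloud, cloud shadow, haze, sensor issue, missing bands
    FOREST = 1           # potential moist forest cover
    DISRUPTION = 2       # potential disruption (absence of tree foliage cover)


class TransitionClass(IntEnum):
    """End-of-record transition class of a pixel (main classes 1-7)."""

    UNDISTURBED = 1      # moist forest, no disturbance observed over the record
    DEFORESTED = 2       # long-term conversion to non-forest
    DEGRADED = 3         # disturbance visible < 2.5 years, still forest
    RECENT = 4           # disturbance initiated in the last 3 years, not yet attributable
    FOREST_REGROWTH = 5  # regrowth after a deforestation episode
    OTHER_LC = 6         # never moist forest during the baseline (savanna, agriculture, ...)
    VEG_REGROWTH = 7     # other land cover followed by sustained vegetation regrowth


# Subclass codes, compatible with their main class.
SUBCLASS_NONE = 0
SUBCLASS_BAMBOO = 11            # 1a
SUBCLASS_MANGROVE = 12          # 1b
SUBCLASS_PLANTATION = 21        # 2a
SUBCLASS_WATER = 22             # 2b
SUBCLASS_OTHER_CONVERSION = 23  # 2c
SUBCLASS_DEGR_SHORT = 31        # 3a: impacts observed <= 1 year
SUBCLASS_DEGR_LONG = 32         # 3b: impacts observed 1-2.5 years
SUBCLASS_RECENT_DEGRADATION = 41
SUBCLASS_RECENT_DEFORESTATION = 42
SUBCLASS_REGROWTH_3_10 = 71     # regrowth aged 3-10 years
SUBCLASS_REGROWTH_10_20 = 72    # regrowth aged 10-20 years
SUBCLASS_REGROWTH_FROM_WATER = 73

SUBCLASS_NAMES = {
    SUBCLASS_NONE: "none",
    SUBCLASS_BAMBOO: "undisturbed_bamboo",
    SUBCLASS_MANGROVE: "undisturbed_mangrove",
    SUBCLASS_PLANTATION: "deforested_to_plantation",
    SUBCLASS_WATER: "deforested_to_water",
    SUBCLASS_OTHER_CONVERSION: "deforested_other",
    SUBCLASS_DEGR_SHORT: "degradation_short_duration",
    SUBCLASS_DEGR_LONG: "degradation_long_duration",
    SUBCLASS_RECENT_DEGRADATION: "recent_degradation",
    SUBCLASS_RECENT_DEFORESTATION: "recent_deforestation",
    SUBCLASS_REGROWTH_3_10: "vegetation_regrowth_3_10yr",
    SUBCLASS_REGROWTH_10_20: "vegetation_regrowth_10_20yr",
    SUBCLASS_REGROWTH_FROM_WATER: "vegetation_regrowth_from_water",
}


class AnnualState(IntEnum):
    """Per-year pixel state in the annual change collection."""

    NODATA = 0
    UNDISTURBED = 1
    DEGRADED = 2
    DEFORESTED = 3
    REGROWTH = 4
    OTHER = 5


class AnnualChangeClass(IntEnum):
    """The ten annual transition categories used by the trend statistics."""

    NONE = 0
    DEGR_SHORT = 1            # short degradation, recovery, never deforested
    DEGR_LONG = 2             # long degradation, recovery, never deforested
    DEGR_BEFORE_DEFOR = 3     # degradation later followed by deforestation
    DEGR_BEFORE_DEFOR_REGROWTH = 4
    DIRECT_DEFOR = 5          # deforestation of undisturbed forest, no recovery
    DIRECT_DEFOR_REGROWTH = 6
    DEFOR_OF_DEGRADED = 7
    DEFOR_OF_DEGRADED_REGROWTH = 8
    DEFOR_TO_WATER = 9
    DEFOR_TO_COMMODITIES = 10


class DecadeTag(IntEnum):
    """Decadal timing tag for degradation and regrowth classes."""

    NONE = 0
    PRE_2000 = 1
    D2000S = 2
    D2010S = 3


def decade_of(year: int) -> DecadeTag:
    if year < 2000:
        return DecadeTag.PRE_2000
    if year < 2010:
        return DecadeTag.D2000S
    return DecadeTag.D2010S


#: Area of one 30 m x 30 m pixel in hectares.
PIXEL_AREA_HA = 0.09
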