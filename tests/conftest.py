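import numpy as np
import pytest

from tmfmonitor.simulate import ArchiveModel
from tmfmonitor.trajectory import PixelSeries, Thresholds, day_number


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture
def dense_archive() -> ArchiveModel:
    return ArchiveModel.dense()


def make_series(observations) -> PixelSeries:
    """Build a PixelSeries from (iso-date, label-code) pairs."""
    observations = sorted(observations)
    dates = np.array([day_number(d) for d, _ in observations], dtype=np.int64)
    labels = np.array([l for _, l in observations], dtype=np.int8)
    return PixelSeries(dates, labels)


def forest_baseline(years=(1990, 1991, 1992, 1993), per_year=3):
    """Valid forest observations qualifying rule A by default."""
    months = (1, 5, 9, 11)[:per_year]
    return [(f"{y}-{m:02d}-15", 1) for y in years for m in months]


@pytest.fixture
def baseline_obs():
    return forest_baseline()
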