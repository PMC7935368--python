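"""Baseline qualification, event segmentation and transition-class rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmfmonitor.labels import (
    DecadeTag,
    ObservationLabel,
    SUBCLASS_DEGR_LONG,
    SUBCLASS_DEGR_SHORT,
    SUBCLASS_RECENT_DEFORESTATION,
    TransitionClass,
)
from tmfmonitor.trajectory import (
    PixelSeries,
    Thresholds,
    classify_grid,
    classify_series,
    day_number,
    determine_baseline,
    recurrence,
    segment_events,
)

from .conftest import forest_baseline, make_series
from .oracle import classify_oracle, oracle_to_tuple, record_to_tuple

F, D, I = 1, 2, 0


class TestBaseline:
    def test_rule_a_four_years_three_obs(self, thresholds):
        series = make_series(forest_baseline())
        res = determine_baseline(series, thresholds)
        assert res.qualifies and res.rule_used == "A" and res.is_tmf
        assert res.baseline_end == day_number("1993-12-31")

    def test_rule_b_five_years_two_obs(self, thresholds):
        obs = [(f"{y}-{m:02d}-10", F) for y in range(1990, 1995) for m in (3, 9)]
        res = determine_baseline(make_series(obs), thresholds)
        assert res.qualifies and res.rule_used == "B"
        assert res.baseline_end == day_number("1994-12-31")

    def test_record_too_short_never_qualifies(self, thresholds):
        obs = [(f"{y}-{m:02d}-10", F) for y in (2017, 2018, 2019) for m in (1, 6, 11)]
        res = determine_baseline(make_series(obs), thresholds)
        assert not res.qualifies

    def test_sparse_years_defer_qualification(self, thresholds):
        # one obs/yr 1990-1994, then 3/yr: window must slide past the sparse years
        obs = [(f"{y}-06-10", F) for y in range(1990, 1995)]
        obs += [(f"{y}-{m:02d}-10", F) for y in range(1995, 1999) for m in (1, 6, 11)]
        res = determine_baseline(make_series(obs), thresholds)
        assert res.qualifies and res.baseline_end == day_number("1998-12-31")

    def test_seasonal_disruptions_flag_nonforest(self, thresholds):
        obs = []
        for y in range(1990, 2020):
            obs += [(f"{y}-01-15", D), (f"{y}-02-15", D), (f"{y}-03-15", D)]
            obs += [(f"{y}-07-15", F), (f"{y}-09-15", F), (f"{y}-11-15", F)]
        res = determine_baseline(make_series(obs), thresholds)
        assert res.qualifies and not res.is_tmf and res.seasonal_nonforest
        rec = classify_series(make_series(obs), thresholds)
        assert rec.transition_class == TransitionClass.OTHER_LC

    def test_all_invalid_never_qualifies(self, thresholds):
        obs = [(f"{y}-06-10", I) for y in range(1990, 2000)]
        res = determine_baseline(make_series(obs), thresholds)
        assert not res.qualifies and res.fail_reason == "no_valid_observations"


class TestSegmentEvents:
    def test_single_episode(self, thresholds, baseline_obs):
        obs = baseline_obs + [
            ("2000-01-01", D), ("2000-01-31", D), ("2000-03-01", D),
            ("2001-06-01", F), ("2002-06-01", F),
        ]
        series = make_series(obs)
        events = segment_events(series, day_number("1994-01-01"), thresholds)
        assert len(events) == 1
        assert events[0].duration_days == 60
        assert events[0].n_disruptions == 3

    def test_two_events_with_forest_confirmed_gap(self, thresholds, baseline_obs):
        obs = baseline_obs + [("1995-02-01", D), ("1995-04-01", D)]
        obs += [(f"{y}-06-01", F) for y in range(1996, 2005)]
        obs += [("2005-06-01", D), ("2007-06-01", D), ("2009-08-01", D)]
        events = segment_events(make_series(obs), day_number("1994-01-01"), thresholds)
        assert len(events) == 2
        assert events[1].duration_days > 900

    def test_invalid_only_gap_does_not_split(self, thresholds, baseline_obs):
        # 400-day disruption-free gap but no valid forest observation inside
        obs = baseline_obs + [
            ("2000-01-01", D), ("2000-02-01", D),
            ("2000-08-01", I), ("2000-12-01", I),
            ("2001-03-10", D),
        ]
        events = segment_events(make_series(obs), day_number("1994-01-01"), thresholds)
        assert len(events) == 1
        assert events[0].n_disruptions == 3


class TestRecurrence:
    def test_single_year(self):
        days = np.array([day_number("2003-02-01"), day_number("2003-09-01")])
        assert recurrence([], days) == 1.0

    def test_three_of_six_years(self):
        days = np.array(
            [day_number(d) for d in ("2000-05-01", "2001-05-01", "2005-05-01")]
        )
        assert recurrence([], days) == pytest.approx(0.5)

    def test_saturated(self):
        days = np.array([day_number(f"{y}-06-01") for y in range(2000, 2010)])
        assert recurrence([], days) == 1.0

    def test_undefined_without_disruptions(self):
        with pytest.raises(ValueError):
            recurrence([], np.array([], dtype=np.int64))


def _classified(obs, thresholds):
    return classify_series(make_series(obs), thresholds)


class TestClassifyTrajectory:
    def test_no_events_undisturbed(self, thresholds, baseline_obs):
        rec = _classified(baseline_obs + [("2005-06-01", F)], thresholds)
        assert rec.transition_class == TransitionClass.UNDISTURBED

    def test_long_degradation_2000s(self, thresholds, baseline_obs):
        obs = baseline_obs + [
            ("2003-01-10", D), ("2003-08-10", D), ("2004-05-25", D),  # ~500 d span
        ] + [(f"{y}-06-01", F) for y in range(2006, 2020)]
        rec = _classified(obs, thresholds)
        assert rec.transition_class == TransitionClass.DEGRADED
        assert rec.subclass == SUBCLASS_DEGR_LONG
        assert rec.decade == DecadeTag.D2000S

    def test_short_degradation(self, thresholds, baseline_obs):
        obs = baseline_obs + [("1998-02-01", D), ("1998-04-01", D)]
        obs += [(f"{y}-06-01", F) for y in range(1999, 2020)]
        rec = _classified(obs, thresholds)
        assert rec.transition_class == TransitionClass.DEGRADED
        assert rec.subclass == SUBCLASS_DEGR_SHORT
        assert rec.decade == DecadeTag.PRE_2000

    def test_deforestation_then_sustained_regrowth(self, thresholds, baseline_obs):
        # cleared 2008-2012 (>900 d), forest again 2013-2019 (>1095 d)
        obs = baseline_obs + [(f"{y}-{m:02d}-01", D) for y in range(2008, 2013) for m in (3, 9)]
        obs += [(f"{y}-{m:02d}-01", F) for y in range(2013, 2020) for m in (2, 8)]
        rec = _classified(obs, thresholds)
        assert rec.transition_class == TransitionClass.FOREST_REGROWTH
        assert rec.regrowth_start_day == day_number("2013-02-01")

    def test_deforestation_of_degraded_forest(self, thresholds, baseline_obs):
        obs = baseline_obs + [("1998-02-01", D), ("1998-05-01", D)]  # 90 d degradation
        obs += [(f"{y}-06-01", F) for y in range(1999, 2006)]
        obs += [(f"{y}-{m:02d}-01", D) for y in range(2006, 2012) for m in (4, 10)]
        rec = _classified(obs, thresholds)
        assert rec.transition_class == TransitionClass.DEFORESTED
        assert rec.defor_after_degradation

    def test_recent_2019_onset_many_disruptions(self, thresholds, baseline_obs):
        obs = baseline_obs + [(f"{y}-06-01", F) for y in range(1994, 2019)]
        obs += [(f"2019-{m:02d}-{dd:02d}", D) for m in range(3, 9) for dd in (5, 20)]
        rec = _classified(obs, thresholds)
        assert rec.transition_class == TransitionClass.RECENT
        assert rec.provisional == "deforestation"
        assert rec.subclass == SUBCLASS_RECENT_DEFORESTATION

    def test_recent_2018_short_event_is_degradation(self, thresholds, baseline_obs):
        obs = baseline_obs + [(f"{y}-06-01", F) for y in range(1994, 2018)]
        obs += [("2018-03-01", D), ("2018-06-01", D), ("2019-06-01", F)]
        rec = _classified(obs, thresholds)
        assert rec.transition_class == TransitionClass.RECENT
        assert rec.provisional == "degradation"

    def test_veg_regrowth_from_other_land_cover(self, thresholds):
        obs = [(f"{y}-{m:02d}-05", D) for y in range(1990, 1995) for m in (2, 6, 10)]
        obs += [(f"{y}-{m:02d}-05", F) for y in range(1996, 2020) for m in (3, 9)]
        rec = _classified(obs, thresholds)
        assert rec.transition_class == TransitionClass.VEG_REGROWTH


class TestOracleAgreement:
    """Exhaustive agreement with the independent brute-force interpreter."""

    def test_exhaustive_monitoring_suffixes(self, thresholds):
        prefix = forest_baseline()
        prefix_days = [day_number(d) for d, _ in prefix]
        start = day_number("1994-03-01")
        n = 7
        suffix_days = [start + 120 * i for i in range(n)]
        dates = np.array(prefix_days + suffix_days, dtype=np.int64)
        for combo in itertools.product((I, F, D), repeat=n):
            labels = np.array([F] * len(prefix) + list(combo), dtype=np.int8)
            rec = classify_series(PixelSeries(dates, labels), thresholds)
            orc = classify_oracle(list(zip(dates.tolist(), labels.tolist())))
            assert record_to_tuple(rec) == oracle_to_tuple(orc), combo

    def test_exhaustive_baseline_lattice(self, thresholds):
        # no qualifying prefix: exercises rule A/B search, OTHER_LC, regrowth
        start = day_number("1990-04-01")
        n = 8
        dates = np.array([start + 183 * i for i in range(n)], dtype=np.int64)
        for combo in itertools.product((I, F, D), repeat=n):
            labels = np.array(combo, dtype=np.int8)
            rec = classify_series(PixelSeries(dates, labels), thresholds)
            orc = classify_oracle(list(zip(dates.tolist(), labels.tolist())))
            assert record_to_tuple(rec) == oracle_to_tuple(orc), combo


_random_series = st.lists(
    st.sampled_from([I, F, D]), min_size=0, max_size=20
).map(
    lambda labels: (
        np.array(
            [day_number("1994-02-01") + 150 * i for i in range(len(labels))],
            dtype=np.int64,
        ),
        np.array(labels, dtype=np.int8),
    )
)

_CLASS_RANK = {
    TransitionClass.UNDISTURBED: 0,
    TransitionClass.DEGRADED: 1,
    TransitionClass.RECENT: 1,
    TransitionClass.DEFORESTED: 2,
}


class TestProperties:
    @settings(max_examples=200, deadline=None)
    @given(_random_series)
    def test_oracle_agreement_random(self, series):
        days, labels = series
        prefix = forest_baseline()
        dates = np.concatenate(
            [np.array([day_number(d) for d, _ in prefix]), days]
        )
        full = np.concatenate([np.full(len(prefix), F, dtype=np.int8), labels])
        th = Thresholds()
        rec = classify_series(PixelSeries(dates, full), th)
        orc = classify_oracle(list(zip(dates.tolist(), full.tolist())))
        assert record_to_tuple(rec) == oracle_to_tuple(orc)

    @settings(max_examples=150, deadline=None)
    @given(_random_series)
    def test_censoring_moves_classes_forward_only(self, series):
        days, labels = series
        prefix = forest_baseline()
        dates = np.concatenate(
            [np.array([day_number(d) for d, _ in prefix]), days]
        )
        full_labels = np.concatenate(
            [np.full(len(prefix), F, dtype=np.int8), labels]
        )
        th = Thresholds()
        rec_full = classify_series(PixelSeries(dates, full_labels), th)
        if rec_full.transition_class not in _CLASS_RANK:
            return
        for cut in range(len(prefix), len(dates)):
            rec_cut = classify_series(
                PixelSeries(dates[:cut], full_labels[:cut]), th
            )
            if rec_cut.transition_class in _CLASS_RANK:
                assert (
                    _CLASS_RANK[rec_cut.transition_class]
                    <= _CLASS_RANK[rec_full.transition_class]
                )

    def test_duration_monotonicity_never_reverts_to_degradation(
        self, thresholds, baseline_obs
    ):
        # extending an event keeps or escalates the class, never de-escalates
        last_class_rank = 0
        for extra_days in (100, 400, 700, 1000, 1300):
            end = np.datetime64("2000-01-01") + np.timedelta64(extra_days, "D")
            obs = baseline_obs + [("2000-01-01", D), (str(end), D)]
            rec = _classified(obs, thresholds)
            rank = _CLASS_RANK[rec.transition_class]
            assert rank >= last_class_rank
            last_class_rank = rank

    def test_recurrence_bounds(self, thresholds, baseline_obs):
        rng = np.random.default_rng(11)
        for _ in range(50):
            years = sorted(rng.choice(range(1995, 2015), size=rng.integers(1, 8),
                                      replace=False))
            obs = list(forest_baseline()) + [(f"{y}-06-01", D) for y in years]
            rec = _classified(obs, thresholds)
            if rec.recurrence is not None:
                assert 0.0 < rec.recurrence <= 1.0


class TestClassifyGrid:
    def test_all_invalid_flagged(self, thresholds):
        dates = np.array([day_number(f"{y}-06-01") for y in range(1990, 2000)])
        stack = np.zeros((10, 2, 2), dtype=np.int8)  # all INVALID
        grid = classify_grid(dates, stack, thresholds)
        assert (grid.class_raster() == 0).all()
        assert grid.records[0][0].baseline.fail_reason == "no_valid_observations"

    def test_ingestion_order_invariance(self, thresholds):
        rng = np.random.default_rng(3)
        dates = np.array([day_number(f"{y}-{m:02d}-01") for y in range(1990, 2005)
                          for m in (2, 6, 10)])
        stack = rng.choice([0, 1, 2], size=(len(dates), 3, 3), p=[0.1, 0.7, 0.2]).astype(np.int8)
        grid1 = classify_grid(dates, stack, thresholds)
        perm = rng.permutation(len(dates))
        grid2 = classify_grid(dates[perm], stack[perm], thresholds)
        assert np.array_equal(grid1.class_raster(), grid2.class_raster())
        assert np.array_equal(
            grid1.metric_rasters()["n_disruptions"],
            grid2.metric_rasters()["n_disruptions"],
        )
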