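"""Transition map assembly, annual layers, edge buffer and hotspot grids."""

import numpy as np
import pytest

from tmfmonitor.geometry import GridGeometry
from tmfmonitor.labels import (
    AnnualChangeClass,
    AnnualState,
    PIXEL_AREA_HA,
    SUBCLASS_MANGROVE,
    SUBCLASS_OTHER_CONVERSION,
    SUBCLASS_WATER,
    TransitionClass,
)
from tmfmonitor.products import (
    AncillaryMasks,
    annual_change_classes,
    annual_state,
    annual_state_stack,
    build_transition_map,
    edge_buffer,
    hotspot_grid,
)
from tmfmonitor.simulate import ArchiveModel, simulate_scene
from tmfmonitor.trajectory import Thresholds, classify_grid, classify_series

from .conftest import forest_baseline, make_series

F, D, I = 1, 2, 0
RATES = {
    "degradation": 0.10,
    "deforestation": 0.08,
    "deforestation_after_degradation": 0.05,
    "regrowth_after_deforestation": 0.05,
}


@pytest.fixture(scope="module")
def scene_grid():
    archive = ArchiveModel.dense()
    days, labels, truth = simulate_scene(25, 25, RATES, archive, seed=21)
    grid = classify_grid(days, labels, Thresholds())
    return grid, truth


def _record(obs, th=None):
    return classify_series(make_series(obs), th or Thresholds())


def _defor_record():
    obs = forest_baseline() + [
        (f"{y}-{m:02d}-01", D) for y in range(2000, 2006) for m in (3, 9)
    ]
    return _record(obs)


def _undisturbed_record():
    return _record(forest_baseline() + [("2005-06-01", F)])


class TestTransitionMap:
    def test_no_masks_default_deforested_subclass(self, scene_grid):
        grid, _ = scene_grid
        tmap = build_transition_map(grid)
        defor = tmap.main == int(TransitionClass.DEFORESTED)
        assert defor.any()
        assert (tmap.subclass[defor] == SUBCLASS_OTHER_CONVERSION).all()

    def test_water_and_mangrove_masks(self, scene_grid):
        grid, _ = scene_grid
        shape = grid.shape
        water = np.zeros(shape, dtype=bool)
        water[:, :] = True  # every deforested pixel becomes a dam reservoir
        mangrove = np.ones(shape, dtype=bool)
        tmap = build_transition_map(
            grid, AncillaryMasks(water=water, mangrove=mangrove)
        )
        defor = tmap.main == int(TransitionClass.DEFORESTED)
        undist = tmap.main == int(TransitionClass.UNDISTURBED)
        assert (tmap.subclass[defor] == SUBCLASS_WATER).all()
        assert (tmap.subclass[undist] == SUBCLASS_MANGROVE).all()

    def test_mask_shape_mismatch_rejected(self, scene_grid):
        grid, _ = scene_grid
        with pytest.raises(ValueError):
            build_transition_map(
                grid, AncillaryMasks(water=np.zeros((2, 2), dtype=bool))
            )

    def test_partition(self, scene_grid):
        grid, _ = scene_grid
        tmap = build_transition_map(grid)
        # every qualified pixel has exactly one main class in 1..7
        assert set(np.unique(tmap.main)) <= set(range(0, 8))
        assert (tmap.main > 0).all()  # dense archive: all pixels qualify


class TestAnnualState:
    def test_undisturbed_every_year(self, thresholds):
        rec = _undisturbed_record()
        for year in (1990, 2000, 2019):
            assert annual_state(rec, year, thresholds) == AnnualState.UNDISTURBED

    def test_attribution_to_onset_year(self, thresholds):
        obs = forest_baseline() + [("1997-11-20", D), ("1998-02-10", D)]
        obs += [(f"{y}-06-01", F) for y in range(1999, 2020)]
        rec = _record(obs)
        assert annual_state(rec, 1996, thresholds) == AnnualState.UNDISTURBED
        assert annual_state(rec, 1997, thresholds) == AnnualState.DEGRADED

    def test_deforestation_then_regrowth_timeline(self, thresholds):
        obs = forest_baseline()
        obs += [(f"{y}-{m:02d}-01", D) for y in range(2000, 2004) for m in (3, 9)]
        obs += [(f"{y}-{m:02d}-01", F) for y in range(2008, 2020) for m in (2, 8)]
        rec = _record(obs)
        assert rec.transition_class == TransitionClass.FOREST_REGROWTH
        assert annual_state(rec, 2005, thresholds) == AnnualState.DEFORESTED
        assert annual_state(rec, 2012, thresholds) == AnnualState.REGROWTH

    def test_year_out_of_range(self, thresholds):
        with pytest.raises(ValueError):
            annual_state(_undisturbed_record(), 1980, thresholds)

    def test_annual_reduction_matches_transition_class(self, scene_grid):
        """Replaying the annual states reproduces the end-of-record class."""
        grid, _ = scene_grid
        states = annual_state_stack(grid)
        final = states[2019]
        main = grid.class_raster()
        expected = {
            int(TransitionClass.UNDISTURBED): AnnualState.UNDISTURBED,
            int(TransitionClass.DEGRADED): AnnualState.DEGRADED,
            int(TransitionClass.DEFORESTED): AnnualState.DEFORESTED,
            int(TransitionClass.FOREST_REGROWTH): AnnualState.REGROWTH,
            int(TransitionClass.OTHER_LC): AnnualState.OTHER,
        }
        for cls_code, state in expected.items():
            sel = main == cls_code
            if sel.any():
                assert (final[sel] == int(state)).all()


class TestAnnualChangeClasses:
    def test_short_degradation_without_deforestation(self, thresholds):
        obs = forest_baseline() + [("2002-03-01", D), ("2002-04-30", D)]
        obs += [(f"{y}-06-01", F) for y in range(2003, 2020)]
        rec = _record(obs)
        from tmfmonitor.products import _record_change_class

        changes = dict(_record_change_class(rec, thresholds, None, 0, 0))
        assert changes == {2002: AnnualChangeClass.DEGR_SHORT}

    def test_deforestation_of_degraded(self, thresholds):
        obs = forest_baseline() + [("1995-03-01", D), ("1995-05-01", D)]
        obs += [(f"{y}-06-01", F) for y in range(1996, 2003)]
        obs += [(f"{y}-{m:02d}-01", D) for y in range(2003, 2009) for m in (4, 10)]
        rec = _record(obs)
        from tmfmonitor.products import _record_change_class

        pairs = _record_change_class(rec, thresholds, None, 0, 0)
        assert (1995, AnnualChangeClass.DEGR_BEFORE_DEFOR) in pairs
        assert (2003, AnnualChangeClass.DEFOR_OF_DEGRADED) in pairs

    def test_direct_deforestation_with_regrowth(self, thresholds):
        obs = forest_baseline()
        obs += [(f"{y}-{m:02d}-01", D) for y in range(2000, 2004) for m in (3, 9)]
        obs += [(f"{y}-{m:02d}-01", F) for y in range(2008, 2020) for m in (2, 8)]
        rec = _record(obs)
        from tmfmonitor.products import _record_change_class

        pairs = _record_change_class(rec, thresholds, None, 0, 0)
        assert pairs == [(2000, AnnualChangeClass.DIRECT_DEFOR_REGROWTH)]

    def test_one_class_per_disturbed_pixel_year(self, scene_grid):
        grid, _ = scene_grid
        changes = annual_change_classes(grid)
        for raster in changes.values():
            assert raster.max() <= 10


class TestEdgeBuffer:
    def test_empty_mask(self):
        out = edge_buffer(np.zeros((10, 10), dtype=bool))
        assert not out.any()

    def test_single_pixel_disc_has_49_members(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 10] = True
        out = edge_buffer(mask, distance_m=120, pixel_m=30)
        assert out.sum() == 49
        assert (out & ~mask).sum() == 48

    def test_brute_force_disc_membership(self):
        rng = np.random.default_rng(8)
        mask = rng.random((30, 30)) < 0.05
        out = edge_buffer(mask, 120, 30)
        rr, cc = np.nonzero(mask)
        expected = np.zeros_like(mask)
        for r in range(30):
            for c in range(30):
                if any((r - a) ** 2 + (c - b) ** 2 <= 16 for a, b in zip(rr, cc)):
                    expected[r, c] = True
        assert np.array_equal(out, expected)

    def test_larger_distance_is_superset(self):
        rng = np.random.default_rng(9)
        mask = rng.random((20, 20)) < 0.1
        b120 = edge_buffer(mask, 120, 30)
        b240 = edge_buffer(mask, 240, 30)
        assert (b240 | b120).sum() == b240.sum()


class TestHotspotGrid:
    def _geo_scene(self):
        archive = ArchiveModel.dense()
        # 0.5 x 0.5 degree scene inside one 1-degree cell
        geom = GridGeometry(rows=20, cols=20, x_origin=24.2, y_origin=-1.2,
                            cell_size=0.025, geographic=True)
        days, labels, truth = simulate_scene(
            20, 20, RATES, archive, seed=31, geometry=geom
        )
        grid = classify_grid(days, labels, Thresholds())
        return grid, geom

    def test_conservation_and_single_cell(self):
        grid, geom = self._geo_scene()
        changes = annual_change_classes(grid)
        table = hotspot_grid(changes, geom)
        assert set(zip(table["lat"], table["lon"])) == {(-2, 24)}
        total_ha = table["defor_ha"].sum() + table["degr_ha"].sum()
        disturbed_pixel_years = sum(
            int(((r > 0)).sum()) for r in changes.values()
        )
        assert total_ha == pytest.approx(disturbed_pixel_years * PIXEL_AREA_HA)

    def test_requires_geographic_grid(self):
        with pytest.raises(ValueError):
            hotspot_grid({}, GridGeometry(rows=2, cols=2))

    def test_boundary_pixel_center_rule(self):
        # a pixel whose center is exactly on a cell boundary belongs to the
        # cell that floor(center) selects
        geom = GridGeometry(rows=1, cols=1, x_origin=9.995, y_origin=0.005,
                            cell_size=0.01, geographic=True)
        lon, lat = geom.pixel_centers()
        assert lon[0, 0] == pytest.approx(10.0)
        assert int(np.floor(lon[0, 0])) == 10
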