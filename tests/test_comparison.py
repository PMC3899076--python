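"""Fractional aggregation, difference maps, RMSD and through-origin fits."""

import numpy as np
import pandas as pd
import pytest

from sarforest import (
    AreaTable,
    ForestMask,
    GridTransform,
    aggregate_fraction,
    difference_map,
    fit_through_origin,
    load_national_areas,
    regional_areas,
    rmsd,
)
from sarforest.datasets import MAINLAND_COUNTRIES


def table(values, source="x"):
    return AreaTable(
        table=pd.DataFrame(
            {"region_id": range(len(values)), "region_name": [str(i) for i in range(len(values))],
             "area_1e3km2": values}
        ),
        source=source,
    )


class TestAggregate:
    def test_all_forest_block(self):
        fm = ForestMask(mask=np.ones((30, 30), dtype=int))
        fr = aggregate_fraction(fm, 30)
        assert fr.shape == (1, 1) and fr.fraction[0, 0] == 1.0
        assert fr.cell_size_m == 1500.0

    def test_checkerboard_half(self):
        m = (np.indices((30, 30)).sum(0) % 2).astype(int)
        fr = aggregate_fraction(ForestMask(mask=m), 30)
        assert fr.fraction[0, 0] == 0.5

    def test_matches_block_loop_oracle(self, rng):
        m = (rng.random((90, 90)) < 0.4).astype(int)
        fr = aggregate_fraction(ForestMask(mask=m), 30)
        assert fr.shape == (3, 3)
        for bi in range(3):
            for bj in range(3):
                block = m[bi * 30:(bi + 1) * 30, bj * 30:(bj + 1) * 30]
                assert fr.fraction[bi, bj] == pytest.approx(block.mean())

    def test_conserves_forest_count(self, rng):
        m = (rng.random((120, 120)) < 0.3).astype(int)
        fm = ForestMask(mask=m)
        fr = aggregate_fraction(fm, 30)
        assert (fr.fraction * fr.n_valid).sum() == pytest.approx(m.sum())

    def test_nodata_excluded_from_denominator(self):
        m = np.ones((30, 30), dtype=int)
        valid = np.ones((30, 30), dtype=bool)
        valid[:15] = False
        fr = aggregate_fraction(ForestMask(mask=np.where(valid, m, 0), valid_mask=valid), 30)
        assert fr.fraction[0, 0] == 1.0
        assert fr.n_valid[0, 0] == 450

    def test_factor_too_large(self):
        with pytest.raises(ValueError):
            aggregate_fraction(ForestMask(mask=np.ones((10, 10), dtype=int)), 30)


class TestDifferenceMap:
    def make(self, frac):
        n = np.full(frac.shape, 900, dtype=int)
        from sarforest.comparison import FractionGrid

        return FractionGrid(fraction=frac, n_valid=n)

    def test_identical_grids(self, rng):
        f = rng.random((5, 5))
        diff, hist = difference_map(self.make(f), self.make(f))
        assert np.allclose(diff, 0.0)
        assert hist.attrs["share_within_30"] == 100.0

    def test_saturated_difference(self):
        a = self.make(np.ones((4, 4)))
        b = self.make(np.zeros((4, 4)))
        diff, hist = difference_map(a, b, bins=(-100, 0, 99.5, 100))
        assert np.allclose(diff, 100.0)
        assert hist["count"].iloc[-1] == 16

    def test_histogram_matches_direct_tabulation(self, rng):
        fa, fb = rng.random((8, 8)), rng.random((8, 8))
        diff, hist = difference_map(self.make(fa), self.make(fb))
        vals = (fa - fb) * 100
        for _, row in hist.iterrows():
            want = np.sum((vals >= row.bin_low) & (vals < row.bin_high))
            # allow right-edge inclusion on the final bin, numpy convention
            assert abs(row["count"] - want) <= 1
        assert hist.attrs["share_within_30"] == pytest.approx(
            100 * np.mean(np.abs(vals) <= 30))

    def test_low_valid_cells_excluded(self, rng):
        from sarforest.comparison import FractionGrid

        f = rng.random((4, 4))
        n = np.full((4, 4), 900)
        n[0, 0] = 100  # < 50% of a full 900-pixel cell
        a = FractionGrid(fraction=f, n_valid=n)
        b = self.make(f)
        diff, hist = difference_map(a, b)
        assert np.isnan(diff[0, 0])
        assert hist.attrs["n_cells"] == 15

    def test_geometry_mismatch(self, rng):
        with pytest.raises(ValueError):
            difference_map(self.make(rng.random((3, 3))), self.make(rng.random((4, 4))))


class TestRMSD:
    def test_identical_tables_zero(self):
        t = table([1.0, 2.0, 3.0])
        assert rmsd(t, t) == 0.0

    def test_symmetry_and_positivity(self, rng):
        a = table(rng.uniform(0, 100, 6))
        b = table(rng.uniform(0, 100, 6))
        assert rmsd(a, b) == rmsd(b, a) >= 0

    def test_unmatched_regions_listed(self):
        a = table([1.0, 2.0])
        b = AreaTable(table=pd.DataFrame(
            {"region_id": [0, 5], "region_name": ["0", "5"], "area_1e3km2": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="5"):
            rmsd(a, b)


class TestPublishedAreas:
    """National forest-area tables reproduce the printed RMSD integers."""

    @pytest.mark.parametrize(
        "other, expected", [("fao_fra", 111), ("globcover", 143), ("mcd12q1", 39)]
    )
    def test_all_countries(self, other, expected):
        p = load_national_areas("palsar")
        assert round(rmsd(p, load_national_areas(other))) == expected

    @pytest.mark.parametrize(
        "other, expected", [("fao_fra", 19), ("globcover", 68), ("mcd12q1", 34)]
    )
    def test_mainland(self, other, expected):
        p = load_national_areas("palsar", mainland_only=True)
        o = load_national_areas(other, mainland_only=True)
        assert set(p.table.region_name) == set(MAINLAND_COUNTRIES)
        assert round(rmsd(p, o)) == expected

    def test_indonesia_includes_gap_fill(self):
        p = load_national_areas("palsar")
        indo = p.table.loc[p.table.region_name == "Indonesia", "area_1e3km2"].iloc[0]
        assert indo == 885 + 419


class TestFitThroughOrigin:
    def test_exact_line(self):
        slope, r2 = fit_through_origin([1, 2, 3], [2, 4, 6])
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_closed_form_example(self):
        slope, _ = fit_through_origin([1, 2, 3], [2, 3, 5])
        assert slope == pytest.approx(23 / 14)

    def test_negative_slope(self):
        x = np.array([1.0, 2.0, 4.0])
        slope, r2 = fit_through_origin(x, -x)
        assert slope == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_recovers_any_k(self, rng):
        x = rng.uniform(1, 10, 20)
        for k in (-3.7, 0.001, 42.0):
            slope, r2 = fit_through_origin(x, k * x)
            assert slope == pytest.approx(k, rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_through_origin([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_through_origin([0.0, 0.0], [1.0, 2.0])


class TestRegionalAreas:
    def test_single_region_all_forest(self):
        fm = ForestMask(mask=np.ones((100, 100), dtype=int),
                        transform=GridTransform(pixel_size_m=50))
        t = regional_areas(fm, np.ones((100, 100), dtype=int))
        assert t.table.area_1e3km2.iloc[0] == pytest.approx(0.025)  # 25 km²

    def test_symmetric_halves(self):
        m = np.zeros((10, 10), dtype=int)
        m[:, :5] = np.tile([1, 0], (10, 3))[:, :5]
        m[:, 5:] = m[:, :5]
        regions = np.ones((10, 10), dtype=int)
        regions[:, 5:] = 2
        t = regional_areas(ForestMask(mask=m), regions)
        areas = t.table.set_index("region_id").area_1e3km2
        assert areas[1] == areas[2]

    def test_partition_sums_to_total(self, rng):
        m = (rng.random((40, 40)) < 0.5).astype(int)
        regions = rng.integers(1, 5, size=(40, 40))
        t = regional_areas(ForestMask(mask=m), regions)
        total = m.sum() * 2500 * 1e-6 * 1e-3
        assert t.table.area_1e3km2.sum() == pytest.approx(total)

    def test_empty_region_layer(self):
        with pytest.raises(ValueError):
            regional_areas(ForestMask(mask=np.ones((4, 4), dtype=int)),
                           np.zeros((4, 4), dtype=int))
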