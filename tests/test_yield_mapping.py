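"""Count/trunk joining, IDW interpolation, georeferenced exports."""

import dataclasses

import numpy as np
import pytest

from vinescout import GridSpec, TrunkRecord, idw_interpolate, join_counts
from vinescout.yield_mapping import (
    YieldRaster,
    export_points_csv,
    export_points_geojson,
    export_raster,
    read_points_csv,
    read_points_geojson,
    read_raster,
)


def _trunk(pid, e, n, **kw):
    return TrunkRecord(plant_id=pid, easting=e, northing=n, **kw)


class TestJoinCounts:
    TRUNKS = [
        _trunk("p1", 0.0, 0.0),
        _trunk("p2", 2.5, 0.0),
        _trunk("p3", 5.0, 0.0, replant_flag=True),
    ]

    def test_empty_counts_leave_trunks_unpopulated(self):
        populated, report = join_counts(self.TRUNKS, {}, {})
        assert populated == [] and report.matched == 0

    def test_bijective_join(self):
        populated, report = join_counts(
            self.TRUNKS[:2],
            {"img_a": 7, "img_b": 9},
            {"img_a": "p1", "img_b": "p2"},
        )
        assert report.matched == 2
        assert {p.plant_id: p.count for p in populated} == {"p1": 7, "p2": 9}

    def test_replant_plant_excluded_and_reported(self):
        populated, report = join_counts(
            self.TRUNKS, {"img_c": 4}, {"img_c": "p3"}
        )
        assert populated == []
        assert report.excluded_replants == ["p3"]

    def test_unmatched_image_reported(self):
        _, report = join_counts(self.TRUNKS, {"mystery": 3}, {})
        assert report.unmatched_images == ["mystery"]

    def test_duplicate_links_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            join_counts(self.TRUNKS, {"a": 1, "b": 2}, {"a": "p1", "b": "p1"})


class TestIdwInterpolate:
    def test_single_point_gives_constant_raster(self):
        points = [_trunk("p", 5.0, 5.0, count=13)]
        grid = GridSpec(origin=(0, 0), cell_size=1.0, nx=10, ny=10)
        raster = idw_interpolate(points, grid)
        assert np.allclose(raster.values, 13.0)

    def test_equidistant_cell_averages_two_counts(self):
        points = [_trunk("a", 0.0, 0.5, count=10), _trunk("b", 9.0, 0.5, count=20)]
        grid = GridSpec(origin=(0, 0), cell_size=1.0, nx=9, ny=1)
        raster = idw_interpolate(points, grid, power=2)
        assert raster.values[0, 4] == pytest.approx(15.0, abs=1e-12)

    @pytest.mark.filterwarnings("ignore:interpolation grid")
    def test_three_point_hand_computed_weights(self):
        # cell center (0.5, 0.5); points at distances 1, 2, 3 exactly
        points = [
            _trunk("a", 1.5, 0.5, count=6),  # d = 1
            _trunk("b", 0.5, 2.5, count=12),  # d = 2
            _trunk("c", 3.5, 0.5, count=30),  # d = 3
        ]
        grid = GridSpec(origin=(0, 0), cell_size=1.0, nx=1, ny=1)
        raster = idw_interpolate(points, grid, power=2, neighbors=3)
        w = np.array([1.0, 1 / 4, 1 / 9])
        expected = (w * [6, 12, 30]).sum() / w.sum()
        assert raster.values[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_exact_at_data_points(self):
        points = [_trunk("a", 0.5, 0.5, count=4), _trunk("b", 3.5, 2.5, count=11)]
        grid = GridSpec(origin=(0, 0), cell_size=1.0, nx=4, ny=3)
        raster = idw_interpolate(points, grid)
        assert raster.values[2, 0] == 4.0  # row 2 = southernmost
        assert raster.values[0, 3] == 11.0

    def test_coinciding_points_average(self):
        points = [_trunk("a", 0.5, 0.5, count=4), _trunk("b", 0.5, 0.5, count=8)]
        grid = GridSpec(origin=(0, 0), cell_size=1.0, nx=1, ny=1)
        raster = idw_interpolate(points, grid)
        assert raster.values[0, 0] == 6.0

    def test_bounded_by_neighbor_range(self, rng):
        points = [
            _trunk(f"p{i}", float(e), float(n), count=int(c))
            for i, (e, n, c) in enumerate(
                zip(rng.uniform(0, 30, 15), rng.uniform(0, 20, 15), rng.integers(2, 40, 15))
            )
        ]
        grid = GridSpec(origin=(-2, -2), cell_size=1.0, nx=36, ny=26)
        raster = idw_interpolate(points, grid, neighbors=6)
        counts = [p.count for p in points]
        assert raster.values.min() >= min(counts) - 1e-9
        assert raster.values.max() <= max(counts) + 1e-9

    def test_uniform_counts_give_uniform_raster(self):
        points = [_trunk(f"p{i}", 2.5 * i, 0.0, count=9) for i in range(6)]
        grid = GridSpec(origin=(-1, -3), cell_size=0.5, nx=32, ny=12)
        raster = idw_interpolate(points, grid)
        assert np.allclose(raster.values, 9.0)

    @pytest.mark.filterwarnings("ignore:interpolation grid")
    def test_large_power_approaches_nearest_neighbor(self):
        points = [_trunk("a", 0.0, 0.0, count=10), _trunk("b", 10.0, 0.0, count=20)]
        grid = GridSpec(origin=(2.0, -0.5), cell_size=1.0, nx=1, ny=1)  # center x=2.5
        values = [
            idw_interpolate(points, grid, power=p).values[0, 0] for p in (2, 8, 32)
        ]
        # nearest neighbor is count 10; convergence is monotone from above
        assert values[0] > values[1] > values[2]
        assert values[2] == pytest.approx(10.0, abs=1e-3)

    def test_neighbors_below_one_rejected(self):
        with pytest.raises(ValueError, match="neighbors"):
            idw_interpolate([_trunk("a", 0, 0, count=1)], GridSpec((0, 0), 1, 1, 1), neighbors=0)

    def test_mixed_crs_rejected(self):
        points = [
            _trunk("a", 0, 0, count=1),
            dataclasses.replace(_trunk("b", 1, 1, count=2), crs="EPSG:4326"),
        ]
        with pytest.raises(ValueError, match="CRS"):
            idw_interpolate(points, GridSpec((0, 0), 1, 2, 2))

    def test_grid_not_covering_points_warns(self):
        points = [_trunk("a", 0, 0, count=1), _trunk("b", 50, 50, count=2)]
        grid = GridSpec(origin=(0, 0), cell_size=1.0, nx=5, ny=5)
        with pytest.warns(UserWarning, match="cover"):
            idw_interpolate(points, grid)


class TestExports:
    def _raster(self):
        values = np.array([[1.5, 2.25], [3.125, -9999.0]])
        return YieldRaster(origin=(517000.0, 4644800.0), cell_size=1.0, values=values)

    def test_ascii_grid_round_trip(self, tmp_path):
        raster = self._raster()
        path = tmp_path / "yield.asc"
        export_raster(raster, path)
        back = read_raster(path)
        assert np.allclose(back.values, raster.values, atol=1e-6)
        assert back.origin == raster.origin
        assert back.cell_size == raster.cell_size

    def test_nodata_serialized_as_sentinel(self, tmp_path):
        path = tmp_path / "yield.asc"
        export_raster(self._raster(), path)
        text = path.read_text()
        assert "NODATA_value -9999" in text
        assert "-9999.000000" in text.splitlines()[-1]

    def test_geojson_round_trip_42_records(self, tmp_path, rng):
        records = [
            _trunk(
                f"plant_{i:04d}",
                517000.0 + 2.5 * (i % 14),
                4644800.0 + 3.0 * (i // 14),
                count=int(c),
                esca_flag=bool(i % 7 == 0),
            )
            for i, c in enumerate(rng.integers(0, 30, size=42))
        ]
        path = tmp_path / "points.geojson"
        export_points_geojson(records, path)
        back = read_points_geojson(path)
        assert back == records

    def test_csv_round_trip(self, tmp_path):
        records = [_trunk("p1", 1.0, 2.0, count=5), _trunk("p2", 3.0, 4.0, count=None)]
        path = tmp_path / "points.csv"
        export_points_csv(records, path)
        back = read_points_csv(path)
        assert back == records
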