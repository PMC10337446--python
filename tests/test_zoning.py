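"""Partition generators, zonal means, normalization, and terciles."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box
from shapely import minimum_rotated_rectangle

from geofence_kde.core_io import PartitionKind, Zone, ZonePartition
from geofence_kde.kde import DensityRaster
from geofence_kde.zoning import (
    MISSING,
    Tercile,
    ZoneRiskTable,
    assign_points,
    classify_terciles,
    make_fishnet,
    make_pseudo_blocks,
    normalize_minmax,
    zonal_mean,
)


def minor_axis_width(polygon) -> float:
    rect = minimum_rotated_rectangle(polygon)
    xs, ys = rect.exterior.coords.xy
    e1 = np.hypot(xs[1] - xs[0], ys[1] - ys[0])
    e2 = np.hypot(xs[2] - xs[1], ys[2] - ys[1])
    return min(e1, e2)


class TestFishnet:
    def test_exact_tiling(self):
        part = make_fishnet((0, 0, 1000, 1000), 500)
        assert len(part) == 4
        assert sum(z.polygon.area for z in part) == pytest.approx(1_000_000)
        assert part.partition_kind is PartitionKind.fishnet_500

    def test_ceiling_cover_of_ragged_extent(self):
        part = make_fishnet((0, 0, 1200, 700), 500)
        assert len(part) == 6  # 3 cols x 2 rows covering 1500 x 1000
        xmin, ymin, xmax, ymax = part.bounds
        assert (xmax - xmin, ymax - ymin) == (1500, 1000)

    def test_pairwise_disjoint_union_area(self):
        part = make_fishnet((13, 7, 2600, 1800), 1000)
        total = sum(z.polygon.area for z in part)
        assert total == pytest.approx(len(part) * 1000**2)
        from shapely.ops import unary_union

        assert unary_union([z.polygon for z in part]).area == pytest.approx(total)


class TestPseudoBlocks:
    def test_tessellation_conserves_area(self):
        part = make_pseudo_blocks((0, 0, 4000, 4000), 4, rng_seed=1, sliver_fraction=0)
        assert len(part) == 4
        assert sum(z.polygon.area for z in part) == pytest.approx(4000**2)

    def test_deterministic_given_seed(self):
        a = make_pseudo_blocks((0, 0, 4000, 4000), 15, rng_seed=9, sliver_fraction=0.2)
        b = make_pseudo_blocks((0, 0, 4000, 4000), 15, rng_seed=9, sliver_fraction=0.2)
        assert [z.zone_id for z in a] == [z.zone_id for z in b]
        assert all(x.polygon.equals(y.polygon) for x, y in zip(a, b))

    def test_sliver_fraction_produces_narrow_zone(self):
        part = make_pseudo_blocks((0, 0, 8000, 8000), 20, rng_seed=5, sliver_fraction=0.2)
        widths = [minor_axis_width(z.polygon) for z in part]
        assert min(widths) < 150
        # splitting conserves area
        assert sum(z.polygon.area for z in part) == pytest.approx(8000**2)


class TestZonalMean:
    def test_constant_raster_gives_constant_means(self):
        raster = DensityRaster(0, 0, 100, np.full((10, 10), 3.5))
        part = make_fishnet((0, 0, 1000, 1000), 500)
        means = zonal_mean(raster, part)
        assert all(m == pytest.approx(3.5) for m in means.values())

    def test_left_column_mean(self):
        # 2x2 raster, centers at (50,50),(150,50),(50,150),(150,150)
        raster = DensityRaster(0, 0, 100, np.array([[1.0, 2.0], [3.0, 4.0]]))
        part = ZonePartition(
            PartitionKind.custom,
            [Zone("left", box(0, 0, 100, 200)), Zone("right", box(100, 0, 200, 200))],
        )
        means = zonal_mean(raster, part)
        assert means["left"] == pytest.approx(2.0)  # mean of {1, 3}
        assert means["right"] == pytest.approx(3.0)

    def test_shared_edge_center_goes_up_and_right(self):
        # centers on x = 100 belong to the right zone only
        raster = DensityRaster(50, 0, 100, np.array([[1.0, 5.0]]))
        part = ZonePartition(
            PartitionKind.custom,
            [Zone("l", box(0, 0, 100, 100)), Zone("r", box(100, 0, 250, 100))],
        )
        means = zonal_mean(raster, part)
        assert means["l"] is MISSING  # its only candidate center sits on the edge
        assert means["r"] == pytest.approx(3.0)

    def test_sliver_between_centers_is_missing(self, caplog):
        raster = DensityRaster(0, 0, 100, np.ones((5, 5)))
        part = ZonePartition(
            PartitionKind.custom,
            [
                Zone("wide_l", box(0, 0, 160, 500)),
                Zone("sliver", box(160, 0, 240, 500)),  # centers are at x=150, 250
                Zone("wide_r", box(240, 0, 500, 500)),
            ],
        )
        import logging

        with caplog.at_level(logging.INFO, logger="geofence_kde"):
            means = zonal_mean(raster, part)
        assert means["sliver"] is MISSING
        assert means["wide_l"] == 1.0 and means["wide_r"] == 1.0
        assert "did not rasterize" in caplog.text

    def test_no_missing_for_large_convex_zones(self):
        raster = DensityRaster(0, 0, 150, np.ones((20, 20)))
        part = make_pseudo_blocks((0, 0, 3000, 3000), 5, rng_seed=2)
        big_and_convex = all(
            z.polygon.area >= (2 * 150) ** 2
            and z.polygon.convex_hull.area <= z.polygon.area * 1.000001
            for z in part
        )
        if big_and_convex:
            assert sum(1 for m in zonal_mean(raster, part).values() if m is MISSING) == 0


class TestNormalize:
    def test_affine_normalization(self):
        norms = normalize_minmax({"a": 0.0, "b": 5.0, "c": 10.0})
        assert norms == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_degenerate_all_equal_gives_one(self):
        assert normalize_minmax({"a": 2.0, "b": 2.0}) == {"a": 1.0, "b": 1.0}

    def test_missing_propagates_and_all_missing_errors(self):
        norms = normalize_minmax({"a": MISSING, "b": 1.0, "c": 3.0})
        assert norms["a"] is MISSING and norms["c"] == 1.0
        with pytest.raises(ValueError):
            normalize_minmax({"a": MISSING})

    def test_rounding_excludes_near_one_at_full_threshold(self):
        # raw max-but-one norm 0.9999984 rounds to 0.999998 < 1.0
        means = {"low": 0.0, "near": 0.9999984, "top": 1.0}
        norms = normalize_minmax(means, decimals=6)
        assert norms["near"] == 0.999998
        table = classify_terciles(norms, threshold=1.0)
        assert table.rows["near"].tercile is Tercile.not_retained
        assert table.retained() == ["top"]

    def test_scale_invariance(self):
        base = {"a": 0.1, "b": 0.4, "c": 0.9, "d": MISSING}
        scaled = {k: (v * 37.5 if v is not MISSING else v) for k, v in base.items()}
        assert normalize_minmax(base) == normalize_minmax(scaled)


def oracle_tercile_sizes(n):
    """Equal-count split with remainders to the lower groups."""
    base, rem = divmod(n, 3)
    return [base + (1 if i < rem else 0) for i in range(3)]


class TestTerciles:
    def test_six_values_split_2_2_2(self):
        norms = {f"z{i}": v for i, v in enumerate([0.3, 0.4, 0.5, 0.6, 0.8, 1.0])}
        table = classify_terciles(norms, threshold=0.3)
        by = {table.rows[f"z{i}"].tercile for i in range(2)}
        assert by == {Tercile.low}
        assert table.rows["z2"].tercile is Tercile.medium
        assert table.rows["z3"].tercile is Tercile.medium
        assert table.rows["z4"].tercile is Tercile.high
        assert table.rows["z5"].tercile is Tercile.high

    def test_zero_retained_is_fine(self):
        table = classify_terciles({"a": 0.1, "b": MISSING}, threshold=0.5)
        assert table.retained() == []
        assert table.rows["a"].tercile is Tercile.not_retained
        assert table.rows["b"].tercile is Tercile.missing

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6, 7, 8, 11])
    def test_group_sizes_match_remainder_rule(self, n):
        norms = {f"z{i:02d}": 0.3 + 0.05 * i for i in range(n)}
        table = classify_terciles(norms, threshold=0.0)
        sizes = [
            sum(1 for r in table.rows.values() if r.tercile is t)
            for t in (Tercile.low, Tercile.medium, Tercile.high)
        ]
        assert sizes == oracle_tercile_sizes(n)

    def test_boundary_ties_drop_to_lower_tercile(self):
        norms = {"a": 0.4, "b": 0.5, "c": 0.5, "d": 0.7, "e": 0.8, "f": 0.9}
        table = classify_terciles(norms, threshold=0.3)
        # rank split is 2/2/2 but the 0.5 tie straddles low|medium
        assert table.rows["b"].tercile is Tercile.low
        assert table.rows["c"].tercile is Tercile.low
        assert table.rows["d"].tercile is Tercile.medium

    def test_retention_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        norms = {f"z{i}": round(float(v), 6) for i, v in enumerate(rng.uniform(0, 1, 30))}
        retained = [
            set(classify_terciles(norms, t).retained()) for t in (0.2, 0.5, 0.8)
        ]
        assert retained[2] <= retained[1] <= retained[0]

    def test_inclusive_threshold(self):
        table = classify_terciles({"edge": 0.3, "below": 0.29}, threshold=0.3)
        assert table.rows["edge"].tercile is not Tercile.not_retained
        assert table.rows["below"].tercile is Tercile.not_retained


def test_risk_table_csv_round_trip(tmp_path):
    table = classify_terciles(
        {"a": 0.9, "b": 0.5, "c": MISSING, "d": 0.1},
        threshold=0.3,
        means={"a": 3.0, "b": 1.5, "c": MISSING, "d": 0.2},
    )
    path = tmp_path / "risk.csv"
    table.to_csv(path)
    back = ZoneRiskTable.from_csv(path)
    assert back.rows == table.rows
    assert back.n_missing == 1


def test_assign_points_unique_zone_per_point():
    part = make_fishnet((0, 0, 1000, 1000), 500)
    # interior, shared-edge, shared-corner, outside
    labels = assign_points(part, [250, 500, 500, 1500], [250, 250, 500, 1500])
    assert labels[0] == "r0_c0"
    assert labels[1] == "r0_c1"  # edge point goes right
    assert labels[2] == "r1_c1"  # corner point goes up and right
    assert labels[3] is None
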