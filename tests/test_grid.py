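import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon, box

from hfmap.errors import GeometryError, GridMismatchError, HFError
from hfmap.grid import (
    FeatureSet,
    GridSpec,
    RasterLayer,
    connected_clusters,
    euclidean_distance,
    mask_water,
    rasterize,
    resample,
)
from hfmap.io import read_ascii_grid, read_geojson, write_ascii_grid, write_geojson

from conftest import make_grid


class TestRasterize:
    def test_axis_aligned_square_burns_its_pixels(self):
        grid = make_grid(5, 5)
        fs = FeatureSet("polygon", [(box(30, 30, 120, 120), {})], grid.crs_id)
        out = rasterize(fs, grid, 10.0)
        assert np.count_nonzero(out.values == 10.0) == 9
        assert out.values.sum() == 90.0

    def test_empty_featureset_gives_zero_raster(self):
        grid = make_grid(4, 4)
        out = rasterize(FeatureSet("polygon", [], grid.crs_id), grid, 10.0)
        assert not out.values.any()

    def test_overlap_resolved_by_pixelwise_max(self):
        grid = make_grid(6, 6)
        a = box(0, 0, 120, 180)
        b = box(60, 0, 180, 180)
        fs = FeatureSet("polygon", [(a, {"s": 5.0}), (b, {"s": 7.0})], grid.crs_id)
        out = rasterize(fs, grid, "s")
        # oracle: rasterize each alone, combine pixel by pixel
        ra = rasterize(FeatureSet("polygon", [(a, {})], grid.crs_id), grid, 5.0)
        rb = rasterize(FeatureSet("polygon", [(b, {})], grid.crs_id), grid, 7.0)
        np.testing.assert_array_equal(out.values, np.maximum(ra.values, rb.values))
        assert (out.values[:, 2:4] == 7.0).all()  # overlap column range

    def test_burn_by_max_is_order_invariant(self):
        grid = make_grid(8, 8)
        rng = np.random.default_rng(0)
        feats = [
            (box(*sorted(rng.uniform(0, 240, 2)), *sorted(rng.uniform(0, 240, 2))),
             {"s": float(rng.uniform(1, 10))})
            for _ in range(6)
        ]
        fwd = rasterize(FeatureSet("polygon", feats, grid.crs_id), grid, "s")
        rev = rasterize(FeatureSet("polygon", feats[::-1], grid.crs_id), grid, "s")
        np.testing.assert_array_equal(fwd.values, rev.values)

    def test_line_burns_every_touched_pixel(self):
        grid = make_grid(5, 5)
        # diagonal across the grid touches at least one pixel per row and column
        fs = FeatureSet("line", [(LineString([(1, 1), (149, 149)]), {})], grid.crs_id)
        out = rasterize(fs, grid, 3.0)
        assert (out.values.max(axis=0) == 3.0).all()
        assert (out.values.max(axis=1) == 3.0).all()

    def test_horizontal_line_touches_exact_row(self):
        grid = make_grid(4, 4)
        fs = FeatureSet("line", [(LineString([(5, 45), (115, 45)]), {})], grid.crs_id)
        out = rasterize(fs, grid, 1.0)
        assert np.count_nonzero(out.values) == 4
        assert (out.values[2, :] == 1.0).all()  # y=45 lies in row 2

    def test_point_burns_containing_pixel(self):
        grid = make_grid(3, 3)
        fs = FeatureSet("point", [(Point(45, 75), {})], grid.crs_id)
        out = rasterize(fs, grid, 9.0)
        assert out.values[0, 1] == 9.0
        assert np.count_nonzero(out.values) == 1

    def test_crs_mismatch_rejected(self):
        grid = make_grid(3, 3)
        fs = FeatureSet("point", [(Point(45, 75), {})], "EPSG:32717")
        with pytest.raises(GridMismatchError):
            rasterize(fs, grid, 1.0)

    def test_invalid_geometry_rejected_with_index(self):
        bowtie = Polygon([(0, 0), (60, 60), (60, 0), (0, 60)])
        with pytest.raises(GeometryError, match="feature 0"):
            FeatureSet("polygon", [(bowtie, {})])

    def test_missing_burn_attribute_rejected(self):
        grid = make_grid(3, 3)
        fs = FeatureSet("polygon", [(box(0, 0, 90, 90), {})], grid.crs_id)
        with pytest.raises(GeometryError, match="feature 0"):
            rasterize(fs, grid, "score")


class TestResample:
    def test_constant_field_exact_for_both_kinds(self):
        src = make_grid(8, 8, 30)
        tgt = make_grid(4, 4, 60)
        cont = RasterLayer.full(src, 3.25)
        cat = RasterLayer.full(src, 4, "categorical")
        assert (resample(cont, tgt).values == 3.25).all()
        assert (resample(cat, tgt).values == 4).all()

    def test_categorical_mode_of_2x2_block(self):
        src = make_grid(2, 2, 30)
        tgt = make_grid(1, 1, 60)
        cat = RasterLayer(src, np.array([[1, 1], [1, 2]]), "categorical")
        assert resample(cat, tgt).values[0, 0] == 1

    def test_bilinear_identity_at_source_centers(self):
        src = make_grid(6, 6, 30)
        ramp = RasterLayer(src, np.arange(36, dtype=float).reshape(6, 6))
        out = resample(ramp, src)
        np.testing.assert_allclose(out.values, ramp.values)

    def test_categorical_never_invents_codes(self):
        rng = np.random.default_rng(3)
        src = make_grid(12, 12, 30)
        codes = rng.choice([2, 5, 9], size=(12, 12))
        for tgt in (make_grid(5, 5, 72), make_grid(24, 24, 15)):
            out = resample(RasterLayer(src, codes, "categorical"), tgt)
            assert set(np.unique(out.values)) <= {2, 5, 9}

    def test_unknown_kind_rejected(self):
        src = make_grid(2, 2)
        layer = RasterLayer.zeros(src)
        layer.kind = "fuzzy"
        with pytest.raises(HFError):
            resample(layer, src)


class TestEuclideanDistance:
    def test_on_and_near_pixels(self):
        grid = make_grid(1, 5)
        mask = RasterLayer(grid, np.array([[1, 0, 0, 0, 0]]), "categorical")
        d = euclidean_distance(mask)
        assert d.values[0, 0] == 0.0
        assert d.values[0, 3] == 90.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        grid = make_grid(20, 30)
        mask_vals = (rng.random((20, 30)) < 0.05).astype(int)
        mask_vals[7, 13] = 1  # guarantee an on-pixel
        d = euclidean_distance(RasterLayer(grid, mask_vals, "categorical"))
        rows, cols = np.nonzero(mask_vals)
        rr, cc = np.meshgrid(np.arange(20), np.arange(30), indexing="ij")
        brute = np.full((20, 30), np.inf)
        for r, c in zip(rows, cols):
            brute = np.minimum(brute, np.hypot(rr - r, cc - c) * 30.0)
        np.testing.assert_allclose(d.values, brute)

    def test_all_zero_mask_rejected(self):
        grid = make_grid(3, 3)
        with pytest.raises(HFError):
            euclidean_distance(RasterLayer.zeros(grid, "categorical"))


def _flood_fill_sizes(mask: np.ndarray, connectivity: int) -> list[int]:
    seen = np.zeros_like(mask, dtype=bool)
    offsets = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    sizes = []
    for r0, c0 in np.argwhere(mask):
        if seen[r0, c0]:
            continue
        stack, size = [(r0, c0)], 0
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            size += 1
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                        and mask[nr, nc] and not seen[nr, nc]):
                    seen[nr, nc] = True
                    stack.append((nr, nc))
        sizes.append(size)
    return sorted(sizes)


class TestConnectedClusters:
    def test_single_isolated_pixel(self):
        grid = make_grid(3, 3)
        vals = np.zeros((3, 3), int)
        vals[1, 1] = 1
        _, sizes = connected_clusters(RasterLayer(grid, vals, "categorical"))
        assert sizes.tolist() == [1]

    def test_diagonal_pixels_joined_under_8_connectivity(self):
        grid = make_grid(3, 3)
        vals = np.zeros((3, 3), int)
        vals[0, 0] = vals[1, 1] = 1
        mask = RasterLayer(grid, vals, "categorical")
        _, sizes8 = connected_clusters(mask, 8)
        _, sizes4 = connected_clusters(mask, 4)
        assert sizes8.tolist() == [2]
        assert sorted(sizes4.tolist()) == [1, 1]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_sizes_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(5)
        mask = rng.random((25, 25)) < 0.35
        grid = make_grid(25, 25)
        _, sizes = connected_clusters(
            RasterLayer(grid, mask.astype(int), "categorical"), connectivity
        )
        assert sorted(sizes.tolist()) == _flood_fill_sizes(mask, connectivity)


class TestMaskWater:
    def test_all_water_gives_all_nodata(self):
        grid = make_grid(4, 4)
        raster = RasterLayer.full(grid, 2.0)
        water = RasterLayer.full(grid, 1, "categorical")
        assert (mask_water(raster, water).values == raster.nodata).all()

    def test_no_water_is_identity(self):
        grid = make_grid(4, 4)
        raster = RasterLayer.full(grid, 2.0)
        out = mask_water(raster, RasterLayer.zeros(grid, "categorical"))
        np.testing.assert_array_equal(out.values, raster.values)

    def test_checkerboard_masks_exactly_half(self):
        grid = make_grid(6, 6)
        raster = RasterLayer.full(grid, 1.0)
        checker = (np.indices((6, 6)).sum(axis=0) % 2).astype(int)
        out = mask_water(raster, RasterLayer(grid, checker, "categorical"))
        assert np.count_nonzero(out.values == raster.nodata) == 18

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            mask_water(
                RasterLayer.zeros(make_grid(4, 4)),
                RasterLayer.zeros(make_grid(5, 5), "categorical"),
            )


class TestIO:
    def test_ascii_grid_roundtrip(self, tmp_path):
        grid = make_grid(5, 7)
        layer = RasterLayer(grid, np.random.default_rng(1).random((5, 7)))
        path = tmp_path / "layer.asc"
        write_ascii_grid(layer, path)
        back = read_ascii_grid(path)
        assert back.grid == grid
        np.testing.assert_allclose(back.values, layer.values, rtol=1e-6)

    def test_geojson_roundtrip(self, tmp_path):
        fs = FeatureSet(
            "line",
            [(LineString([(0, 0), (100, 50)]), {"class": 2})],
            "EPSG:32718",
        )
        path = tmp_path / "roads.geojson"
        write_geojson(fs, path)
        back = read_geojson(path)
        assert back.geometry_kind == "line"
        assert back.crs_id == "EPSG:32718"
        assert back.features[0][1] == {"class": 2}
        assert back.features[0][0].equals(fs.features[0][0])
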