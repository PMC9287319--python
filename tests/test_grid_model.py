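import numpy as np
import pytest
import tifffile

from irrimap import (
    Grid,
    GridError,
    GridTransform,
    align_nearest,
    apply_mask,
    pixel_area_ha,
    read_grid,
    write_grid,
)


@pytest.fixture
def transform():
    return GridTransform(100.0, 200.0, 500.0, -500.0)


class TestRoundTripIO:
    def test_float_grid_with_nodata(self, tmp_path, transform):
        values = np.array([[1.5, -9999.0], [2.25, 3.75]])
        grid = Grid(values, transform=transform, crs_tag="EPSG:4326", nodata=-9999.0)
        path = tmp_path / "gi.tif"
        write_grid(grid, path)
        back = read_grid(path)
        np.testing.assert_array_equal(back.values, values)
        assert back.transform == transform  # full precision
        assert back.crs_tag == "EPSG:4326"
        assert back.nodata == -9999.0
        assert back.valid_mask().tolist() == [[True, False], [True, True]]

    def test_binary_map_roundtrip_uint8_no_nodata(self, tmp_path, transform):
        grid = Grid(np.array([[1, 0], [0, 1]], dtype=np.uint8), transform=transform)
        path = tmp_path / "irr.tif"
        write_grid(grid, path)
        back = read_grid(path, "binary")
        assert back.values.dtype == np.uint8
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.nodata is None

    def test_integer_labels_roundtrip(self, tmp_path, transform):
        grid = Grid(np.arange(6, dtype=np.int32).reshape(2, 3), transform=transform)
        path = tmp_path / "regions.tif"
        write_grid(grid, path)
        back = read_grid(path, "labels")
        np.testing.assert_array_equal(back.values, grid.values)


class TestReadValidation:
    def test_binary_rejects_value_two(self, tmp_path, transform):
        write_grid(Grid(np.array([[2, 0], [1, 1]], dtype=np.uint8), transform=transform),
                   tmp_path / "bad.tif")
        with pytest.raises(GridError, match="outside"):
            read_grid(tmp_path / "bad.tif", "binary")

    def test_missing_file(self, tmp_path):
        with pytest.raises(GridError, match="no such raster"):
            read_grid(tmp_path / "absent.tif")

    def test_multi_page_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "multi.tif", np.zeros((3, 4, 4), dtype=np.uint8))
        with pytest.raises(GridError, match="single"):
            read_grid(tmp_path / "multi.tif")

    def test_labels_must_be_integer(self, tmp_path, transform):
        write_grid(Grid(np.ones((2, 2)) * 1.5, transform=transform), tmp_path / "f.tif")
        with pytest.raises(GridError, match="integer"):
            read_grid(tmp_path / "f.tif", "labels")


class TestApplyMask:
    def test_all_true_identity(self, transform):
        grid = Grid(np.random.default_rng(0).random((4, 4)), transform=transform)
        mask = Grid(np.ones((4, 4), dtype=bool), transform=transform)
        np.testing.assert_array_equal(apply_mask(grid, mask).values, grid.values)

    def test_all_false_zeroes_binary(self, transform):
        grid = Grid(np.ones((3, 3), dtype=np.uint8), transform=transform)
        mask = Grid(np.zeros((3, 3), dtype=bool), transform=transform)
        assert apply_mask(grid, mask).values.sum() == 0

    def test_mixed_mask_changes_exactly_masked_cells(self, transform):
        rng = np.random.default_rng(1)
        grid = Grid(rng.random((5, 5)), transform=transform, nodata=-1.0)
        mask = Grid(rng.random((5, 5)) > 0.5, transform=transform)
        out = apply_mask(grid, mask)
        keep = mask.values.astype(bool)
        np.testing.assert_array_equal(out.values[keep], grid.values[keep])
        assert (out.values[~keep] == -1.0).all()

    def test_idempotent(self, transform):
        rng = np.random.default_rng(2)
        grid = Grid(rng.random((5, 5)), transform=transform, nodata=-1.0)
        mask = Grid(rng.random((5, 5)) > 0.5, transform=transform)
        once = apply_mask(grid, mask)
        twice = apply_mask(once, mask)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_lattice_mismatch(self, transform):
        grid = Grid(np.ones((2, 2)), transform=transform)
        mask = Grid(np.ones((3, 3), dtype=bool), transform=transform)
        with pytest.raises(GridError):
            apply_mask(grid, mask)


class TestAlignNearest:
    def test_identity_on_same_lattice(self, transform):
        src = Grid(np.arange(16.0).reshape(4, 4), transform=transform)
        out = align_nearest(src, src)
        np.testing.assert_array_equal(out.values, src.values)

    def test_upsample_replicates_blocks(self):
        src = Grid(np.array([[1.0, 2.0], [3.0, 4.0]]), transform=GridTransform(0, 0, 2, -2))
        template = Grid(np.zeros((4, 4)), transform=GridTransform(0, 0, 1, -1))
        out = align_nearest(src, template)
        expected = np.repeat(np.repeat(src.values, 2, axis=0), 2, axis=1)
        np.testing.assert_array_equal(out.values, expected)

    def test_downsample_matches_brute_force_nearest_center(self):
        rng = np.random.default_rng(3)
        src = Grid(rng.integers(0, 2, (4, 4)).astype(np.uint8),
                   transform=GridTransform(0, 0, 1, -1))
        template = Grid(np.zeros((2, 2)), transform=GridTransform(0, 0, 2, -2))
        out = align_nearest(src, template)
        # oracle: per output cell, scan all source centers for the nearest;
        # equidistant ties resolve to the containing cell (larger index)
        for r in range(2):
            for c in range(2):
                tx, ty = template.transform.cell_center(r, c)
                best = min(
                    ((sr, sc) for sr in range(4) for sc in range(4)),
                    key=lambda rc: (
                        (src.transform.cell_center(*rc)[0] - tx) ** 2
                        + (src.transform.cell_center(*rc)[1] - ty) ** 2,
                        -rc[0],
                        -rc[1],
                    ),
                )
                assert out.values[r, c] == src.values[best]

    def test_never_invents_values(self):
        rng = np.random.default_rng(4)
        src = Grid(rng.choice([3.0, 7.0, 11.0], size=(5, 7)),
                   transform=GridTransform(0, 0, 1.5, -1.5))
        template = Grid(np.zeros((6, 6)), transform=GridTransform(0.3, -0.2, 1.0, -1.0))
        out = align_nearest(src, template)
        vals = out.values[~np.isnan(out.values)]
        assert np.isin(vals, [3.0, 7.0, 11.0]).all()

    def test_crs_mismatch_refused(self, transform):
        a = Grid(np.ones((2, 2)), transform=transform, crs_tag="EPSG:4326")
        b = Grid(np.ones((2, 2)), transform=transform, crs_tag="EPSG:32650")
        with pytest.raises(GridError, match="CRS"):
            align_nearest(a, b)

    def test_disjoint_extents_refused(self):
        a = Grid(np.ones((2, 2)), transform=GridTransform(0, 0, 1, -1))
        b = Grid(np.ones((2, 2)), transform=GridTransform(1000, -1000, 1, -1))
        with pytest.raises(GridError, match="disjoint"):
            align_nearest(a, b)


def test_pixel_area_default_500m_is_25ha():
    assert pixel_area_ha(GridTransform(0, 0, 500.0, -500.0)) == pytest.approx(25.0)


def test_cell_size_must_be_positive():
    with pytest.raises(GridError):
        Grid(np.ones((2, 2)), transform=GridTransform(0, 0, 0.0, -1.0))
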