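import numpy as np
import pytest

from parasdm.raster import (
    AlignmentError,
    Grid,
    GridFormatError,
    RasterStack,
    ensemble_mean,
    intersect_mask,
    read_ascii_grid,
    write_ascii_grid,
)


def _write(tmp_path, text, name="g.asc"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadAsciiGrid:
    def test_two_by_two(self, tmp_path):
        p = _write(
            tmp_path,
            "ncols 2\nnrows 2\nxllcorner 10\nyllcorner 40\ncellsize 0.5\n"
            "NODATA_value -9999\n1 2\n3 4\n",
        )
        g = read_ascii_grid(p)
        assert g.values[0, 0] == 1.0   # NW cell
        assert g.values[1, 1] == 4.0   # SE cell
        assert g.cellsize == 0.5

    def test_nodata_cell_flagged(self, tmp_path):
        p = _write(
            tmp_path,
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n-9999 5\n",
        )
        g = read_ascii_grid(p)
        assert np.isnan(g.values[0, 0])
        assert g.values[0, 1] == 5.0
        assert g.valid.tolist() == [[False, True]]

    def test_center_dialect_converted_to_corner(self, tmp_path):
        p = _write(
            tmp_path,
            "ncols 1\nnrows 1\nxllcenter 10\nyllcenter 40\ncellsize 2\n"
            "NODATA_value -9999\n7\n",
        )
        g = read_ascii_grid(p)
        assert g.xll == 9.0
        assert g.yll == 39.0

    def test_malformed_header_names_line(self, tmp_path):
        p = _write(tmp_path, "ncols 2 extra\nnrows 1\n")
        with pytest.raises(GridFormatError, match="line 1"):
            read_ascii_grid(p)

    def test_non_numeric_header(self, tmp_path):
        p = _write(tmp_path, "ncols two\nnrows 1\n")
        with pytest.raises(GridFormatError):
            read_ascii_grid(p)

    def test_truncated_values(self, tmp_path):
        p = _write(
            tmp_path,
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 2 3\n",
        )
        with pytest.raises(GridFormatError, match="expected 4 values, found 3"):
            read_ascii_grid(p)


class TestWriteAsciiGrid:
    def test_round_trip_preserves_values(self, tmp_path, rng):
        vals = rng.uniform(-100, 100, size=(10, 10))
        g = Grid(nrows=10, ncols=10, xll=-3.25, yll=17.5, cellsize=0.125,
                 values=vals)
        p = tmp_path / "rt.asc"
        write_ascii_grid(g, p, precision=17)
        g2 = read_ascii_grid(p)
        np.testing.assert_allclose(g2.values, vals)
        assert g2.geometry == g.geometry

    def test_nodata_serialized_as_sentinel(self, tmp_path):
        vals = np.array([[np.nan, 2.0]])
        g = Grid(nrows=1, ncols=2, xll=0, yll=0, cellsize=1, nodata=-1.0,
                 values=vals)
        p = tmp_path / "nd.asc"
        write_ascii_grid(g, p)
        assert "-1.0" in p.read_text().splitlines()[5]
        g2 = read_ascii_grid(p)
        assert np.isnan(g2.values[0, 0])

    def test_empty_extent_rejected(self):
        with pytest.raises(ValueError):
            Grid(nrows=0, ncols=2, xll=0, yll=0, cellsize=1)


class TestGridGeometry:
    def test_half_open_cell_rule(self, tiny_grid):
        g = tiny_grid
        # lower-left corner of the NW cell belongs to it
        assert g.cell_of(10.0, 40.5) == (0, 0)
        # points just inside the other corners of that cell stay in it
        eps = 1e-9
        assert g.cell_of(10.5 - eps, 40.5) == (0, 0)
        assert g.cell_of(10.0, 41.0 - eps) == (0, 0)
        assert g.cell_of(10.5 - eps, 41.0 - eps) == (0, 0)
        # shared edges belong to the next cell east/north
        assert g.cell_of(10.5, 40.5) == (0, 1)
        assert g.cell_of(10.0, 40.0) == (1, 0)

    def test_outside_extent_raises(self, tiny_grid):
        with pytest.raises(ValueError, match="outside"):
            tiny_grid.cell_of(11.0, 40.5)   # right edge is exclusive
        with pytest.raises(ValueError, match="outside"):
            tiny_grid.cell_of(9.99, 40.5)


def _stack(vals, **kw):
    g = Grid(nrows=vals.shape[0], ncols=vals.shape[1], xll=0, yll=0,
             cellsize=1, values=vals, **kw)
    return RasterStack({"Bio1": g})


class TestEnsembleMean:
    def test_equal_weights(self):
        members = [_stack(np.full((2, 2), v)) for v in (10.0, 20.0, 30.0)]
        out = ensemble_mean(members)
        np.testing.assert_allclose(out["Bio1"].values, 20.0)

    def test_explicit_weights(self):
        members = [_stack(np.full((1, 1), v)) for v in (4.0, 8.0, 16.0)]
        out = ensemble_mean(members, weights=(0.5, 0.25, 0.25))
        assert out["Bio1"].values[0, 0] == 8.0

    def test_nodata_propagates(self):
        a = _stack(np.array([[1.0, np.nan]]))
        b = _stack(np.array([[3.0, 5.0]]))
        out = ensemble_mean([a, b])
        assert out["Bio1"].values[0, 0] == 2.0
        assert np.isnan(out["Bio1"].values[0, 1])

    def test_permutation_invariant(self, rng):
        members = [_stack(rng.uniform(size=(3, 3))) for _ in range(3)]
        out1 = ensemble_mean(members)
        out2 = ensemble_mean(members[::-1])
        np.testing.assert_allclose(out1["Bio1"].values, out2["Bio1"].values)

    def test_single_member_identity(self, rng):
        m = _stack(rng.uniform(size=(3, 3)))
        np.testing.assert_allclose(
            ensemble_mean([m])["Bio1"].values, m["Bio1"].values
        )

    def test_geometry_mismatch_raises(self):
        a = _stack(np.zeros((2, 2)))
        b = RasterStack({"Bio1": Grid(nrows=2, ncols=2, xll=5, yll=0,
                                      cellsize=1, values=np.zeros((2, 2)))})
        with pytest.raises(AlignmentError):
            ensemble_mean([a, b])

    def test_bad_weights_rejected(self):
        m = _stack(np.zeros((1, 1)))
        with pytest.raises(ValueError, match="sum to 1"):
            ensemble_mean([m, m], weights=(0.5, 0.6))


class TestIntersectMask:
    def test_all_valid(self):
        a = _stack(np.ones((2, 2)))
        assert intersect_mask(a).all()

    def test_disjoint_nodata(self):
        a = _stack(np.array([[np.nan, 1.0], [1.0, 1.0]]))
        b = _stack(np.array([[1.0, np.nan], [1.0, 1.0]]))
        m = intersect_mask(a, b)
        assert m.tolist() == [[False, False], [True, True]]

    def test_symmetric_and_idempotent(self, rng):
        vals1 = rng.uniform(size=(4, 4))
        vals1[rng.random((4, 4)) < 0.3] = np.nan
        vals2 = rng.uniform(size=(4, 4))
        vals2[rng.random((4, 4)) < 0.3] = np.nan
        a, b = _stack(vals1), _stack(vals2)
        m_ab = intersect_mask(a, b)
        m_ba = intersect_mask(b, a)
        np.testing.assert_array_equal(m_ab, m_ba)
        # masking again with the mask itself changes nothing
        mg = a["Bio1"].copy(values=np.where(m_ab, 1.0, np.nan))
        np.testing.assert_array_equal(intersect_mask(a, b, mg), m_ab)
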