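"""Raster/point model, extraction, screening and spatial statistics."""

import numpy as np
import pandas as pd
import pytest

import nichecast as nc
from nichecast.grids import _contiguity_pairs


def small_stack():
    grid = nc.GridSpec(x_origin=0.0, y_top=3.0, cell_size=1.0, n_rows=3, n_cols=4)
    vals = np.arange(12, dtype=float).reshape(3, 4)
    return nc.PredictorStack({"a": nc.Layer(grid, vals), "b": nc.Layer(grid, vals * 10)})


class TestExtractValues:
    def test_cell_center_returns_cell_value(self):
        stack = small_stack()
        sm = nc.extract_values(stack, [1.5], [1.5])  # center of row 1, col 1
        assert sm.frame.loc[0, "a"] == 5.0
        assert sm.frame.loc[0, "b"] == 50.0

    def test_shared_edge_half_open_convention(self):
        stack = small_stack()
        # x=1.0 is the closed left edge of column 1; y=2.0 is the closed top
        # edge of row 1 (row 0 covers (2, 3])
        sm = nc.extract_values(stack, [1.0], [2.0])
        assert sm.frame.loc[0, "a"] == 5.0  # row 1, col 1

    def test_empty_point_list(self):
        sm = nc.extract_values(small_stack(), [], [])
        assert len(sm) == 0
        assert list(sm.frame.columns) == ["a", "b"]

    def test_out_of_bounds_dropped_and_tallied(self):
        sm = nc.extract_values(small_stack(), [0.5, -5.0], [0.5, 0.5])
        assert len(sm) == 1
        assert sm.n_dropped == 1

    def test_nodata_cell_dropped(self):
        stack = small_stack()
        stack["a"].values[0, 0] = np.nan
        sm = nc.extract_values(stack, [0.5], [2.5])  # row 0, col 0
        assert len(sm) == 0
        assert sm.n_dropped == 1


class TestCorrelationScreen:
    def test_duplicate_and_negated_columns_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        frame = pd.DataFrame({"a": a, "dup": a.copy(), "neg": -a})
        retained, corr = nc.correlation_screen(frame)
        assert retained == ["a"]
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_independent_noise_all_retained(self):
        rng = np.random.default_rng(7)
        frame = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("xyz"))
        retained, corr = nc.correlation_screen(frame)
        assert retained == ["x", "y", "z"]
        off_diag = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.85)

    def test_zero_variance_column_retained(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "const": [5.0] * 4})
        retained, _ = nc.correlation_screen(frame)
        assert "const" in retained

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            nc.correlation_screen(pd.DataFrame({"a": [1.0, 2.0]}))


def morans_i_bruteforce(values: np.ndarray, contiguity: str = "rook") -> float:
    """O(n^2) double loop over all cell pairs; the independent oracle."""
    n_rows, n_cols = values.shape
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)
             if np.isfinite(values[r, c])]
    n = len(cells)
    xbar = np.mean([values[r, c] for r, c in cells])
    num = 0.0
    s0 = 0.0
    for (r1, c1) in cells:
        for (r2, c2) in cells:
            if (r1, c1) == (r2, c2):
                continue
            dr, dc = abs(r1 - r2), abs(c1 - c2)
            if contiguity == "rook":
                w = 1.0 if dr + dc == 1 else 0.0
            else:
                w = 1.0 if max(dr, dc) == 1 else 0.0
            if w:
                num += (values[r1, c1] - xbar) * (values[r2, c2] - xbar)
                s0 += 1.0
    den = sum((values[r, c] - xbar) ** 2 for r, c in cells)
    return (n / s0) * num / den


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        vals = ((np.indices((10, 10)).sum(axis=0) % 2) * 2 - 1).astype(float)
        res = nc.morans_i(vals, contiguity="rook", n_perm=99, seed=0)
        assert res["I"] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("contiguity", ["rook", "queen"])
    def test_matches_bruteforce_oracle(self, contiguity):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 10))
        vals[2, 3] = np.nan  # oracle must agree under nodata too
        res = nc.morans_i(vals, contiguity=contiguity, n_perm=19, seed=0)
        assert res["I"] == pytest.approx(morans_i_bruteforce(vals, contiguity), abs=1e-12)

    def test_two_block_field_matches_oracle(self):
        vals = np.zeros((10, 10))
        vals[:, :5] = 1.0
        res = nc.morans_i(vals, contiguity="rook", n_perm=19, seed=0)
        assert res["I"] == pytest.approx(morans_i_bruteforce(vals, "rook"), abs=1e-12)

    def test_checkerboard_permutation_p_small(self):
        vals = ((np.indices((10, 10)).sum(axis=0) % 2) * 2 - 1).astype(float)
        res = nc.morans_i(vals, contiguity="rook", inference="permutation",
                          n_perm=999, seed=5)
        assert res["p"] <= 0.01

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            nc.morans_i(np.ones((5, 5)), n_perm=9)

    def test_normal_inference_agrees_in_sign(self):
        vals = np.zeros((10, 10))
        vals[:, :5] = 1.0
        res = nc.morans_i(vals, inference="normal")
        assert res["z"] > 0 and res["p"] < 0.05


class TestRegionStats:
    def test_printed_count_percentages(self):
        # the two published region splits: 388/500 and 173/401
        t1 = nc.region_percentages({"allopatric": 388, "sympatric": 112})
        assert t1.loc["allopatric", "percent"] == 77.6
        t2 = nc.region_percentages({"allopatric": 173, "sympatric": 228})
        assert t2.loc["allopatric", "percent"] == 43.1

    def test_point_counting_conserves_totals(self):
        grid = nc.GridSpec(0.0, 2.0, 1.0, 2, 2)
        region = nc.Layer(grid, np.array([[1.0, 1.0], [2.0, np.nan]]))
        occ = nc.OccurrenceSet("sp", [0.5, 1.5, 0.5, 1.5, 5.0],
                               [1.5, 1.5, 0.5, 0.5, 0.5])
        stats = nc.region_occurrence_stats(occ, region)
        assert stats["count"].sum() == 5
        assert stats.loc["unassigned", "count"] == 2  # nodata cell + out of bounds

    def test_single_region_is_100_percent(self):
        grid = nc.GridSpec(0.0, 1.0, 1.0, 1, 2)
        region = nc.Layer(grid, np.array([[1.0, 1.0]]))
        occ = nc.OccurrenceSet("sp", [0.5, 1.5], [0.5, 0.5])
        stats = nc.region_occurrence_stats(occ, region)
        assert stats["percent"].tolist() == [100.0]


class TestLatitudinalProfile:
    def test_constant_layer_constant_bands(self):
        grid = nc.GridSpec(0.0, 10.0, 1.0, 10, 5)
        layer = nc.Layer(grid, np.full((10, 5), 0.4))
        prof = nc.latitudinal_profile(layer, band_width=2.5)
        assert len(prof) == 4
        assert np.allclose(prof["mean"], 0.4)

    def test_band_count_is_ceiling_of_extent_ratio(self):
        grid = nc.GridSpec(0.0, 10.0, 1.0, 10, 5)
        layer = nc.Layer(grid, np.zeros((10, 5)))
        assert len(nc.latitudinal_profile(layer, 3.0)) == 4  # ceil(10/3)
        assert len(nc.latitudinal_profile(layer, 100.0)) == 1  # single band

    def test_latitude_gradient_is_monotone(self):
        grid = nc.GridSpec(0.0, 10.0, 1.0, 10, 5)
        yy = np.repeat(grid.row_centers_y()[:, None], 5, axis=1)
        prof = nc.latitudinal_profile(nc.Layer(grid, yy / 10.0), band_width=2.0)
        means = prof["mean"].to_numpy()
        assert np.all(np.diff(means) > 0)  # bands ordered south -> north


class TestIO:
    def test_ascii_grid_roundtrip(self, tmp_path):
        grid = nc.GridSpec(2.0, 13.0, 0.5, 4, 6)
        vals = np.arange(24, dtype=float).reshape(4, 6)
        vals[1, 2] = np.nan
        path = tmp_path / "layer.asc"
        nc.write_ascii_grid(nc.Layer(grid, vals), path)
        back = nc.read_ascii_grid(path)
        assert back.grid == grid
        assert np.array_equal(back.values, vals, equal_nan=True)

    def test_occurrence_csv_roundtrip(self, tmp_path):
        occ = nc.OccurrenceSet("newt", [1.0, 2.0], [3.0, 4.0],
                               np.array(["allopatric", "sympatric"], dtype=object))
        path = tmp_path / "occ.csv"
        nc.write_occurrences_csv(occ, path)
        back = nc.read_occurrences_csv(path)
        assert back.species_id == "newt"
        assert np.array_equal(back.x, occ.x)
        assert list(back.region) == ["allopatric", "sympatric"]

    def test_resample_nearest_identity(self):
        grid = nc.GridSpec(0.0, 4.0, 1.0, 4, 4)
        layer = nc.Layer(grid, np.arange(16, dtype=float).reshape(4, 4))
        again = nc.grids.resample_nearest(layer, grid)
        assert np.array_equal(again.values, layer.values)


def test_contiguity_pair_counts():
    i, j = _contiguity_pairs((4, 5), "rook")
    # rook edges: 4*(5-1) horizontal + (4-1)*5 vertical, both directions
    assert i.size == 2 * (4 * 4 + 3 * 5)
    i, j = _contiguity_pairs((4, 5), "queen")
    assert i.size == 2 * (4 * 4 + 3 * 5 + 2 * 3 * 4)
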