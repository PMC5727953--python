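"""MESS similarity, the MEDI transform, and multi-GCM consensus averaging."""

import numpy as np
import pandas as pd
import pytest

import nichecast as nc


def make_stack(values_by_name):
    first = next(iter(values_by_name.values()))
    first = np.atleast_2d(np.asarray(first, dtype=float))
    grid = nc.GridSpec(0.0, float(first.shape[0]), 1.0, first.shape[0], first.shape[1])
    return nc.PredictorStack({
        n: nc.Layer(grid, np.atleast_2d(np.asarray(v, dtype=float)))
        for n, v in values_by_name.items()
    })


def mess_bruteforce(ref: pd.DataFrame, stack) -> np.ndarray:
    """Independent per-cell/per-variable evaluation of the piecewise rule."""
    shape = stack.grid.shape
    out = np.full(shape, np.inf)
    for var in ref.columns:
        r = np.sort(ref[var].to_numpy(dtype=float))
        lo, hi = r[0], r[-1]
        for i in range(shape[0]):
            for j in range(shape[1]):
                v = stack[var].values[i, j]
                if not np.isfinite(v):
                    out[i, j] = np.nan
                    continue
                f = 100.0 * np.sum(r < v) / r.size
                if f == 0:
                    s = 100.0 * (v - lo) / (hi - lo)
                elif f <= 50:
                    s = 2.0 * f
                elif f < 100:
                    s = 2.0 * (100.0 - f)
                else:
                    s = 100.0 * (hi - v) / (hi - lo)
                out[i, j] = min(out[i, j], s)
    return out


class TestMess:
    def test_hand_examples_on_1_to_100_reference(self):
        ref = pd.DataFrame({"v": np.arange(1.0, 101.0)})
        stack = make_stack({"v": [[50.0, 0.0, 1.0]]})
        mes = nc.compute_mess(ref, stack).mes.values[0]
        assert mes[0] == pytest.approx(98.0)  # f = 49 -> 2f
        assert mes[1] == pytest.approx(100.0 * (0 - 1) / 99)  # below the minimum
        assert mes[2] == pytest.approx(0.0)  # exactly at the minimum

    def test_mes_is_min_over_variables(self):
        ref = pd.DataFrame({"a": np.arange(1.0, 11.0), "b": np.arange(1.0, 11.0)})
        stack = make_stack({"a": [[5.0]], "b": [[0.0]]})
        res = nc.compute_mess(ref, stack)
        assert res.mes.values[0, 0] == res.per_variable["b"].values[0, 0]
        assert res.mes.values[0, 0] < 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        vals = {c: rng.normal(scale=2.0, size=(15, 20)) for c in "abcd"}
        stack = make_stack(vals)
        res = nc.compute_mess(ref, stack)
        assert np.allclose(res.mes.values, mess_bruteforce(ref, stack), atol=1e-9)

    def test_missing_variable_rejected(self):
        ref = pd.DataFrame({"a": np.arange(5.0), "zz": np.arange(5.0)})
        with pytest.raises(ValueError, match="zz"):
            nc.compute_mess(ref, make_stack({"a": [[1.0]]}))

    def test_nodata_propagates(self):
        ref = pd.DataFrame({"a": np.arange(1.0, 11.0)})
        stack = make_stack({"a": [[5.0, np.nan]]})
        mes = nc.compute_mess(ref, stack).mes.values
        assert np.isnan(mes[0, 1]) and np.isfinite(mes[0, 0])


class TestMedi:
    @pytest.mark.parametrize("mes,medi", [(0.0, 100.0), (-20.0, 120.0), (100.0, 0.0)])
    def test_affine_identities(self, mes, medi):
        grid = nc.GridSpec(0.0, 1.0, 1.0, 1, 1)
        layer = nc.Layer(grid, np.array([[mes]]))
        assert nc.mes_to_medi(layer).layer.values[0, 0] == medi

    def test_inverse_transform_roundtrip(self):
        rng = np.random.default_rng(0)
        grid = nc.GridSpec(0.0, 5.0, 1.0, 5, 5)
        mes = nc.Layer(grid, rng.uniform(-50, 100, size=(5, 5)))
        medi = nc.mes_to_medi(mes)
        back = 100.0 - medi.layer.values
        assert np.allclose(back, mes.values)

    def test_negative_mes_iff_medi_above_100(self):
        rng = np.random.default_rng(1)
        grid = nc.GridSpec(0.0, 4.0, 1.0, 4, 4)
        mes = nc.Layer(grid, rng.uniform(-30, 30, size=(4, 4)))
        medi = nc.mes_to_medi(mes).layer.values
        assert np.array_equal(medi > 100, mes.values < 0)


class TestExtrapolatedArea:
    def test_all_analog_is_zero(self):
        grid = nc.GridSpec(0.0, 2.0, 1.0, 2, 2)
        assert nc.extrapolated_area_fraction(nc.Layer(grid, np.full((2, 2), 10.0))) == 0.0

    def test_three_of_twelve_is_25_percent(self):
        grid = nc.GridSpec(0.0, 3.0, 1.0, 3, 4)
        vals = np.full((3, 4), 5.0)
        vals[0, :3] = -30.0
        assert nc.extrapolated_area_fraction(nc.Layer(grid, vals)) == 25.0

    def test_nodata_excluded_from_both_sides(self):
        grid = nc.GridSpec(0.0, 2.0, 1.0, 2, 2)
        vals = np.array([[np.nan, -30.0], [5.0, np.nan]])
        assert nc.extrapolated_area_fraction(nc.Layer(grid, vals)) == 50.0


class TestConsensus:
    def grid(self):
        return nc.GridSpec(0.0, 1.0, 1.0, 1, 2)

    def test_equal_medi_equals_plain_mean(self):
        g = self.grid()
        p1 = nc.Layer(g, np.array([[0.8, 0.3]]))
        p2 = nc.Layer(g, np.array([[0.2, 0.5]]))
        wa = nc.consensus({"a": p1, "b": p2}, {"a": 70.0, "b": 70.0}, "medi_weighted")
        mean = nc.consensus({"a": p1, "b": p2}, method="mean")
        assert np.allclose(wa.combined.values, mean.combined.values)

    def test_hand_weighted_example(self):
        g = self.grid()
        p1 = nc.Layer(g, np.full((1, 2), 0.8))
        p2 = nc.Layer(g, np.full((1, 2), 0.2))
        wa = nc.consensus({"a": p1, "b": p2}, {"a": 50.0, "b": 150.0}, "medi_weighted")
        # weights 1/50 and 1/150 normalize to 0.75/0.25 -> 0.65
        assert wa.combined.values[0, 0] == pytest.approx(0.65)

    def test_enormous_medi_converges_to_other_projection(self):
        g = self.grid()
        p1 = nc.Layer(g, np.full((1, 2), 0.8))
        p2 = nc.Layer(g, np.full((1, 2), 0.2))
        wa = nc.consensus({"a": p1, "b": p2}, {"a": 50.0, "b": 1e6}, "medi_weighted")
        assert wa.combined.values[0, 0] == pytest.approx(0.8, abs=1e-3)

    def test_nonpositive_medi_rejected(self):
        g = self.grid()
        p1 = nc.Layer(g, np.full((1, 2), 0.8))
        p2 = nc.Layer(g, np.full((1, 2), 0.2))
        with pytest.raises(ValueError, match="MEDI"):
            nc.consensus({"a": p1, "b": p2}, {"a": -5.0, "b": 70.0}, "medi_weighted")

    def test_grid_mismatch_rejected(self):
        p1 = nc.Layer(nc.GridSpec(0.0, 1.0, 1.0, 1, 2), np.full((1, 2), 0.8))
        p2 = nc.Layer(nc.GridSpec(0.0, 1.0, 1.0, 1, 3), np.full((1, 3), 0.2))
        with pytest.raises(ValueError, match="grid"):
            nc.consensus({"a": p1, "b": p2}, method="mean")

    @pytest.mark.parametrize("method,medis", [
        ("mean", None), ("medi_weighted", {"a": 80.0, "b": 120.0}),
    ])
    def test_output_within_input_range(self, method, medis):
        rng = np.random.default_rng(2)
        g = nc.GridSpec(0.0, 6.0, 1.0, 6, 6)
        p1 = nc.Layer(g, rng.uniform(size=(6, 6)))
        p2 = nc.Layer(g, rng.uniform(size=(6, 6)))
        out = nc.consensus({"a": p1, "b": p2}, medis, method).combined.values
        lo = np.minimum(p1.values, p2.values)
        hi = np.maximum(p1.values, p2.values)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)
        assert np.all((out >= 0) & (out <= 1))

    def test_percell_medi_layers_downweight_shifted_region(self, landscape,
                                                           montane_model):
        """On a scenario shifted outside the training range, the weighted
        consensus tracks the less-shifted GCM where climate is non-analog."""
        from nichecast import synthetic as syn

        model = montane_model["model"]
        samples = montane_model["samples"]
        span = np.ptp(landscape["temp_range"].valid_values())
        variants = syn.make_scenario_variants(landscape, [
            syn.ScenarioShift("mild", offsets={"temp_range": 0.1 * span}),
            syn.ScenarioShift("wild", offsets={"temp_range": 1.5 * span}),
        ])
        ref = samples.frame
        projs = {g: nc.project(model, st) for g, st in variants.items()}
        medis = {
            g: nc.mes_to_medi(nc.compute_mess(ref, st)) for g, st in variants.items()
        }
        wa = nc.consensus(projs, medis, "medi_weighted").combined.values
        mean = nc.consensus(projs, method="mean").combined.values
        assert not np.allclose(wa, mean, atol=1e-6)
        # weighted result is closer to the mild-GCM projection than the mean is
        mild = projs["mild"].suitability.values
        assert np.nanmean(np.abs(wa - mild)) < np.nanmean(np.abs(mean - mild))
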