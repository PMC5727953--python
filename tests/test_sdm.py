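"""Boosted suitability model: fitting contract, evaluation, interrogation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import nichecast as nc
from nichecast.sdm import auc_rank, bernoulli_deviance

from conftest import FAST_BRT


def logistic_samples(n=400, slope=3.0, seed=0, extra_noise_cols=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(slope * x)).astype(int)
    data = {"x": x}
    for i in range(extra_noise_cols):
        data[f"noise{i}"] = rng.normal(size=n)
    return pd.DataFrame(data), y


class TestDevianceAndAuc:
    def test_null_model_deviance_on_balanced_data_is_2ln2(self):
        y = np.array([0, 1] * 50)
        assert bernoulli_deviance(y, np.full(100, 0.5)) == pytest.approx(
            2 * np.log(2), abs=1e-12
        )
        assert round(bernoulli_deviance(y, np.full(100, 0.5)), 3) == 1.386

    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert auc_rank(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_ties_get_half_credit(self):
        y = np.array([0, 1])
        assert auc_rank(y, np.array([0.5, 0.5])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank(np.ones(4), np.arange(4.0))


class TestFitContract:
    def test_single_class_response_rejected(self):
        X = pd.DataFrame({"x": np.arange(40.0)})
        with pytest.raises(ValueError, match="both classes"):
            nc.BoostedSuitability(cv_folds=2).fit(X, np.ones(40, dtype=int))

    def test_training_deviance_non_increasing_without_bagging(self):
        X, y = logistic_samples(n=200, seed=1)
        model = nc.BoostedSuitability(
            learning_rate=0.05, bag_fraction=1.0, max_trees=300, n_step=50,
            cv_folds=5, random_state=0,
        ).fit(X, y)
        dev = model.staged_training_deviance()
        assert np.all(np.diff(dev) <= 1e-9)

    def test_predictions_strictly_inside_unit_interval(self, montane_model):
        p = montane_model["model"].predict_suitability(montane_model["samples"].frame)
        assert np.all((p > 0) & (p < 1))

    def test_single_predictor_logistic_truth_recovers_auc(self):
        X, y = logistic_samples(n=400, slope=3.0, seed=2)
        model = nc.BoostedSuitability(random_state=5, **FAST_BRT).fit(X, y)
        rep = nc.evaluate_model(model)
        assert rep.cv_auc_mean > 0.8

    def test_fit_fully_reproducible_under_seed(self):
        X, y = logistic_samples(n=150, seed=3)
        kw = dict(learning_rate=0.05, max_trees=300, n_step=50, cv_folds=5,
                  random_state=77)
        m1 = nc.BoostedSuitability(**kw).fit(X, y)
        m2 = nc.BoostedSuitability(**kw).fit(X, y)
        assert m1.n_trees_ == m2.n_trees_
        assert np.array_equal(m1.cv_deviance_, m2.cv_deviance_)
        assert np.array_equal(
            m1.predict_suitability(X), m2.predict_suitability(X)
        )

    def test_n_trees_at_cv_minimum(self, montane_model):
        model = montane_model["model"]
        best = int(np.argmin(model.cv_deviance_))
        assert model.n_trees_ == model.n_step * (best + 1)
        assert model.n_trees_ > 0


class TestEvaluate:
    def test_total_deviance_balanced_is_1386(self, montane_model):
        rep = nc.evaluate_model(montane_model["model"])
        assert round(rep.mean_total_deviance, 3) == 1.386

    def test_residual_below_total(self, montane_model):
        rep = nc.evaluate_model(montane_model["model"])
        assert rep.mean_residual_deviance < rep.mean_total_deviance

    def test_relative_influence_sums_to_100(self, montane_model):
        rep = nc.evaluate_model(montane_model["model"])
        assert rep.relative_influence.sum() == pytest.approx(100.0, abs=1e-9)

    def test_auc_in_unit_interval(self, montane_model):
        rep = nc.evaluate_model(montane_model["model"])
        assert 0.0 <= rep.cv_auc_mean <= 1.0


class TestPartialDependence:
    def test_unknown_predictor_rejected(self, montane_model):
        with pytest.raises(ValueError):
            nc.partial_dependence(montane_model["model"], "nope")

    def test_grid_length(self, montane_model):
        pd_ = nc.partial_dependence(montane_model["model"], "temp_range", n_grid=37)
        assert pd_.grid.size == 37 and pd_.values.size == 37

    def test_constant_predictor_flat_curve(self):
        X, y = logistic_samples(n=200, seed=4)
        X["const"] = 1.0
        model = nc.BoostedSuitability(
            learning_rate=0.05, max_trees=300, n_step=50, cv_folds=5, random_state=0
        ).fit(X, y)
        rep = nc.evaluate_model(model)
        assert rep.relative_influence["const"] == 0.0
        curve = nc.partial_dependence(model, "const", n_grid=10)
        assert np.ptp(curve.values) < 1e-6

    def test_monotone_truth_recovered(self):
        X, y = logistic_samples(n=400, slope=3.0, seed=5, extra_noise_cols=1)
        model = nc.BoostedSuitability(random_state=6, **FAST_BRT).fit(X, y)
        assert nc.partial_dependence(model, "x", n_grid=50).direction() == 1

    def test_opposite_species_have_opposite_directions(
        self, montane_model, lowland_model
    ):
        """Parameter recovery: the two species' responses to the shared
        predictor come out with opposite Spearman signs."""
        for pred in ("temp_range", "annual_precip"):
            d_m = nc.partial_dependence(montane_model["model"], pred, 50).direction()
            d_l = nc.partial_dependence(lowland_model["model"], pred, 50).direction()
            assert d_m == -d_l != 0


class TestInteractions:
    def test_all_pairs_reported(self, montane_model):
        scores = nc.interaction_strengths(montane_model["model"], n_grid=8)
        p = len(montane_model["model"].feature_names_in_)
        assert len(scores) == p * (p - 1) // 2
        assert all(s.strength >= 0 for s in scores)

    def test_multiplicative_truth_scores_above_additive(self):
        rng = np.random.default_rng(8)
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y_add = (rng.random(n) < expit(1.5 * X["a"] + 1.5 * X["b"])).astype(int)
        y_mult = (rng.random(n) < expit(3.0 * X["a"] * X["b"])).astype(int)
        kw = dict(learning_rate=0.05, max_trees=600, n_step=50, cv_folds=5)
        m_add = nc.BoostedSuitability(random_state=1, **kw).fit(X, y_add)
        m_mult = nc.BoostedSuitability(random_state=1, **kw).fit(X, y_mult)
        s_add = nc.interaction_strengths(m_add, n_grid=15)[0].strength
        s_mult = nc.interaction_strengths(m_mult, n_grid=15)[0].strength
        assert s_mult > s_add

    def test_symmetry_of_reported_pair(self, montane_model):
        scores = nc.interaction_strengths(montane_model["model"], n_grid=8)
        # each unordered pair appears exactly once
        pairs = [frozenset(s.pair) for s in scores]
        assert len(pairs) == len(set(pairs))


class TestProject:
    def test_projection_matches_training_predictions(self, landscape, montane_model):
        model = montane_model["model"]
        proj = nc.project(model, landscape)
        occ = montane_model["occ"]
        r, c, _ = landscape.grid.cell_of(occ.x, occ.y)
        sm = nc.extract_values(landscape, occ.x, occ.y)
        direct = model.predict_suitability(sm.frame)
        assert np.allclose(proj.suitability.values[r, c], direct)

    def test_constant_stack_constant_projection(self, montane_model):
        grid = nc.GridSpec(0.0, 10.0, 1.0, 10, 10)
        model = montane_model["model"]
        means = montane_model["samples"].frame.mean()
        stack = nc.PredictorStack({
            n: nc.Layer(grid, np.full((10, 10), means[n]))
            for n in model.feature_names_in_
        })
        proj = nc.project(model, stack)
        assert np.ptp(proj.suitability.values) == 0.0

    def test_missing_layer_named_in_error(self, landscape, montane_model):
        partial = nc.PredictorStack({"temp_range": landscape["temp_range"]})
        with pytest.raises(ValueError, match="annual_precip"):
            nc.project(montane_model["model"], partial)

    def test_nodata_preserved(self, landscape, montane_model):
        stack = landscape.copy()
        stack["temp_range"].values[5, 5] = np.nan
        proj = nc.project(montane_model["model"], stack)
        assert np.isnan(proj.suitability.values[5, 5])
        assert np.isfinite(proj.suitability.values[6, 6])
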