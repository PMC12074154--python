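"""Boosted-tree training, tuning determinism, importance, raster prediction."""

import numpy as np
import pandas as pd
import pytest

from standagb.agb_estimator import (GBDTConfig, make_training_table,
                                    predict_raster, tune_and_train,
                                    variable_importance)
from standagb.biomass_samples import AGBSample
from standagb.raster import GridSpec, Raster
from standagb.spectral_features import FEATURE_NAMES, FeatureStack

#: Small grid for table tests.
FAST = GBDTConfig(shrinkage_grid=(0.05, 0.1), ntree_grid=(50, 100),
                  split_seed=3)


def _table(n, rng, signal_features=("NDVI", "TCG", "B8"), noise_sd=0.0,
           permute=False):
    data = {name: rng.uniform(0, 1, n) for name in FEATURE_NAMES}
    t = pd.DataFrame(data)
    y = (500 * t[signal_features[0]] + 300 * t[signal_features[1]]
         + 200 * t[signal_features[2]])
    if noise_sd:
        y = y + rng.normal(0, noise_sd, n)
    if permute:
        y = pd.Series(rng.permutation(y.to_numpy()))
    t["agb_g_m2"] = y
    return t


def _stack(rng, nrows=4, ncols=4, constant=None):
    grid = GridSpec(0.0, nrows * 30.0, 30.0, nrows, ncols)
    layers = {}
    for name in FEATURE_NAMES:
        if constant is None:
            layers[name] = Raster(rng.uniform(0, 1, (nrows, ncols)), grid)
        else:
            layers[name] = Raster(np.full((nrows, ncols), constant), grid)
    return FeatureStack(layers)


def _samples_on(stack, cells, agb=100.0):
    g = stack.grid
    return [AGBSample(cell_row=r, cell_col=c,
                      x_center=g.x0 + (c + 0.5) * g.cell,
                      y_center=g.y0 - (r + 0.5) * g.cell,
                      agb_g_m2=agb, n_trees=3, species="poplar",
                      s_m2=g.cell**2)
            for r, c in cells]


class TestMakeTrainingTable:
    def test_rows_match_stack_values(self, rng):
        stack = _stack(rng)
        samples = _samples_on(stack, [(0, 0), (1, 2), (3, 3)])
        table, n_dropped = make_training_table(samples, stack)
        assert table.shape == (3, 27) and n_dropped == 0
        assert table.loc[1, "NDVI"] == stack.layers["NDVI"].data[1, 2]

    def test_missing_pixel_dropped_and_counted(self, rng):
        stack = _stack(rng)
        stack.layers["EVI"].data[2, 2] = np.nan
        samples = _samples_on(stack, [(0, 0), (2, 2)])
        table, n_dropped = make_training_table(samples, stack)
        assert len(table) == 1 and n_dropped == 1

    def test_all_dropped_is_an_error(self, rng):
        stack = _stack(rng)
        stack.layers["EVI"].data[:] = np.nan
        with pytest.raises(ValueError, match="usable"):
            make_training_table(_samples_on(stack, [(0, 0)]), stack)


class TestTuneAndTrain:
    def test_learnable_deterministic_response(self, rng):
        """A noise-free response must be learned almost perfectly once the
        ensemble is deep enough and data are plentiful."""
        table = _table(1500, rng)
        cfg = GBDTConfig(shrinkage_grid=(0.1,), ntree_grid=(800,),
                         split_seed=3)
        bundle = tune_and_train(table, cfg)
        assert bundle.valid_metrics.r2 >= 0.99
        assert bundle.train_metrics.r2 >= bundle.valid_metrics.r2

    def test_permuted_labels_score_poorly(self, rng):
        clean = tune_and_train(_table(200, rng), FAST)
        noise = tune_and_train(_table(200, rng, permute=True), FAST)
        assert noise.valid_metrics.r2 <= 0.3
        assert noise.valid_metrics.r2 < clean.valid_metrics.r2

    def test_repeat_run_identical(self, rng):
        table = _table(120, np.random.default_rng(9))
        b1 = tune_and_train(table, FAST)
        b2 = tune_and_train(table, FAST)
        assert (b1.best_ntree, b1.best_shrinkage) == \
            (b2.best_ntree, b2.best_shrinkage)
        assert b1.valid_metrics.r2 == b2.valid_metrics.r2
        assert b1.importance == b2.importance

    def test_staged_grid_matches_independent_fits(self, rng):
        """Scoring the ntree axis from staged predictions must equal
        refitting each ensemble size separately (no subsampling)."""
        from sklearn.ensemble import GradientBoostingRegressor
        from sklearn.model_selection import train_test_split

        from standagb.height_dbh import compute_metrics

        table = _table(100, rng, noise_sd=30.0)
        cfg = GBDTConfig(shrinkage_grid=(0.1,), ntree_grid=(20, 60),
                         split_seed=5)
        bundle = tune_and_train(table, cfg)
        X = table[list(FEATURE_NAMES)].to_numpy()
        y = table["agb_g_m2"].to_numpy()
        X_tr, X_va, y_tr, y_va = train_test_split(X, y, train_size=0.8,
                                                  random_state=5)
        for nt in (20, 60):
            gbm = GradientBoostingRegressor(
                n_estimators=nt, learning_rate=0.1, max_depth=3,
                random_state=5).fit(X_tr, y_tr)
            r2 = compute_metrics(gbm.predict(X_va), y_va, k=2).r2
            assert bundle.grid_scores[f"0.1:{nt}"] == pytest.approx(r2,
                                                                    abs=1e-12)

    def test_added_noise_feature_changes_little(self, rng):
        table = _table(300, rng, noise_sd=20.0)
        base = tune_and_train(table, FAST)
        table2 = table.copy()
        table2.insert(0, "pure_noise", rng.uniform(0, 1, len(table)))
        more = tune_and_train(table2, FAST)
        assert abs(more.valid_metrics.r2 - base.valid_metrics.r2) < 0.05

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="30"):
            tune_and_train(_table(20, rng), FAST)


class TestImportance:
    def test_single_feature_response_dominates(self, rng):
        t = _table(250, rng)
        t["agb_g_m2"] = 1000 * t["TCG"]
        bundle = tune_and_train(t, FAST)
        top_name, top_share = bundle.importance[0]
        assert top_name == "TCG" and top_share >= 0.9

    def test_contributions_sum_to_one(self, rng):
        bundle = tune_and_train(_table(150, rng), FAST)
        assert sum(v for _, v in bundle.importance) == pytest.approx(
            1.0, abs=1e-9)
        assert all(v >= 0 for _, v in bundle.importance)

    def test_covers_all_26_variables(self, rng):
        bundle = tune_and_train(_table(150, rng), FAST)
        assert {n for n, _ in bundle.importance} == set(FEATURE_NAMES)

    def test_never_split_feature_has_zero_share(self, rng):
        t = _table(250, rng)
        t["agb_g_m2"] = 1000 * t["TCG"]
        bundle = tune_and_train(t, FAST)
        shares = dict(variable_importance(bundle))
        assert min(shares.values()) == 0.0


class TestPredictRaster:
    def test_training_pixels_reproduce_tabular_predictions(self, rng):
        stack = _stack(rng)
        cells = [(r, c) for r in range(4) for c in range(4)]
        samples = _samples_on(stack, cells)
        for i, s in enumerate(samples):
            s.agb_g_m2 = 50.0 + 10.0 * i
        table, _ = make_training_table(samples, stack)
        bundle = tune_and_train(
            pd.concat([table] * 3, ignore_index=True), FAST)
        raster = predict_raster(bundle, stack)
        direct = bundle.model.predict(
            table[list(bundle.feature_names)].to_numpy())
        flat = np.array([raster.data[r, c] for r, c in cells])
        np.testing.assert_allclose(flat, np.clip(direct, 0, None),
                                   rtol=1e-12)

    def test_constant_stack_gives_constant_raster(self, rng):
        train_stack = _stack(rng)
        cells = [(r, c) for r in range(4) for c in range(4)]
        samples = _samples_on(train_stack, cells, agb=200.0)
        table, _ = make_training_table(samples, train_stack)
        bundle = tune_and_train(pd.concat([table] * 2, ignore_index=True),
                                FAST)
        const = _stack(rng, constant=0.5)
        out = predict_raster(bundle, const)
        assert np.unique(out.data).size == 1

    def test_output_grid_matches_stack_and_missing_propagates(self, rng):
        stack = _stack(rng)
        stack.layers["NDVI"].data[0, 0] = np.nan
        cells = [(r, c) for r in range(4) for c in range(4) if (r, c) != (0, 0)]
        samples = _samples_on(stack, cells, agb=150.0)
        table, _ = make_training_table(samples, stack)
        bundle = tune_and_train(pd.concat([table] * 2, ignore_index=True),
                                FAST)
        out = predict_raster(bundle, stack)
        assert out.grid == stack.grid
        assert np.isnan(out.data[0, 0])
        assert np.isfinite(np.delete(out.data.ravel(), 0)).all()

    def test_variable_mismatch_rejected(self, rng):
        stack = _stack(rng)
        cells = [(r, c) for r in range(4) for c in range(4)]
        table, _ = make_training_table(_samples_on(stack, cells), stack)
        bundle = tune_and_train(pd.concat([table] * 2, ignore_index=True),
                                FAST)
        broken = FeatureStack(dict(stack.layers))
        del broken.layers["TCW"]
        with pytest.raises(ValueError, match="TCW"):
            predict_raster(bundle, broken)
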