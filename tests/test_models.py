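import numpy as np
import pandas as pd
import pytest

from rigiddg.models import (DNNConfig, RFConfig, SVRConfig, ablate,
                            dnn_ensemble, evaluate, load_model, predict,
                            save_model, train_model, tune)
from rigiddg.features import grouped_split
from rigiddg.synth import SyntheticSpec, gen_feature_dataset


@pytest.fixture(scope="module")
def splits(clean_dataset):
    records, X, y, split = clean_dataset
    return (X.iloc[split.train], y.iloc[split.train],
            X.iloc[split.dev], y.iloc[split.dev],
            X.iloc[split.test], y.iloc[split.test])


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0 and m.pearson_r == pytest.approx(1.0)

    def test_constant_shift(self):
        y = np.array([0.5, 1.5, -2.0, 3.0])
        m = evaluate(y + 2.0, y)
        assert m.rmse == pytest.approx(2.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_closed_form(self):
        m = evaluate([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert m.pearson_r == pytest.approx(-1.0)
        assert m.rmse == pytest.approx(np.sqrt(8.0 / 3.0))

    def test_shift_invariance_of_rmse(self):
        rng = np.random.default_rng(0)
        p, y = rng.normal(size=50), rng.normal(size=50)
        assert evaluate(p + 3.0, y + 3.0).rmse == pytest.approx(evaluate(p, y).rmse)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p, y = rng.normal(size=40), rng.normal(size=40)
        perm = rng.permutation(40)
        assert evaluate(p[perm], y[perm]) == evaluate(p, y)

    def test_constant_labels_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate([1.0, 2.0], [5.0, 5.0])


class TestTrainPredict:
    def test_constant_labels_reproduced(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(30, 4))
        y = np.full(30, 1.7)
        rf = train_model(X, y, RFConfig(n_trees=50))
        assert np.allclose(predict(rf, X), 1.7)
        svr = train_model(X, y, SVRConfig())
        assert np.all(np.abs(predict(svr, X) - 1.7) <= 0.1 + 1e-9)  # eps-tube

    def test_planted_linear_signal_recovered_in_training(self, splits):
        Xtr, ytr, *_ = splits
        for cfg in (SVRConfig(), RFConfig()):
            m = train_model(Xtr, ytr, cfg)
            assert evaluate(predict(m, Xtr), ytr).pearson_r >= 0.99

    def test_same_seed_bit_identical(self, splits):
        Xtr, ytr, Xdev, ydev, Xte, _ = splits
        for cfg in (RFConfig(seed=7), DNNConfig(seed=7, max_epochs=40)):
            m1 = train_model(Xtr, ytr, cfg, X_val=Xdev, y_val=ydev)
            m2 = train_model(Xtr, ytr, cfg, X_val=Xdev, y_val=ydev)
            assert np.array_equal(predict(m1, Xte), predict(m2, Xte))

    def test_empty_prediction_set(self, splits):
        Xtr, ytr, *_ = splits
        m = train_model(Xtr, ytr, RFConfig(n_trees=20))
        assert len(predict(m, Xtr.iloc[:0])) == 0

    def test_shuffled_rows_give_shuffled_predictions(self, splits):
        Xtr, ytr, _, _, Xte, _ = splits
        m = train_model(Xtr, ytr, RFConfig(n_trees=50))
        p = predict(m, Xte)
        perm = np.random.default_rng(0).permutation(len(Xte))
        assert np.array_equal(predict(m, Xte.iloc[perm]), p[perm])

    def test_deep_forest_fits_training_tighter_than_test(self, splits):
        Xtr, ytr, _, _, Xte, yte = splits
        m = train_model(Xtr, ytr, RFConfig(n_trees=100))
        assert (evaluate(predict(m, Xtr), ytr).rmse
                < evaluate(predict(m, Xte), yte).rmse)

    def test_nonfinite_features_rejected(self):
        X = np.ones((12, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_model(X, np.ones(12), RFConfig())

    def test_feature_count_mismatch_rejected(self, splits):
        Xtr, ytr, *_ = splits
        m = train_model(Xtr, ytr, DNNConfig(max_epochs=5))
        with pytest.raises(ValueError, match="features"):
            predict(m, Xtr.iloc[:, :10])

    def test_save_load_round_trip(self, tmp_path, splits):
        Xtr, ytr, _, _, Xte, _ = splits
        m = train_model(Xtr, ytr, RFConfig(n_trees=20))
        path = tmp_path / "model.joblib"
        save_model(m, path, config=RFConfig(n_trees=20))
        assert np.array_equal(predict(load_model(path), Xte), predict(m, Xte))


class TestDNN:
    def test_heldout_recovery_of_clean_signal(self, splits):
        Xtr, ytr, Xdev, ydev, Xte, yte = splits
        m = train_model(Xtr, ytr, DNNConfig(seed=3), X_val=Xdev, y_val=ydev)
        assert evaluate(predict(m, Xte), yte).pearson_r >= 0.7

    def test_sgd_optimizer_trains(self, splits):
        Xtr, ytr, _, _, Xte, yte = splits
        cfg = DNNConfig(seed=0, optimizer="sgd", learning_rate=0.01,
                        activation="tanh", max_epochs=100)
        m = train_model(Xtr, ytr, cfg)
        assert evaluate(predict(m, Xtr), ytr).pearson_r > 0.5

    def test_config_bounds_validated(self):
        with pytest.raises(ValueError):
            DNNConfig(n_hidden_layers=5)
        with pytest.raises(ValueError):
            DNNConfig(activation="gelu")


class TestDNNEnsemble:
    def test_single_seed_equals_single_model(self, splits):
        Xtr, ytr, _, _, Xte, _ = splits
        cfg = DNNConfig(seed=11, max_epochs=30)
        single = train_model(Xtr, ytr, cfg)
        ens = dnn_ensemble(Xtr, ytr, cfg, n_restarts=3)
        # force every restart to the same weights as the single model
        ens.models_ = [single] * 3
        assert np.allclose(predict(ens, Xte), predict(single, Xte))

    def test_ensemble_rmse_not_worse_than_worst_member(self, splits):
        Xtr, ytr, Xdev, ydev, Xte, yte = splits
        ens = dnn_ensemble(Xtr, ytr, DNNConfig(seed=5), n_restarts=5,
                           X_val=Xdev, y_val=ydev)
        worst = max(m.rmse for m in ens.restart_metrics(Xte, yte))
        assert evaluate(predict(ens, Xte), yte).rmse <= worst + 1e-12

    def test_reproducible_for_fixed_seed(self, splits):
        Xtr, ytr, _, _, Xte, _ = splits
        cfg = DNNConfig(seed=2, max_epochs=30)
        p1 = predict(dnn_ensemble(Xtr, ytr, cfg, 3), Xte)
        p2 = predict(dnn_ensemble(Xtr, ytr, cfg, 3), Xte)
        assert np.array_equal(p1, p2)

    def test_requires_at_least_two_restarts(self, splits):
        Xtr, ytr, *_ = splits
        with pytest.raises(ValueError):
            dnn_ensemble(Xtr, ytr, DNNConfig(), n_restarts=1)


class TestTune:
    def test_grid_of_one_returns_it(self, splits):
        Xtr, ytr, *_ = splits
        cfg = RFConfig(n_trees=30)
        assert tune(Xtr, ytr, [cfg], n_folds=3).best is cfg

    def test_degenerate_gamma_loses_to_default(self, splits):
        Xtr, ytr, *_ = splits
        grid = [SVRConfig(gamma=1e-6), SVRConfig(gamma=0.015)]
        assert tune(Xtr, ytr, grid, n_folds=5).best.gamma == 0.015

    def test_tied_configs_pick_first_listed(self, splits):
        Xtr, ytr, *_ = splits
        a, b = RFConfig(n_trees=25, seed=1), RFConfig(n_trees=25, seed=1)
        assert tune(Xtr, ytr, [a, b], n_folds=3).best is a

    def test_grouped_folds_require_enough_groups(self):
        X = np.random.default_rng(0).uniform(size=(40, 3))
        y = X[:, 0]
        groups = ["g1", "g2"] * 20
        with pytest.raises(ValueError, match="groups"):
            tune(X, y, [RFConfig(n_trees=10)], n_folds=5, groups=groups)

    def test_trace_covers_grid(self, splits):
        Xtr, ytr, *_ = splits
        grid = [RFConfig(n_trees=10), RFConfig(n_trees=20)]
        result = tune(Xtr, ytr, grid, n_folds=3)
        assert len(result.trace) == 2
        assert {"config", "mean_rmse"} <= set(result.trace.columns)

    def test_empty_grid_rejected(self, splits):
        Xtr, ytr, *_ = splits
        with pytest.raises(ValueError):
            tune(Xtr, ytr, [], n_folds=3)


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(n_records=200, n_groups=40, noise_sd=0.1, seed=4,
                         planted_weights={"mut1_sasa_rel": -0.05})
    records, X, y = gen_feature_dataset(spec)
    split = grouped_split(records, seed=4)
    return X, y, (split.train + split.dev, split.test)


class TestAblation:

    def test_causal_feature_ranked_first(self, planted):
        X, y, split = planted
        table = ablate(X, y, RFConfig(n_trees=100), split)
        assert table.iloc[0]["feature"] == "mut1_sasa"

    def test_one_row_per_feature_group(self, planted):
        X, y, split = planted
        groups = {"mut1_sasa": ["mut1_sasa_abs", "mut1_sasa_rel"],
                  "temperature": ["temperature"], "ph": ["ph"]}
        table = ablate(X, y, RFConfig(n_trees=50), split, feature_groups=groups)
        assert len(table) == 3
        assert set(table["feature"]) == set(groups)

    def test_constant_zero_column_is_inert_up_to_learner_stochasticity(self, planted):
        # A constant column carries no information, but removing it shifts
        # the forest's feature-subsampling RNG stream, so metrics agree only
        # up to the forest's own seed-to-seed variability.
        X, y, split = planted
        X = X.copy()
        X["inert"] = 0.0
        groups = {"zero": ["inert"], "ph": ["ph"]}
        table = ablate(X, y, RFConfig(n_trees=200, seed=9), split,
                       feature_groups=groups)
        base = table.attrs["baseline"]
        row = table.set_index("feature").loc["zero"]
        assert row["pearson_r"] == pytest.approx(base.pearson_r, abs=0.05)
        assert row["rmse"] == pytest.approx(base.rmse, rel=0.15)

    def test_removing_everything_rejected(self, planted):
        X, y, split = planted
        with pytest.raises(ValueError):
            ablate(X, y, RFConfig(n_trees=10), split,
                   feature_groups={"all": list(X.columns)})
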