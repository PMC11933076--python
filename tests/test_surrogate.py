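"""Train/test splitting, epsilon-SVR surrogates and error metrics."""

import numpy as np
import pandas as pd
import pytest

from fiberopt import published
from fiberopt.report import EvaluationMetrics
from fiberopt.schema import FEATURE_SETS, LABELS
from fiberopt.surrogate import (
    SvrHyperparams,
    SurrogateModel,
    TooFewRowsError,
    default_hyperparams,
    error_metrics,
    evaluate,
    split_dataset,
    train_svr,
)


class TestSplit:
    def test_eighty_twenty_sizes(self):
        train, test = split_dataset(100)
        assert (len(train), len(test)) == (80, 20)

    def test_disjoint_and_exhaustive(self):
        train, test = split_dataset(73, seed=5)
        assert set(train) | set(test) == set(range(73))
        assert set(train) & set(test) == set()

    def test_seed_determinism(self):
        a = split_dataset(50, seed=9)
        b = split_dataset(50, seed=9)
        c = split_dataset(50, seed=10)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()
        assert not (a[1] == c[1]).all()

    def test_too_few_rows(self):
        with pytest.raises(TooFewRowsError):
            split_dataset(4)


def _training_frame(rng, n, label):
    cols = FEATURE_SETS[label]
    return pd.DataFrame(rng.random((n, len(cols))), columns=cols)


class TestTrainSvr:
    def test_constant_label_predicts_constant(self, rng):
        X = _training_frame(rng, 40, "average_diameter_nm")
        hp = SvrHyperparams(gamma=1.0, C=10.0, epsilon=0.01)
        model = train_svr(X, np.full(40, 0.6), "average_diameter_nm", hp)
        pred = model.predict(X.to_numpy())
        assert np.all(np.abs(pred - 0.6) <= hp.epsilon + 1e-9)

    def test_published_release_hyperparams_fit_smooth_surface(self, surface_pre):
        """With the published drug-release hyperparameters, the SVR fits a
        noiseless smooth planted surface to high training R^2."""
        pre, _ = surface_pre
        lbl = "drug_release_pct"
        model = train_svr(pre.features, pre.labels[lbl], lbl, default_hyperparams(lbl))
        X = pre.features[list(model.feature_set)].to_numpy()
        y = pre.labels[lbl].to_numpy()
        pred = model.predict(X)
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.9

    def test_duplicating_rows_leaves_predictions_unchanged(self, rng):
        lbl = "encapsulation_efficiency_pct"
        X = _training_frame(rng, 60, lbl)
        y = np.sin(3 * X.iloc[:, 0]) + X.iloc[:, 1].to_numpy()
        hp = SvrHyperparams(gamma=1.0, C=50.0, epsilon=0.01)
        m1 = train_svr(X, y, lbl, hp)
        X2 = pd.concat([X, X], ignore_index=True)
        m2 = train_svr(X2, np.concatenate([y, y]), lbl, hp)
        probe = rng.random((30, X.shape[1]))
        np.testing.assert_allclose(m1.predict(probe), m2.predict(probe), atol=1e-6)

    def test_row_permutation_invariance(self, rng):
        lbl = "average_diameter_nm"
        X = _training_frame(rng, 80, lbl)
        y = X.iloc[:, 0].to_numpy() ** 2
        hp = SvrHyperparams(gamma=2.0, C=20.0, epsilon=0.01)
        m1 = train_svr(X, y, lbl, hp)
        perm = rng.permutation(80)
        m2 = train_svr(X.iloc[perm].reset_index(drop=True), y[perm], lbl, hp)
        probe = rng.random((20, X.shape[1]))
        np.testing.assert_allclose(m1.predict(probe), m2.predict(probe), atol=1e-8)

    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        lbl = "drug_release_pct"
        X = _training_frame(rng, 50, lbl)
        y = X.iloc[:, 0].to_numpy()
        model = train_svr(X, y, lbl, SvrHyperparams(gamma=1.0, C=10.0, epsilon=0.01))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SurrogateModel.from_json(path)
        probe = rng.random((25, X.shape[1]))
        np.testing.assert_allclose(model.predict(probe), back.predict(probe))

    def test_manual_predict_matches_sklearn(self, rng):
        from sklearn.svm import SVR

        lbl = "average_diameter_nm"
        X = _training_frame(rng, 70, lbl)
        y = np.cos(4 * X.iloc[:, 2].to_numpy())
        hp = SvrHyperparams(gamma=3.0, C=15.0, epsilon=0.005)
        model = train_svr(X, y, lbl, hp)
        ref = SVR(kernel="rbf", gamma=hp.gamma, C=hp.C, epsilon=hp.epsilon)
        ref.fit(X.to_numpy(), y)
        probe = rng.random((40, X.shape[1]))
        np.testing.assert_allclose(model.predict(probe), ref.predict(probe), atol=1e-10)

    def test_default_hyperparams_echo_published_values(self):
        hp = default_hyperparams("anticancer_activity_pct")
        assert hp.epsilon == 0.08052
        assert (hp.gamma, hp.C) == (0.85080, 41.04649)


class TestMetrics:
    def test_perfect_predictions(self):
        m = error_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert (m.mae, m.mse, m.rmse) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        """Errors {3, 4}: MAE 3.5, MSE 12.5, RMSE sqrt(12.5) = 3.53553."""
        m = error_metrics(np.array([3.0, 4.0]), np.array([0.0, 0.0]))
        assert m.mae == pytest.approx(3.5)
        assert m.mse == pytest.approx(12.5)
        assert m.rmse == pytest.approx(3.5355339, abs=1e-6)

    def test_brute_force_oracle_agreement(self, rng):
        for _ in range(20):
            y = rng.normal(size=17)
            p = rng.normal(size=17)
            m = error_metrics(y, p)
            assert m.mae == pytest.approx(sum(abs(a - b) for a, b in zip(y, p)) / 17, abs=1e-12)
            assert m.mse == pytest.approx(sum((a - b) ** 2 for a, b in zip(y, p)) / 17, abs=1e-12)
            assert m.rmse == pytest.approx(m.mse**0.5, abs=1e-12)
            assert m.mae <= m.rmse + 1e-12

    def test_inconsistent_metrics_rejected(self):
        with pytest.raises(ValueError):
            EvaluationMetrics(mae=13.14296, mse=99.67285, rmse=9.98362)

    def test_evaluate_in_original_units(self, surface_ds, surface_pre):
        """Metrics are computed after inverse-transforming predictions, so a
        diameter error is in nanometres (same magnitude as the raw labels)."""
        ds, _ = surface_ds
        pre, _ = surface_pre
        lbl = "average_diameter_nm"
        train, test = split_dataset(ds.n_rows, seed=1)
        model = train_svr(
            pre.features.iloc[train],
            pre.labels[lbl].iloc[train],
            lbl,
            SvrHyperparams(gamma=2.0, C=100.0, epsilon=1e-3),
        )
        m = evaluate(model, pre.features.iloc[test], pre.labels[lbl].iloc[test], pre.state)
        label_sd = float(ds.labels[lbl].std())
        assert 0 < m.rmse < label_sd  # beats the trivial predictor, right units
        assert m.mae <= m.rmse


def test_published_metric_rows_self_consistent():
    """The published diameter row (MSE 8361.02123, RMSE 91.43862) and its two
    companions satisfy RMSE = sqrt(MSE) at printed precision."""
    for lbl in published.SELF_CONSISTENT_METRIC_LABELS:
        _, mse, rmse = published.REPORTED_METRICS[lbl]
        assert np.sqrt(mse) == pytest.approx(rmse, abs=5e-5)
    assert set(LABELS) - set(published.SELF_CONSISTENT_METRIC_LABELS) == {
        "anticancer_activity_pct"
    }
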