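"""Box-Cox, SoftImpute and min-max scaling behavior."""

import numpy as np
import pytest

from fiberopt.preprocessing import (
    DegenerateColumnError,
    box_cox_forward,
    box_cox_inverse,
    fit_box_cox,
    inverse_min_max,
    min_max_scale,
    preprocess_pipeline,
    soft_impute,
)
from fiberopt.schema import FEATURES


class TestBoxCox:
    def test_lambda_one_is_identity_minus_one(self):
        x = np.array([0.5, 1.0, 4.2])
        np.testing.assert_allclose(box_cox_forward(x, 0.0, 1.0), x - 1.0)

    def test_lambda_zero_is_log(self):
        assert box_cox_forward(np.e, 0.0, 0.0) == pytest.approx(1.0)

    def test_lognormal_data_fit_lambda_near_zero(self, rng):
        """exp(standard normal) draws are exactly normalized by the log
        transform, so the fitted exponent must be close to 0."""
        x = np.exp(rng.standard_normal(5000))
        shift, lam = fit_box_cox(x)
        assert shift == 0.0
        assert abs(lam) <= 0.1

    def test_shift_rule_for_nonpositive_columns(self):
        x = np.array([-2.0, 0.0, 3.0, 5.0])
        shift, _ = fit_box_cox(x)
        assert shift == pytest.approx(1e-6 + 2.0)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateColumnError):
            fit_box_cox(np.full(10, 3.3))

    def test_forward_inverse_round_trip(self, rng):
        x = rng.uniform(0.1, 50.0, 200)
        shift, lam = fit_box_cox(x)
        back = box_cox_inverse(box_cox_forward(x, shift, lam), shift, lam)
        np.testing.assert_allclose(back, x, rtol=1e-9)


class TestSoftImpute:
    def test_no_missing_is_identity(self, rng):
        X = rng.normal(size=(10, 4))
        res = soft_impute(X, np.zeros_like(X, dtype=bool))
        assert res.n_iter == 0
        assert res.converged
        np.testing.assert_array_equal(res.completed, X)

    def test_nuclear_norm_oracle_agreement(self):
        """As lambda -> 0 the iteration solves minimal-nuclear-norm
        completion: on a 2x2 with one masked corner it matches a dense 1-D
        scan of the nuclear norm over the free cell.  (Note the minimizer is
        1, not the rank-1-consistent 4: three observed cells of a 2x2 are
        too few for rank-1 recovery.)"""

        def nuclear(m):
            return np.linalg.svd(m, compute_uv=False).sum()

        zs = np.linspace(-2.0, 6.0, 8001)
        oracle = zs[
            int(np.argmin([nuclear(np.array([[1.0, 2.0], [2.0, z]])) for z in zs]))
        ]
        X = np.array([[1.0, 2.0], [2.0, 0.0]])
        mask = np.array([[False, False], [False, True]])
        res = soft_impute(X, mask, lambda_nuclear=1e-3, tol=0.0, max_iter=20000)
        assert res.completed[1, 1] == pytest.approx(oracle, abs=1e-2)

    def test_rank1_entry_recovered_as_lambda_vanishes(self):
        """A masked off-diagonal cell of a rank-1 outer product is exactly
        the minimal-nuclear-norm value (confirmed by a 1-D oracle scan), and
        the iteration recovers it as lambda -> 0."""

        def nuclear(m):
            return np.linalg.svd(m, compute_uv=False).sum()

        a = np.array([1.0, 2.0, 3.0])
        X = np.outer(a, a)  # cell (1, 2) is 6
        zs = np.linspace(0.0, 10.0, 10001)

        def with_z(z):
            M = X.copy()
            M[1, 2] = z
            return M

        oracle = zs[int(np.argmin([nuclear(with_z(z)) for z in zs]))]
        assert oracle == pytest.approx(6.0, abs=1e-3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        res = soft_impute(
            np.where(mask, 0.0, X), mask, lambda_nuclear=1e-3, tol=0.0, max_iter=100000
        )
        assert res.completed[1, 2] == pytest.approx(6.0, abs=5e-3)

    def test_low_rank_recovery(self, rng):
        """10% masked cells of a rank-2 20x8 matrix are recovered within 5%
        of the matrix's value scale."""
        U = rng.normal(size=(20, 2))
        V = rng.normal(size=(8, 2))
        X = U @ V.T
        mask = np.zeros(X.size, dtype=bool)
        mask[rng.choice(X.size, size=16, replace=False)] = True
        mask = mask.reshape(X.shape)
        res = soft_impute(X, mask, lambda_nuclear=1e-2, tol=1e-9, max_iter=50000)
        rmse = np.sqrt(np.mean((res.completed[mask] - X[mask]) ** 2))
        assert rmse <= 0.05 * np.std(X)

    def test_objective_non_increasing(self, rng):
        X = rng.normal(size=(30, 6))
        mask = rng.random(X.shape) < 0.2
        res = soft_impute(X, mask)
        hist = np.array(res.objective_history)
        assert (np.diff(hist) <= 1e-8 * np.abs(hist[:-1])).all()

    def test_observed_cells_unchanged(self, rng):
        X = rng.normal(size=(15, 5))
        mask = rng.random(X.shape) < 0.15
        res = soft_impute(X, mask)
        np.testing.assert_array_equal(res.completed[~mask], X[~mask])

    def test_fully_missing_column_rejected(self):
        X = np.ones((4, 2))
        mask = np.zeros_like(X, dtype=bool)
        mask[:, 1] = True
        with pytest.raises(Exception, match="1"):
            soft_impute(X, mask)


class TestMinMax:
    def test_anchors_map_to_unit_interval(self):
        assert min_max_scale(8.0, 8.0, 24.0) == 0.0
        assert min_max_scale(24.0, 8.0, 24.0) == 1.0

    def test_distance_example(self):
        """A 15 cm distance with the literature (8, 24) anchors scales to
        (15-8)/(24-8) = 0.4375, and the inverse recovers 15."""
        assert min_max_scale(15.0, 8.0, 24.0) == pytest.approx(0.4375)
        assert inverse_min_max(0.4375, 8.0, 24.0) == pytest.approx(15.0)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(DegenerateColumnError):
            min_max_scale(1.0, 2.0, 2.0)


class TestPipeline:
    def test_all_columns_span_unit_interval(self, surface_pre):
        pre, _ = surface_pre
        for col in pre.features:
            assert pre.features[col].min() == pytest.approx(0.0, abs=1e-12)
            assert pre.features[col].max() == pytest.approx(1.0, abs=1e-12)
        assert not pre.features.isna().values.any()

    def test_all_observed_skips_imputation(self, surface_pre):
        pre, _ = surface_pre
        assert pre.imputation.n_iter == 0

    def test_inverse_recovers_original_features(self, surface_ds, surface_pre):
        ds, _ = surface_ds
        pre, _ = surface_pre
        for col in FEATURES:
            back = pre.state.inverse_column(col, pre.features[col].to_numpy())
            np.testing.assert_allclose(back, ds.features[col], rtol=1e-6, atol=1e-8)

    def test_rank_order_preserved(self, surface_ds, surface_pre):
        """The chain is strictly monotone per column, so ranks (hence any
        Spearman statistic) survive preprocessing untouched."""
        from scipy.stats import rankdata

        ds, _ = surface_ds
        pre, _ = surface_pre
        for col in ("distance_cm", "dox_concentration_wt_pct", "voltage_kV"):
            raw = ds.features[col].to_numpy()
            scaled = pre.features[col].to_numpy()
            np.testing.assert_array_equal(rankdata(raw), rankdata(scaled))

    def test_missing_cells_completed(self, marginal_ds):
        ds, _ = marginal_ds
        pre = preprocess_pipeline(ds)
        assert not pre.features.isna().values.any()
        assert pre.imputation.converged

    def test_transform_state_json_round_trip(self, surface_pre, tmp_path):
        from fiberopt.preprocessing import TransformState

        pre, _ = surface_pre
        path = tmp_path / "state.json"
        pre.state.to_json(path)
        back = TransformState.from_json(path)
        x = np.linspace(8.5, 23.0, 7)
        np.testing.assert_allclose(
            back.forward_column("distance_cm", x),
            pre.state.forward_column("distance_cm", x),
        )
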