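"""NIPALS PLS1: oracle equivalence, invariances, CV and LV selection."""

import numpy as np
import pandas as pd
import pytest

from ramancal import io
from ramancal.pls import (
    CVConfig,
    PLSModel,
    cross_validate,
    fit_pls,
    predict,
    select_latent_variables,
    split_train_test,
)


def _ols_predict(X, y, X_new):
    """Independent oracle: intercept + least squares via normal equations."""
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.column_stack([np.ones(len(X_new)), X_new]) @ beta


def _as_set(X, batch=None, fingerprint="fp", grid=None):
    n = X.shape[0]
    refs = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "batch_id": batch if batch is not None else ["b"] * n,
        "site_id": "site", "time_h": 0.0,
        **{c: 0.0 for c in io.CONCENTRATION_COLUMNS},
    })
    g = grid if grid is not None else np.arange(X.shape[1], dtype=float)
    return io.SpectraSet(g, X, refs, fingerprint=fingerprint)


class TestFit:
    def test_rank_one_problem_solved_with_one_component(self, rng):
        v = rng.normal(size=40)
        y = rng.normal(size=25)
        X = np.outer(y, v)
        model = fit_pls(X, y, 1)
        np.testing.assert_allclose(model.predict_matrix(X), y, atol=1e-10)

    def test_full_lv_pls_equals_ols(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8)
        model = fit_pls(X, y, 8)
        np.testing.assert_allclose(
            model.predict_matrix(X), _ols_predict(X, y, X), atol=1e-8
        )

    def test_agrees_with_sklearn_reference(self, rng):
        # independent cross-check of the NIPALS implementation
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 25))
        y = X[:, :5] @ rng.normal(size=5) + 0.1 * rng.normal(size=40)
        for k in (1, 3, 6):
            ours = fit_pls(X, y, k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.predict_matrix(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_translation_of_y_shifts_only_the_intercept(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        a = fit_pls(X, y, 3)
        b = fit_pls(X, y + 5.0, 3)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)
        assert b.y_mean - a.y_mean == pytest.approx(5.0)

    def test_scores_are_orthogonal(self, rng):
        from ramancal.pls import _nipals_pls1

        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        Xc, yc = X - X.mean(0), y - y.mean()
        _, _, _, T = _nipals_pls1(Xc, yc, 8)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_training_rmse_non_increasing_in_lv(self, rng):
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        errors = [
            np.sqrt(np.mean((fit_pls(X, y, k).predict_matrix(X) - y) ** 2))
            for k in range(1, 9)
        ]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_lv_exceeding_rank_rejected(self, rng):
        y = rng.normal(size=20)
        X = np.outer(y, rng.normal(size=15))  # rank 1
        with pytest.raises(ValueError, match="exhausted"):
            fit_pls(X, y, 5)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pls(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + 0.1 * rng.normal(size=30)
        perm = rng.permutation(30)
        a = fit_pls(X, y, 4)
        b = fit_pls(X[perm], y[perm], 4)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-8)
        np.testing.assert_allclose(
            a.predict_matrix(X), b.predict_matrix(X), atol=1e-8
        )


class TestPredictGuards:
    def test_mean_spectrum_predicts_mean_y(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 2)
        assert model.predict_matrix(X.mean(0)[None, :])[0] == pytest.approx(
            y.mean())

    def test_fingerprint_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        sset = _as_set(X, fingerprint="fp-a")
        model = fit_pls(X, y, 2, fingerprint="fp-a", grid=sset.grid)
        other = _as_set(X, fingerprint="fp-b")
        with pytest.raises(ValueError, match="fingerprint"):
            predict(model, other)

    def test_grid_length_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 2, fingerprint="fp", grid=np.arange(6.0))
        other = _as_set(rng.normal(size=(5, 9)))
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, other)


class TestCrossValidation:
    def _two_factor_data(self, rng, n=60, p=120):
        T = rng.normal(size=(n, 2))
        P = rng.normal(size=(2, p))
        X = T @ P
        y = T @ np.array([1.0, -0.5])
        groups = np.repeat([f"g{i}" for i in range(12)], n // 12)
        return X, y, groups

    def test_two_factor_data_needs_exactly_two_components(self, rng):
        X, y, groups = self._two_factor_data(rng)
        curve = cross_validate(X, y, groups, CVConfig(folds=6, max_lv=6))
        assert curve[1] < 0.01 * curve[0]

    def test_curve_is_deterministic_given_config(self, rng):
        X, y, groups = self._two_factor_data(rng)
        cfg = CVConfig(folds=6, max_lv=5, seed=42)
        np.testing.assert_array_equal(
            cross_validate(X, y, groups, cfg),
            cross_validate(X, y, groups, cfg),
        )

    def test_curve_values_non_negative_finite(self, rng):
        X = rng.normal(size=(48, 20))
        y = rng.normal(size=48)
        groups = np.repeat(np.arange(8), 6)
        curve = cross_validate(X, y, groups, CVConfig(folds=4, max_lv=6))
        assert np.all(np.isfinite(curve)) and np.all(curve >= 0)

    def test_fewer_groups_than_folds_rejected(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        groups = np.repeat([0, 1, 2], 4)
        with pytest.raises(ValueError, match="groups"):
            cross_validate(X, y, groups, CVConfig(folds=5))

    def test_fold_leaving_under_two_training_groups_rejected(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        groups = np.repeat([0, 1], 6)
        with pytest.raises(ValueError):
            cross_validate(X, y, groups, CVConfig(folds=2, max_lv=2))


class TestLVSelection:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([5.0, 2.0, 1.0, 1.001, 0.999], 3),  # within 1% of the minimum
            ([9.0, 5.0, 2.0, 1.0], 4),           # strictly decreasing, big gaps
            ([3.0], 1),                          # single entry
            ([2.0, 2.0, 2.0], 1),                # ties resolve to smaller LV
        ],
    )
    def test_parsimony_rule(self, curve, expected):
        assert select_latent_variables(np.array(curve), tol=0.01) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_latent_variables(np.array([]))

    def test_parsimony_refuses_overfitting_on_flat_curves(self):
        # a signal-poor analyte yields a flat, noisy RMSECV curve: raw argmin
        # chases the noise while the tolerance rule stays at one component
        flat = np.array([1.0, 0.999, 1.001, 0.9985, 0.998])
        assert select_latent_variables(flat, tol=0.0) == 5
        assert select_latent_variables(flat, tol=0.01) == 1


class TestSplit:
    def _batched_set(self, rng, n_batches=10, per_batch=10):
        X = rng.normal(size=(n_batches * per_batch, 5))
        batches = np.repeat([f"b{i}" for i in range(n_batches)], per_batch)
        return _as_set(X, batch=list(batches))

    def test_equal_batches_split_exactly(self, rng):
        sset = self._batched_set(rng)
        train, test = split_train_test(sset, 0.7, seed=0)
        assert train.n_samples == 70
        assert test.n_samples == 30

    def test_seeding_controls_assignment(self, rng):
        sset = self._batched_set(rng)
        t1, _ = split_train_test(sset, 0.7, seed=1)
        t2, _ = split_train_test(sset, 0.7, seed=1)
        t3, _ = split_train_test(sset, 0.7, seed=99)
        assert set(t1.references.batch_id) == set(t2.references.batch_id)
        assert set(t1.references.batch_id) != set(t3.references.batch_id)

    def test_batches_disjoint_and_exhaustive(self, rng):
        sset = self._batched_set(rng, n_batches=7, per_batch=3)
        train, test = split_train_test(sset, 0.7, seed=5)
        tb = set(train.references.batch_id)
        eb = set(test.references.batch_id)
        assert tb.isdisjoint(eb)
        assert tb | eb == set(sset.references.batch_id)

    def test_invalid_fraction_rejected(self, rng):
        sset = self._batched_set(rng)
        for frac in (0.0, 1.0, -0.3, 2.0):
            with pytest.raises(ValueError):
                split_train_test(sset, frac, seed=0)

    def test_stratified_split_keeps_every_stratum_in_training(self, rng):
        X = rng.normal(size=(40, 5))
        batches = np.repeat([f"b{i}" for i in range(8)], 5)
        sites = np.repeat(["s1", "s1", "s1", "s1", "s2", "s2", "s2", "s2"], 5)
        sset = _as_set(X, batch=list(batches))
        sset.references["site_id"] = sites
        train, _ = split_train_test(sset, 0.7, seed=0, stratify_key="site_id")
        assert set(train.references.site_id) == {"s1", "s2"}


class TestSerialization:
    def test_round_trip_is_bit_identical(self, rng, tmp_path):
        X = rng.normal(size=(25, 12))
        y = X @ rng.normal(size=12)
        model = fit_pls(X, y, 4, analyte="glucose", fingerprint="fp",
                        grid=np.arange(12.0), rmsecv=np.array([3.0, 1.0]))
        path = tmp_path / "model.json"
        model.save(path)
        back = PLSModel.load(path)
        np.testing.assert_array_equal(model.coef, back.coef)
        np.testing.assert_array_equal(model.x_mean, back.x_mean)
        np.testing.assert_array_equal(
            model.predict_matrix(X), back.predict_matrix(X))
        assert back.analyte == "glucose" and back.n_lv == 4
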