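"""PLS1 engine: oracle equivalences, cross-validation, selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import gazestate as gs
from gazestate.errors import InsufficientDataError, SchemaError
from gazestate.pls import loo_msep, msep, select_components, select_indicators


def standardized(X):
    X = np.asarray(X, dtype=float)
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


class TestMsep:
    def test_zero_when_equal(self):
        assert msep([1.0, -1.0], [1.0, -1.0]) == 0.0

    def test_arithmetic(self):
        assert msep([1.0, -1.0], [0.0, 0.0]) == 1.0

    def test_matches_direct_computation(self, rng):
        y = rng.normal(size=50)
        yhat = rng.normal(size=50)
        assert msep(y, yhat) == pytest.approx(float(np.sum((y - yhat) ** 2) / 50))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            msep([1.0], [1.0, 2.0])


class TestFitPls1:
    def test_single_column_equal_to_response(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        X = standardized(y.reshape(-1, 1))
        model = gs.fit_pls1(X, y, 1)
        pred = gs.predict_scores(model, X)
        assert np.allclose(pred, y, atol=1e-12)
        assert msep(y, pred) < 1e-24

    def test_full_rank_equals_ols(self, rng):
        """With as many components as columns, PLS coefficients coincide
        with the closed-form normal-equations solution."""
        X = standardized(rng.normal(size=(6, 3)))
        y = rng.normal(size=6)
        model = gs.fit_pls1(X, y, 3)
        A = np.column_stack([np.ones(6), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.max(np.abs(model.coefficients.to_numpy() - beta[1:])) < 1e-8
        assert model.intercept == pytest.approx(beta[0])

    def test_orthonormal_single_component_proportional_to_xty(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(8, 3)))
        y = rng.normal(size=8)
        model = gs.fit_pls1(Q, y, 1)
        xty = Q.T @ (y - y.mean())
        ratio = model.coefficients.to_numpy() / xty
        assert np.allclose(ratio, ratio[0])

    @pytest.mark.parametrize("ncomp", [1, 2, 3])
    def test_matches_reference_implementation(self, rng, ncomp):
        """Coefficients agree with an established PLS implementation."""
        X = standardized(rng.normal(size=(12, 8)))
        y = rng.normal(size=12)
        model = gs.fit_pls1(X, y, ncomp)
        sk = PLSRegression(n_components=ncomp, scale=False).fit(X, y)
        assert np.allclose(model.coefficients.to_numpy(), sk.coef_.ravel(), atol=1e-10)

    def test_score_orthogonality(self, rng):
        X = standardized(rng.normal(size=(15, 10)))
        y = rng.normal(size=15)
        T = gs.fit_pls1(X, y, 5).scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_scale_equivariance(self, rng):
        X = standardized(rng.normal(size=(10, 4)))
        y = rng.normal(size=10)
        p1 = gs.predict_scores(gs.fit_pls1(X, y, 2), X)
        p3 = gs.predict_scores(gs.fit_pls1(X, 3.0 * y, 2), X)
        assert np.allclose(p3, 3.0 * p1, atol=1e-10)

    def test_deterministic(self, rng):
        X = standardized(rng.normal(size=(9, 5)))
        y = rng.normal(size=9)
        a = gs.fit_pls1(X, y, 3)
        b = gs.fit_pls1(X, y, 3)
        assert np.array_equal(a.coefficients.to_numpy(), b.coefficients.to_numpy())

    def test_early_stop_on_exhausted_covariance(self):
        X = standardized(np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]]))
        y = np.ones(4)  # centred response is zero: nothing to extract
        model = gs.fit_pls1(X, y, 2)
        assert model.n_components == 0
        assert np.allclose(gs.predict_scores(model, X), 1.0)

    def test_ncomp_out_of_range(self, rng):
        X = standardized(rng.normal(size=(5, 3)))
        with pytest.raises(InsufficientDataError):
            gs.fit_pls1(X, rng.normal(size=5), 5)


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, small_cohort):
        sets = [gs.indicator_set(t) for t in small_cohort.sequences]
        dm = gs.standardize(gs.assemble_design(sets, "S"))
        y = np.array([t.condition for t in small_cohort.sequences], float)
        model = gs.fit_pls1(dm, y, 2)
        raw = gs.assemble_design(sets, "S").values
        p_raw = gs.predict_scores(model, raw)  # standardised via stored params
        p_std = model.intercept + dm.values.to_numpy() @ model.coefficients.to_numpy()
        assert np.allclose(p_raw, p_std, atol=1e-10)

    def test_column_permutation_invariance(self, small_cohort, rng):
        sets = [gs.indicator_set(t) for t in small_cohort.sequences]
        dm = gs.standardize(gs.assemble_design(sets, "S"))
        y = np.array([t.condition for t in small_cohort.sequences], float)
        model = gs.fit_pls1(dm, y, 2)
        raw = gs.assemble_design(sets, "S").values
        shuffled = raw[list(rng.permutation(raw.columns))]
        assert np.allclose(
            gs.predict_scores(model, raw), gs.predict_scores(model, shuffled)
        )

    def test_missing_selected_indicator(self, small_cohort):
        sets = [gs.indicator_set(t) for t in small_cohort.sequences]
        dm = gs.standardize(gs.assemble_design(sets, "S"))
        y = np.array([t.condition for t in small_cohort.sequences], float)
        model = gs.fit_pls1(dm, y, 1)
        with pytest.raises(SchemaError):
            gs.predict_scores(model, gs.assemble_design(sets, "S").values.iloc[:, :3])


def _brute_force_loo(X, y, ncomp):
    """Independent fold loop: manual standardisation per fold plus an
    established PLS implementation."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        m = np.ones(n, bool)
        m[i] = False
        mu, sd = X[m].mean(0), X[m].std(0, ddof=1)
        Z = (X[m] - mu) / sd
        sk = PLSRegression(n_components=ncomp, scale=False).fit(Z, y[m])
        preds[i] = sk.predict(((X[i] - mu) / sd).reshape(1, -1)).ravel()[0]
    return float(np.mean((y - preds) ** 2))


class TestLooMsep:
    def test_noiseless_linear_recovery(self):
        y = np.array([2.0, -1.0, 0.5, -2.0, 1.0, -0.5])
        X = y.reshape(-1, 1) * 4.0 + 7.0
        report = loo_msep(X, y, max_ncomp=1)
        assert report.msep_by_ncomp[1] < 1e-10
        assert report.chosen_ncomp == 1

    @pytest.mark.parametrize("ncomp", [1, 2])
    def test_matches_brute_force_fold_loop(self, rng, ncomp):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        report = loo_msep(X, y, max_ncomp=3)
        assert report.msep_by_ncomp[ncomp] == pytest.approx(
            _brute_force_loo(X, y, ncomp), abs=1e-8
        )

    def test_noise_floor_when_y_independent_of_x(self):
        """Across 100 seeded replicates, LOO MSEP of pure noise stays above
        half the response variance."""
        mseps, variances = [], []
        for s in range(100):
            r = np.random.default_rng(s)
            X = r.normal(size=(24, 5))
            y = r.normal(size=24)
            mseps.append(loo_msep(X, y, max_ncomp=3).msep)
            variances.append(y.var(ddof=1))
        assert np.mean(mseps) >= 0.5 * np.mean(variances)

    def test_select_components_is_argmin(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        report = loo_msep(X, y, max_ncomp=4)
        k = select_components(X, y, max_ncomp=4)
        assert report.msep_by_ncomp[k] == min(report.msep_by_ncomp.values())
        ties = [c for c, v in report.msep_by_ncomp.items()
                if v == report.msep_by_ncomp[k]]
        assert k == min(ties)


class TestSelectIndicators:
    def test_true_column_always_retained(self):
        """A column identical to the response survives elimination against
        20 pure-noise columns in every one of 20 seeded replicates."""
        kept = 0
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            y = np.where(np.arange(24) % 2 == 0, 1.0, -1.0)
            X = pd.DataFrame(
                r.normal(size=(24, 21)), columns=[f"n{i}" for i in range(21)]
            )
            X["signal"] = y
            sel, _, _ = select_indicators(X, y)
            kept += "signal" in sel
        assert kept == 20

    def test_identical_columns_leave_one_survivor(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        X = pd.DataFrame({f"c{i}": y * 2.0 for i in range(4)})
        sel, model, _ = select_indicators(X, y)
        assert sel == ["c0"]  # ties drop the later canonical column

    def test_selection_never_worse_than_full_model(self, rng):
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(12, 8)))
            X.columns = [f"x{i}" for i in range(8)]
            y = X["x0"].to_numpy() + 0.5 * rng.normal(size=12)
            sel, _, report = select_indicators(X, y)
            assert report.msep <= loo_msep(X, y).msep + 1e-12

    def test_vip_strategy_returns_valid_subset(self, small_cohort):
        sets = [gs.indicator_set(t) for t in small_cohort.sequences]
        dm = gs.assemble_design(sets, "S")
        y = np.array([t.condition for t in small_cohort.sequences], float)
        sel, model, report = select_indicators(dm, y, strategy="vip")
        assert set(sel) <= set(dm.columns)
        assert list(model.selected) == sel


class TestModelSerialisation:
    def test_json_round_trip(self, small_cohort, tmp_path):
        from gazestate.io import load_model, save_model

        sets = [gs.indicator_set(t) for t in small_cohort.sequences]
        dm = gs.standardize(gs.assemble_design(sets, "S"))
        y = np.array([t.condition for t in small_cohort.sequences], float)
        model = gs.fit_pls1(dm, y, 2)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded, _ = load_model(path)
        raw = gs.assemble_design(sets, "S").values
        assert np.allclose(
            gs.predict_scores(model, raw), gs.predict_scores(loaded, raw), atol=1e-12
        )
        save_model(loaded, tmp_path / "again.json")
        assert (tmp_path / "again.json").read_text() == path.read_text()
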