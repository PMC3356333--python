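"""Cross-validated best-subset, sign-constrained FD weighting, joint models."""

import numpy as np
import pandas as pd
import pytest

import traitbef as tb
from traitbef.model_selection import SignConstraint, _constrained_ls

from conftest import random_predictors


def explicit_press_loop(X, y, refit):
    """Independent oracle: leave each row out, refit, predict it."""
    n = len(y)
    press = 0.0
    for i in range(n):
        m = np.arange(n) != i
        predict = refit(X[m], y[m])
        press += (y[i] - predict(X[i])) ** 2
    return press


def ols_refit(Xtr, ytr):
    Z = np.column_stack([np.ones(len(ytr)), Xtr])
    beta, *_ = np.linalg.lstsq(Z, ytr, rcond=None)
    return lambda x: float(beta[0] + x @ beta[1:])


class TestLoocvPress:
    def test_perfect_linear_fit_has_zero_press(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(25, 1))
        y = 2.0 + 3.0 * x[:, 0]
        assert tb.loocv_press(x, y) == pytest.approx(0.0, abs=1e-18)

    def test_hat_shortcut_equals_explicit_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X = rng.normal(size=(30, 4))
            y = rng.normal(size=30)
            got = tb.loocv_press(X, y)
            want = explicit_press_loop(X, y, ols_refit)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-8)

    def test_constrained_press_order_invariant(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=(30, 2)), rng.gamma(2, 1, size=(30, 3))])
        y = rng.normal(size=30)
        con = SignConstraint(sign=1, n_unconstrained=2)
        a = tb.loocv_press(X, y, con)
        perm = rng.permutation(30)
        b = tb.loocv_press(X[perm], y[perm], con)
        assert a == pytest.approx(b, rel=1e-9)

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="n plots"):
            tb.loocv_press(rng.normal(size=(10, 9)), rng.normal(size=10))


class TestModelA:
    def test_recovers_sparse_truth(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            pm = random_predictors(rng)
            y = (
                3.0 * pm.cwm["t03"].to_numpy()
                - 2.0 * pm.cwm["t11"].to_numpy()
                + rng.normal(0, 0.3, 66)
            )
            best, _ = tb.fit_model_A(pm, y, max_subset_size=3)
            hits += set(best.spec.cwm_traits) == {"t03", "t11"}
        assert hits >= 27  # >= 90%

    def test_constant_response_selects_intercept_only(self):
        rng = np.random.default_rng(5)
        pm = random_predictors(rng)
        best, _ = tb.fit_model_A(pm, np.full(66, 7.0), max_subset_size=3)
        assert best.spec.cwm_traits == ()
        assert best.r2 == 0.0

    def test_duplicate_columns_tie_break(self):
        rng = np.random.default_rng(6)
        pm = random_predictors(rng, p=4)
        pm.cwm["t01"] = pm.cwm["t00"]  # duplicated predictor column
        y = 2.0 * pm.cwm["t00"].to_numpy() + rng.normal(0, 0.1, 66)
        best, ranked = tb.fit_model_A(pm, y, max_subset_size=2)
        # smaller subset wins over {t00, t01}; lexicographic order picks t00
        assert best.spec.cwm_traits == ("t00",)

    def test_overfitting_guard(self):
        rng = np.random.default_rng(7)
        pm = random_predictors(rng, n=14)
        with pytest.raises(ValueError, match="overfitting"):
            tb.fit_model_A(pm, rng.normal(size=14), max_subset_size=7)

    def test_top_list_sorted_by_press(self):
        rng = np.random.default_rng(8)
        pm = random_predictors(rng, p=6)
        y = pm.cwm["t00"].to_numpy() + rng.normal(0, 0.5, 66)
        _, ranked = tb.fit_model_A(pm, y, max_subset_size=2)
        presses = [f.loocv_press for f in ranked]
        assert presses == sorted(presses)


class TestModelB:
    def test_recovers_positive_fd_trait(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(200 + rep)
            pm = random_predictors(rng)
            y = 4.0 * pm.fd["t07"].to_numpy() + rng.normal(0, 0.3, 66)
            best, _ = tb.fit_model_B(pm, y, max_subset_size=4)
            ok = (
                best.fd_sign == 1
                and best.fd_weights.get("t07", 0.0) >= 0.9
            )
            hits += ok
        assert hits >= 27

    def test_recovers_negative_fd_trait(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(300 + rep)
            pm = random_predictors(rng)
            y = -4.0 * pm.fd["t07"].to_numpy() + rng.normal(0, 0.3, 66)
            best, _ = tb.fit_model_B(pm, y, max_subset_size=4)
            hits += best.fd_sign == -1 and best.fd_weights.get("t07", 0.0) >= 0.9
        assert hits >= 27

    def test_qp_matches_dense_grid_search(self):
        rng = np.random.default_rng(9)
        n = 40
        F = rng.gamma(2, 1, size=(n, 2))
        y = 1.0 + 2.0 * F[:, 0] + 0.5 * F[:, 1] + rng.normal(0, 0.2, n)
        a, _, c = _constrained_ls(None, F, y, sign=1)

        def sse(c1, c2):
            r = y - (y - F @ [c1, c2]).mean() - F @ [c1, c2]
            return float(r @ r)

        C = 2.0 * max(c.max(), 1.0)
        grid = np.linspace(0, C, 201)
        best_grid = min(
            (sse(c1, c2), c1, c2) for c1 in grid for c2 in grid
        )
        assert abs(c[0] - best_grid[1]) <= 1e-3 * C + C / 200
        assert abs(c[1] - best_grid[2]) <= 1e-3 * C + C / 200
        assert sse(c[0], c[1]) <= best_grid[0] + 1e-9

    def test_no_signal_returns_intercept_only_with_warning(self):
        rng = np.random.default_rng(10)
        pm = random_predictors(rng, n=30, p=2)
        # constant response: neither sign selects any trait
        with pytest.warns(UserWarning, match="intercept-only"):
            best, _ = tb.fit_model_B(pm, np.full(30, 5.0), max_subset_size=2)
        assert best.spec.fd_traits == ()
        assert best.intercept == pytest.approx(5.0)

    def test_weight_normalization_and_kkt(self):
        rng = np.random.default_rng(11)
        pm = random_predictors(rng)
        y = 2 * pm.fd["t01"].to_numpy() + pm.fd["t02"].to_numpy() + rng.normal(0, 0.4, 66)
        best, _ = tb.fit_model_B(pm, y, max_subset_size=5)
        w = np.array(list(best.fd_weights.values()))
        assert np.all(w >= -1e-10)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        assert best.fd_scale > 0

    def test_active_set_respects_cap(self):
        rng = np.random.default_rng(12)
        pm = random_predictors(rng)
        y = pm.fd.iloc[:, :6].sum(axis=1).to_numpy() + rng.normal(0, 0.1, 66)
        best, _ = tb.fit_model_B(pm, y, max_subset_size=3)
        assert len(best.spec.fd_traits) <= 3


class TestModelC:
    def test_joint_recovery(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(400 + rep)
            pm = random_predictors(rng)
            y = (
                3.0 * pm.cwm["t04"].to_numpy()
                + 2.0 * pm.fd["t09"].to_numpy()
                + rng.normal(0, 0.3, 66)
            )
            best, _ = tb.fit_model_C(pm, y, max_subset_size=3)
            hits += (
                "t04" in best.spec.cwm_traits
                and "t09" in best.spec.fd_traits
                and best.spec.fd_sign == "positive"
            )
        assert hits >= 24  # >= 80%

    def test_cwm_only_truth_selects_no_fd(self):
        none_count = 0
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            pm = random_predictors(rng)
            y = 3.0 * pm.cwm["t02"].to_numpy() + rng.normal(0, 0.3, 66)
            best, _ = tb.fit_model_C(pm, y, max_subset_size=3)
            none_count += best.spec.fd_sign == "none"
        assert none_count >= 11  # majority of replicates

    def test_zero_fd_candidates_reduce_to_ols(self):
        rng = np.random.default_rng(13)
        pm = random_predictors(rng, p=5)
        pm.fd.iloc[:, :] = 0.0  # no usable FD variation
        y = 2.0 * pm.cwm["t01"].to_numpy() + rng.normal(0, 0.2, 66)
        bestC, _ = tb.fit_model_C(pm, y, max_subset_size=2)
        bestA, _ = tb.fit_model_A(pm, y, max_subset_size=2)
        assert bestC.spec.cwm_traits == bestA.spec.cwm_traits
        assert bestC.spec.fd_traits == ()
        assert bestC.r2 == pytest.approx(bestA.r2, abs=1e-12)
        for tr in bestA.cwm_coefficients:
            assert bestC.cwm_coefficients[tr] == pytest.approx(
                bestA.cwm_coefficients[tr], rel=1e-10
            )

    def test_sse_nesting_of_winner(self, predictor_matrix, community_biomass):
        best, _ = tb.fit_model_C(predictor_matrix, community_biomass, max_subset_size=4)
        if best.spec.fd_traits:
            # refit the same CWM subset without FD: SSE must not decrease
            X = predictor_matrix.cwm[list(best.spec.cwm_traits)].to_numpy()
            Z = np.column_stack([np.ones(len(community_biomass)), X])
            beta, *_ = np.linalg.lstsq(Z, community_biomass, rcond=None)
            sse_a = float(np.sum((community_biomass - Z @ beta) ** 2))
            yhat = best.predict(predictor_matrix)
            sse_c = float(np.sum((community_biomass - yhat) ** 2))
            assert sse_c <= sse_a + 1e-6 * sse_a
        assert best.r2 >= 0

    def test_replacement_diagnostic_structure(self, predictor_matrix, community_biomass):
        _, ranked = tb.fit_model_C(predictor_matrix, community_biomass, max_subset_size=4)
        diag = tb.replacement_correlations(ranked, predictor_matrix)
        assert set(diag.columns) == {"model_rank", "dropped", "replacement", "corr_rank"}
        if len(diag):
            assert (diag["corr_rank"] >= 1).all()


class TestPartialR2:
    def test_null_fd_part_near_zero(self):
        small = 0
        for rep in range(20):
            rng = np.random.default_rng(600 + rep)
            pm = random_predictors(rng)
            y = 3.0 * pm.cwm["t00"].to_numpy() + rng.normal(0, 1.0, 66)
            fit = tb.ModelFit(
                spec=tb.ModelSpec("C", ("t00",), ("t05",), "positive", 3),
                intercept=0.0,
                cwm_coefficients={"t00": 3.0},
                fd_weights={"t05": 1.0},
                fd_scale=0.0,
                fd_sign=1,
                r2=0.5,
                loocv_press=1.0,
            )
            _, pr_fd = tb.partial_r2(fit, pm, y)
            small += pr_fd < 0.05
        assert small >= 18

    def test_orthogonal_groups_sum_to_joint(self):
        rng = np.random.default_rng(14)
        n = 2000
        names = ["a", "b"]
        cwm = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        fd = pd.DataFrame({"a": rng.gamma(2, 1, n), "b": rng.gamma(2, 1, n)})
        pm = tb.PredictorMatrix(
            plot_ids=[str(i) for i in range(n)],
            cwm=cwm,
            fd=fd,
            trait_abbrevs=names,
        )
        y = 2.0 * cwm["a"].to_numpy() + 1.5 * fd["b"].to_numpy() + rng.normal(0, 1, n)
        fit = tb.ModelFit(
            spec=tb.ModelSpec("C", ("a",), ("b",), "positive", 2),
            intercept=0.0,
            cwm_coefficients={"a": 2.0},
            fd_weights={"b": 1.0},
            fd_scale=1.5,
            fd_sign=1,
            r2=0.8,
            loocv_press=1.0,
        )
        pr_cwm, pr_fd = tb.partial_r2(fit, pm, y)
        Z = np.column_stack([np.ones(n), cwm["a"], fd["b"]])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        sse = float(np.sum((y - Z @ beta) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        joint = 1 - sse / sst
        assert pr_cwm + pr_fd == pytest.approx(joint, abs=0.02)

    def test_empty_group_reports_zero(self):
        rng = np.random.default_rng(15)
        pm = random_predictors(rng, n=30, p=3)
        fit = tb.ModelFit(
            spec=tb.ModelSpec("A", ("t00",), (), "none", 2),
            intercept=0.0,
            cwm_coefficients={"t00": 1.0},
            fd_weights={},
            fd_scale=0.0,
            fd_sign=0,
            r2=0.5,
            loocv_press=1.0,
        )
        y = pm.cwm["t00"].to_numpy() + rng.normal(0, 0.1, 30)
        pr_cwm, pr_fd = tb.partial_r2(fit, pm, y)
        assert pr_fd == 0.0
        assert pr_cwm > 0.9
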