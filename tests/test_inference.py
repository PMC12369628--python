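"""OLS + AICc machinery, forward selection, retrodiction and LOOCV."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleomet.inference import (
    PerfectFitError,
    _assemble_design,
    fit_linear_model,
    forward_select,
    gaussian_aicc,
    loocv,
    predict_point,
    retrodict,
    shapiro_wilk,
)
from paleomet.pem import build_pem, location_scores
from paleomet.phylo import GraftSpec, graft_fossil

from conftest import random_tree


def exhaustive_best_aicc(y, U, z):
    """Oracle: smallest AICc over all eigenvector subsets."""
    import itertools

    m, n = U.shape[1], len(y)
    best = math.inf
    for r in range(m + 1):
        for sub in itertools.combinations(range(1, m + 1), r):
            X, names = _assemble_design(U, z, sub)
            if n - (X.shape[1] + 1) - 1 <= 0:
                continue
            try:
                f = fit_linear_model(y, X, names, sub, True)
            except (PerfectFitError, ValueError):
                continue
            best = min(best, f.aicc)
    return best


class TestFitLinearModel:
    def test_aicc_matches_direct_formula(self, rng):
        """Oracle recomputation of AICc from the RSS at n=10, 3 coefs."""
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = fit_linear_model(y, X, ["intercept", "x1", "x2"])
        k = 3 + 1
        ll = -0.5 * n * (math.log(2 * math.pi * fit.rss / n) + 1)
        expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(expected, abs=1e-10)
        assert gaussian_aicc(fit.rss, n, 3) == pytest.approx(expected, abs=1e-10)

    def test_intercept_only(self, rng):
        y = rng.normal(size=12)
        fit = fit_linear_model(y, np.ones((12, 1)), ["intercept"])
        assert fit.adj_r2 == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.fitted, y.mean())
        assert math.isnan(fit.f_pvalue)

    def test_residuals_sum_to_zero_with_intercept(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = fit_linear_model(rng.normal(size=n), X, ["intercept", "x"])
        assert abs(fit.residuals.sum()) < 1e-8

    def test_perfect_fit_is_flagged_not_minus_inf(self, rng):
        n = 8
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        with pytest.raises(PerfectFitError):
            fit_linear_model(2.0 + 3.0 * x, X, ["intercept", "x"])

    def test_rank_deficiency_rejected(self, rng):
        n = 10
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            fit_linear_model(rng.normal(size=n), X, ["i", "a", "b"])

    def test_aicc_needs_degrees_of_freedom(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            gaussian_aicc(1.0, 5, 3)


class TestForwardSelect:
    def test_noiseless_recovers_exact_support(self, rng):
        t = random_tree(rng, 12)
        basis = build_pem(t)
        U = basis.U
        z = rng.normal(0, 1, U.shape[0])
        y = 2.0 * U[:, 0] - U[:, 2] + 0.5 * z
        fit = forward_select(y, basis, z)
        assert fit.indices == (1, 3)
        assert fit.rss < 1e-10

    def test_greedy_never_beats_exhaustive(self, rng):
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(8, 10)))
            basis = build_pem(t)
            U = basis.U[:, :6]
            n = U.shape[0]
            z = rng.normal(0, 1, n)
            beta = np.zeros(6)
            k = int(rng.integers(0, 3))
            beta[rng.choice(6, size=k, replace=False)] = rng.normal(0, 2, k)
            y = U @ beta + 0.5 * z + rng.normal(0, 0.3, n)
            greedy = forward_select(y, U, z)
            best = exhaustive_best_aicc(y, U, z)
            assert greedy.aicc >= best - 1e-8

    def test_selection_is_deterministic(self, rng):
        t = random_tree(rng, 15)
        basis = build_pem(t)
        z = rng.normal(0, 1, basis.n_tips)
        y = basis.U[:, 0] + 0.3 * z + rng.normal(0, 0.3, basis.n_tips)
        f1 = forward_select(y, basis, z)
        f2 = forward_select(y.copy(), basis, z.copy())
        assert f1.indices == f2.indices
        np.testing.assert_array_equal(f1.coef, f2.coef)

    def test_mismatched_lengths_rejected(self, rng):
        t = random_tree(rng, 8)
        basis = build_pem(t)
        with pytest.raises(ValueError):
            forward_select(np.zeros(basis.n_tips - 1), basis, None)


class TestRetrodict:
    def test_zero_distance_twin_predicts_its_fitted_value(self, rng):
        t = random_tree(rng, 10)
        basis = build_pem(t)
        z = rng.normal(0, 1, basis.n_tips)
        y = basis.U[:, 0] + 0.4 * z + rng.normal(0, 0.2, basis.n_tips)
        fit = forward_select(y, basis, z)
        twin_of = basis.tip_labels[4]
        g = graft_fossil(
            t, GraftSpec("TWIN", attach=twin_of, attach_time=0.0, stem_length=0.0)
        )
        scores = location_scores(basis, g, "TWIN")
        i = basis.tip_index(twin_of)
        pred = predict_point(fit, scores, z[i])
        assert pred == pytest.approx(fit.fitted[i], abs=1e-8)

    def test_back_transformed_interval_is_log_symmetric(self, rng):
        t = random_tree(rng, 10)
        basis = build_pem(t)
        z = rng.normal(0, 1, basis.n_tips)
        y = basis.U[:, 0] + 0.4 * z + rng.normal(0, 0.2, basis.n_tips)
        fit = forward_select(y, basis, z)
        r = retrodict(fit, rng.normal(0, 0.2, basis.n_eigenvectors), 0.0)
        assert math.log10(r.upper) - math.log10(r.point) == pytest.approx(
            math.log10(r.point) - math.log10(r.lower), abs=1e-10
        )
        assert r.lower < r.point < r.upper

    def test_prediction_interval_contains_confidence_interval(self, rng):
        t = random_tree(rng, 10)
        basis = build_pem(t)
        z = rng.normal(0, 1, basis.n_tips)
        y = basis.U[:, 0] + 0.4 * z + rng.normal(0, 0.2, basis.n_tips)
        fit = forward_select(y, basis, z)
        s = rng.normal(0, 0.2, basis.n_eigenvectors)
        ci = retrodict(fit, s, 0.0, kind="confidence")
        pi = retrodict(fit, s, 0.0, kind="prediction")
        pi_stem = retrodict(fit, s, 0.0, kind="prediction", stem_variance=0.05)
        assert ci.lower_log10 > pi.lower_log10 > pi_stem.lower_log10
        assert ci.upper_log10 < pi.upper_log10 < pi_stem.upper_log10

    def test_dropping_informative_eigenvector_never_narrows(self, rng):
        for _ in range(25):
            t = random_tree(rng, 12)
            basis = build_pem(t)
            U = basis.U
            n = U.shape[0]
            z = rng.normal(0, 1, n)
            y = 2 * U[:, 0] - 1.5 * U[:, 2] + 0.5 * z + rng.normal(0, 0.2, n)
            scores = rng.normal(0, 0.2, U.shape[1])
            Xf, nf = _assemble_design(U, z, (1, 3))
            full = fit_linear_model(y, Xf, nf, (1, 3), True)
            Xr, nr = _assemble_design(U, z, (3,))
            reduced = fit_linear_model(y, Xr, nr, (3,), True)
            wf = retrodict(full, scores, 0.1)
            wr = retrodict(reduced, scores, 0.1)
            assert (wr.upper_log10 - wr.lower_log10) >= (
                wf.upper_log10 - wf.lower_log10
            ) - 1e-12

    def test_coefficient_recovery_within_two_se(self, rng):
        """With known truth, estimates fall within 2 SE >= 93% of the time."""
        t = random_tree(rng, 20)
        basis = build_pem(t)
        U = basis.U
        n = U.shape[0]
        z = rng.normal(0, 1, n)
        truth = np.array([0.5, 2.0, -1.0, 0.5])  # intercept, V1, V3, z
        hits = total = 0
        for _ in range(300):
            y = truth[0] + truth[1] * U[:, 0] + truth[2] * U[:, 2] + truth[3] * z \
                + rng.normal(0, 0.3, n)
            X, names = _assemble_design(U, z, (1, 3))
            fit = fit_linear_model(y, X, names, (1, 3), True)
            se = np.sqrt(fit.sigma2 * np.diag(fit.xtx_inv))
            hits += int(np.sum(np.abs(fit.coef - truth) <= 2 * se))
            total += len(truth)
        assert hits / total >= 0.93


class TestShapiroWilk:
    def test_w_bounded_by_one(self, rng):
        w, _ = shapiro_wilk(rng.normal(size=50))
        assert w <= 1.0

    def test_rejection_rates(self, rng):
        normal_rej = skew_rej = 0
        reps = 400
        for _ in range(reps):
            _, p = shapiro_wilk(rng.normal(size=50))
            normal_rej += p < 0.05
            _, p = shapiro_wilk(rng.exponential(size=50))
            skew_rej += p < 0.05
        assert 0.02 <= normal_rej / reps <= 0.09
        assert skew_rej / reps > 0.90

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk(np.ones(10))


class TestLoocv:
    def _traits_frame(self, tree, y, z):
        return pd.DataFrame(
            {"log_mmr_mi": y, "log_q": z},
            index=pd.Index(tree.tip_labels(), name="taxon"),
        )

    def test_exact_function_of_copredictor_degenerates_to_p_one(self, rng):
        t = random_tree(rng, 12)
        z = rng.normal(0, 1, t.n_tips)
        df = self._traits_frame(t, 1.5 + 2.0 * z, z)
        report = loocv(df, t)
        assert report.zero_variance
        assert report.pvalue == 1.0
        assert all(f.ok for f in report.folds)
        preds = np.array([f.predicted for f in report.folds])
        obs = np.array([f.observed for f in report.folds])
        np.testing.assert_allclose(preds, obs, atol=1e-8)

    def test_one_row_per_extant_taxon_and_valid_pvalues(self, rng):
        t = random_tree(rng, 14)
        basis = build_pem(t)
        z = rng.normal(0, 1, t.n_tips)
        order = basis.tip_labels
        y = basis.U[:, 0] + 0.5 * z[[order.index(l) for l in t.tip_labels()]] \
            + rng.normal(0, 0.15, t.n_tips)
        df = self._traits_frame(t, y, z)
        report = loocv(df, t)
        assert len(report.folds) == t.n_tips
        assert 0.0 <= report.pvalue <= 1.0
        assert 0.0 <= report.shapiro_p <= 1.0
        frame = report.to_frame()
        assert set(frame["taxon"]) == set(t.tip_labels())

    def test_requires_ten_taxa(self, rng):
        t = random_tree(rng, 6)
        df = self._traits_frame(t, rng.normal(size=6), rng.normal(size=6))
        with pytest.raises(ValueError, match="at least 10"):
            loocv(df, t)
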