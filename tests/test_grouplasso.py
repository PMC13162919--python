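import numpy as np
import pytest

from fusesurv.cox import fit_cox
from fusesurv.grouplasso import (
    GroupStructure,
    compute_lambda_max,
    cv_select_lambda,
    default_lambda_grid,
    fit_grlasso_path,
    group_penalty,
    selection_frequency,
)
from fusesurv.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="module")
def toy_problem():
    """Well-conditioned 2-group toy problem with signal in group 0."""
    rng = np.random.default_rng(42)
    n = 120
    X = rng.normal(size=(n, 5))
    lp = X[:, 0] * 0.8 - X[:, 1] * 0.5
    T = rng.exponential(np.exp(-lp))
    C = rng.exponential(2 * T.mean(), size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    X = (X - X.mean(0)) / X.std(0)
    gs = GroupStructure(groups=["g0", "g1"], assignment=[0, 0, 1, 1, 1])
    return X, time, event, gs


class TestGroupPenalty:
    def test_zero_beta(self):
        gs = GroupStructure(groups=["a"], assignment=[0, 0])
        assert group_penalty(np.zeros(2), gs, 1.0) == 0.0

    def test_direct_evaluation(self):
        # group A: (3,4) w=sqrt2; group B: zeros w=sqrt3; lambda=0.5
        gs = GroupStructure(groups=["A", "B"], assignment=[0, 0, 1, 1, 1])
        val = group_penalty(np.array([3.0, 4.0, 0, 0, 0]), gs, 0.5)
        assert val == pytest.approx(0.5 * np.sqrt(2) * 5, abs=1e-12)
        assert val == pytest.approx(3.5355, abs=1e-4)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(0)
        gs = GroupStructure(groups=["a", "b"], assignment=[0, 1, 1])
        beta = rng.normal(size=3)
        assert group_penalty(2 * beta, gs, 0.7) == pytest.approx(
            2 * group_penalty(beta, gs, 0.7), abs=1e-12
        )

    def test_negative_lambda_rejected(self):
        gs = GroupStructure(groups=["a"], assignment=[0])
        with pytest.raises(ValueError):
            group_penalty(np.ones(1), gs, -0.1)

    def test_default_weights_sqrt_size(self):
        gs = GroupStructure(groups=["a", "b"], assignment=[0, 0, 0, 1])
        np.testing.assert_allclose(gs.weights, [np.sqrt(3), 1.0])


class TestLambdaMax:
    def test_all_zero_at_lambda_max(self, toy_problem):
        X, time, event, gs = toy_problem
        lam_max = compute_lambda_max(X, time, event, gs)
        path = fit_grlasso_path(
            X, time, event, gs, np.array([lam_max * 1.001, lam_max])
        )
        assert np.all(path.coefs == 0)

    def test_just_below_lambda_max_nonzero(self, toy_problem):
        X, time, event, gs = toy_problem
        lam_max = compute_lambda_max(X, time, event, gs)
        path = fit_grlasso_path(X, time, event, gs, np.array([lam_max * 0.95]))
        assert np.any(path.coefs != 0)

    def test_bisection_oracle(self, toy_problem):
        # smallest lambda on a fine grid whose fit is all-zero
        X, time, event, gs = toy_problem
        lam_max = compute_lambda_max(X, time, event, gs)
        grid = lam_max * np.linspace(1.2, 0.8, 41)
        path = fit_grlasso_path(X, time, event, gs, grid)
        nz = np.array([np.any(c != 0) for c in path.coefs])
        first_nz = grid[int(np.argmax(nz))]
        last_zero = grid[int(np.argmax(nz)) - 1]
        assert first_nz < lam_max <= last_zero * 1.0001

    def test_permuted_outcome_shrinks_lambda_max(self, toy_problem):
        X, time, event, gs = toy_problem
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(time))
        lam_signal = compute_lambda_max(X, time, event, gs)
        lam_null = np.mean(
            [
                compute_lambda_max(X, time[rng.permutation(len(time))],
                                   event[rng.permutation(len(time))], gs)
                for _ in range(5)
            ]
        )
        assert lam_null < lam_signal

    def test_duplicating_other_group_invariant(self, toy_problem):
        X, time, event, gs = toy_problem
        # duplicate group 1's features; group 0's gradient norm unchanged
        X2 = np.hstack([X, X[:, 2:5]])
        gs2 = GroupStructure(
            groups=["g0", "g1"],
            assignment=[0, 0, 1, 1, 1, 1, 1, 1],
            weights=[np.sqrt(2), np.sqrt(6)],
        )
        from fusesurv.grouplasso import _CoxData

        d1 = _CoxData(X, time, event)
        d2 = _CoxData(X2, time, event)
        _, g1 = d1.nll_grad(np.zeros(5))
        _, g2 = d2.nll_grad(np.zeros(8))
        assert np.linalg.norm(g1[:2]) == pytest.approx(
            np.linalg.norm(g2[:2]), abs=1e-12
        )


class TestPathFit:
    def test_lambda_zero_matches_newton_cox(self, toy_problem):
        X, time, event, gs = toy_problem
        lam_max = compute_lambda_max(X, time, event, gs)
        grid = np.r_[default_lambda_grid(lam_max, 10, 0.01), 0.0]
        path = fit_grlasso_path(X, time, event, gs, grid, tol=1e-8)
        fit = fit_cox(X, time, event)
        np.testing.assert_allclose(path.coefs[-1], fit.beta, atol=1e-4)

    def test_kkt_residuals_along_path(self, toy_problem):
        X, time, event, gs = toy_problem
        path = fit_grlasso_path(
            X, time, event, gs,
            default_lambda_grid(path_lambda_max(X, time, event, gs), 25, 0.01),
        )
        assert np.all(path.kkt_residuals < 1e-6)

    def test_group_aligned_sparsity(self, toy_problem):
        X, time, event, gs = toy_problem
        path = fit_grlasso_path(
            X, time, event, gs,
            default_lambda_grid(path_lambda_max(X, time, event, gs), 30, 0.01),
        )
        for coef in path.coefs:
            for g in range(gs.n_groups):
                bg = coef[gs.members(g)]
                assert np.all(bg == 0) or np.all(bg != 0)

    def test_warm_equals_cold(self, toy_problem):
        X, time, event, gs = toy_problem
        lam_max = compute_lambda_max(X, time, event, gs)
        grid = default_lambda_grid(lam_max, 12, 0.05)
        warm = fit_grlasso_path(X, time, event, gs, grid, tol=1e-8)
        for i in (4, 8, 11):
            cold = fit_grlasso_path(
                X, time, event, gs, np.array([grid[i]]), tol=1e-8
            )
            np.testing.assert_allclose(warm.coefs[i], cold.coefs[0], atol=1e-5)

    def test_signal_family_enters_first(self):
        spec = CohortSpec(
            n_patients=2000,
            family_sizes={"A": 6, "B": 5, "C": 4},
            true_group_effects={"B": [0.5, -0.4, 0.3, 0.3, -0.2]},
            clinical_effects=(0, 0, 0),
            demographic_effects=(0, 0),
            seed=13,
        )
        cohort = generate_cohort(spec)
        X = cohort.features()
        X = (X - X.mean(0)) / X.std(0)
        gs = GroupStructure.from_taxonomy(cohort.feature_names, cohort.taxonomy)
        lam_max = compute_lambda_max(X, cohort.time, cohort.event, gs)
        path = fit_grlasso_path(
            X, cohort.time, cohort.event, gs,
            default_lambda_grid(lam_max, 40, 0.05),
        )
        first_active = next(ag for ag in path.active_groups if ag)
        assert [gs.groups[g] for g in first_active] == ["B"]
        # oracle: B has the largest per-group weighted gradient norm at 0
        from fusesurv.grouplasso import _CoxData

        _, g0 = _CoxData(X, cohort.time, cohort.event).nll_grad(
            np.zeros(X.shape[1])
        )
        norms = {
            gs.groups[g]: np.linalg.norm(g0[gs.members(g)]) / gs.weights[g]
            for g in range(gs.n_groups)
        }
        assert max(norms, key=norms.get) == "B"

    def test_nonstandardised_warning(self, toy_problem, caplog):
        X, time, event, gs = toy_problem
        import logging

        with caplog.at_level(logging.WARNING, logger="fusesurv.grouplasso"):
            fit_grlasso_path(
                X * 3.0, time, event, gs,
                np.array([compute_lambda_max(X * 3, time, event, gs)]),
            )
        assert any("standardised" in r.message for r in caplog.records)


def path_lambda_max(X, time, event, gs):
    return compute_lambda_max(X, time, event, gs)


class TestCvSelect:
    def test_deterministic(self, toy_problem):
        X, time, event, gs = toy_problem
        a = cv_select_lambda(X, time, event, gs, seed=3)
        b = cv_select_lambda(X, time, event, gs, seed=3)
        assert a.selected_lambda == b.selected_lambda
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)

    def test_curve_recorded(self, toy_problem):
        X, time, event, gs = toy_problem
        path = cv_select_lambda(X, time, event, gs, seed=0)
        assert path.cv_mean.shape == path.lambdas.shape
        assert path.cv_se.shape == path.lambdas.shape
        assert path.selected_lambda == path.lambdas[path.selected_index]
        assert path.cv_mean[path.selected_index] == path.cv_mean.min()

    def test_one_se_rule_larger_lambda(self, toy_problem):
        X, time, event, gs = toy_problem
        lo = cv_select_lambda(X, time, event, gs, seed=0)
        hi = cv_select_lambda(X, time, event, gs, seed=0, one_se=True)
        assert hi.selected_lambda >= lo.selected_lambda

    def test_sparse_under_null_monte_carlo(self):
        # pure-noise features: <=1 active group at the selected lambda in
        # at least 80% of seeds
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 120
            X = rng.normal(size=(n, 9))
            X = (X - X.mean(0)) / X.std(0)
            T = rng.exponential(size=n)
            C = rng.exponential(2.0, size=n)
            time = np.minimum(T, C)
            event = (T <= C).astype(int)
            gs = GroupStructure(
                groups=["a", "b", "c"], assignment=[0] * 3 + [1] * 3 + [2] * 3
            )
            grid = default_lambda_grid(
                compute_lambda_max(X, time, event, gs), 30, 0.05
            )
            sel = cv_select_lambda(X, time, event, gs, seed=seed,
                                   lambda_grid=grid)
            if len(sel.active_groups[sel.selected_index]) <= 1:
                ok += 1
        assert ok >= 0.8 * n_seeds

    def test_zero_event_fold_error(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        time = rng.exponential(size=20)
        event = np.r_[np.ones(2, int), np.zeros(18, int)]
        gs = GroupStructure(groups=["a"], assignment=[0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cv_select_lambda(X, time, event, gs, k_folds=5, seed=0)

    def test_invalid_k(self, toy_problem):
        X, time, event, gs = toy_problem
        with pytest.raises(ValueError):
            cv_select_lambda(X, time, event, gs, k_folds=1)


class TestSelectionFrequency:
    def test_zero_everywhere(self):
        df = selection_frequency([np.zeros(3)] * 5, ["a", "b", "c"])
        assert (df["selection_frequency"] == 0).all()
        assert (df["coefficient"] == 0).all()

    def test_mean_and_count(self):
        coefs = [np.array([1.0, 0.0]), np.array([2.0, 0.0]),
                 np.array([3.0, 1.0]), np.array([4.0, 0.0]),
                 np.array([5.0, 0.0])]
        df = selection_frequency(coefs, ["x", "y"]).set_index("feature")
        assert df.loc["x", "selection_frequency"] == 5
        assert df.loc["x", "coefficient"] == pytest.approx(3.0)
        assert df.loc["y", "selection_frequency"] == 1
        assert df.loc["y", "coefficient"] == pytest.approx(0.2)

    def test_sorted_by_frequency_then_magnitude(self):
        coefs = [np.array([0.1, -2.0, 0.5])] * 5
        coefs[0] = np.array([0.1, -2.0, 0.0])
        df = selection_frequency(coefs, ["a", "b", "c"])
        assert list(df["feature"][:2]) == ["b", "a"]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            selection_frequency([], [])
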