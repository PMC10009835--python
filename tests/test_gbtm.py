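"""Censored-normal density, mixture likelihood and EM fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from champs_traj.gbtm import (
    GbtmParams,
    TrajectorySpec,
    child_group_loglik,
    cnorm_expected_observed,
    cnorm_log_density,
    count_parameters,
    fit_gbtm,
    mixture_loglik,
    posterior_probs,
    predict_trajectory,
    _design_matrix,
)


class TestCnormLogDensity:
    @pytest.mark.parametrize(
        "y, mu, sigma, expected",
        [
            (3.0, 3.0, 1.0, -0.9189385332),   # standard normal mode
            (0.0, 0.0, 1.0, np.log(0.5)),     # symmetric mass at the floor
            (0.0, 2.0, 1.0, -3.7831843337),   # log Phi(-2)
            (8.0, 8.0, 1.0, np.log(0.5)),     # symmetric mass at the ceiling
        ],
    )
    def test_reference_values(self, y, mu, sigma, expected):
        assert cnorm_log_density(y, mu, sigma) == pytest.approx(expected, abs=1e-9)

    def test_tail_stability(self):
        # stays finite and accurate deep in the tails
        val = cnorm_log_density(0.0, 40.0, 1.0)
        assert np.isfinite(val)
        assert val == pytest.approx(stats.norm.logcdf(-40.0), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cnorm_log_density(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            cnorm_log_density(9.0, 0.0, 1.0)

    def test_total_probability_is_one(self):
        # floor mass + ceiling mass + interior integral = 1
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu, sigma = rng.uniform(-2, 10), rng.uniform(0.3, 3)
            interior, _ = integrate.quad(
                lambda y: np.exp(cnorm_log_density(y, mu, sigma)), 1e-9, 8 - 1e-9
            )
            total = (
                np.exp(cnorm_log_density(0.0, mu, sigma))
                + np.exp(cnorm_log_density(8.0, mu, sigma))
                + interior
            )
            assert total == pytest.approx(1.0, abs=1e-7)


class TestCnormExpectedObserved:
    def test_degenerate_sigma_clips(self):
        assert cnorm_expected_observed(4.0, 0.0) == 4.0
        assert cnorm_expected_observed(-3.0, 0.0) == 0.0
        assert cnorm_expected_observed(11.0, 0.0) == 8.0

    def test_full_left_censoring(self):
        assert cnorm_expected_observed(-100.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_against_numerical_integration(self):
        # E[clip(X, 0, 8)] by quadrature on the latent normal
        rng = np.random.default_rng(1)
        for _ in range(50):
            mu, sigma = rng.uniform(-4, 12), rng.uniform(0.2, 4)
            num = (
                integrate.quad(
                    lambda x: x * stats.norm.pdf(x, mu, sigma), 0, 8, limit=200
                )[0]
                + 8 * stats.norm.sf(8, mu, sigma)
            )
            assert cnorm_expected_observed(mu, sigma) == pytest.approx(num, abs=1e-8)
        assert cnorm_expected_observed(8.0, 2.0) == pytest.approx(7.20213, abs=1e-5)

    def test_bounded(self):
        mu = np.linspace(-20, 20, 101)
        out = cnorm_expected_observed(mu, 3.0)
        assert np.all(out >= 0) and np.all(out <= 8)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            cnorm_expected_observed(1.0, -1.0)


class TestChildGroupLoglik:
    SPEC = TrajectorySpec(1, order=1, age_center=10.0, age_scale=5.0)

    def test_single_observation_equals_density(self):
        beta = np.array([2.0, 1.0])
        val = child_group_loglik([3.0], [10.0], beta, 1.0, self.SPEC)
        assert val == pytest.approx(cnorm_log_density(3.0, 2.0, 1.0))

    def test_missing_months_ignored(self):
        beta = np.array([3.0, 0.0])
        val = child_group_loglik([np.nan, 3.0, np.nan], [6.0, 10.0, 14.0], beta, 1.0, self.SPEC)
        assert val == pytest.approx(np.log(stats.norm.pdf(0.0)))

    def test_two_observation_sum(self):
        beta = np.array([2.0, 1.0])
        ages = [10.0, 15.0]  # scaled 0, 1 -> mu 2, 3
        expected = cnorm_log_density(1.0, 2.0, 0.8) + cnorm_log_density(4.0, 3.0, 0.8)
        assert child_group_loglik([1.0, 4.0], ages, beta, 0.8, self.SPEC) == pytest.approx(expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            child_group_loglik([np.nan], [10.0], np.array([0.0, 0.0]), 1.0, self.SPEC)


def _toy_panel():
    return pd.DataFrame({
        "child_id": ["a", "a", "b", "b", "b"],
        "age": [8.0, 12.0, 8.0, 10.0, 12.0],
        "y": [1.0, 2.0, 6.0, 8.0, 7.0],
    })


class TestMixtureLoglik:
    SPEC2 = TrajectorySpec(2, order=1, age_center=10.0, age_scale=2.0)

    def test_matches_brute_force(self):
        panel = _toy_panel()
        params = GbtmParams(
            beta=np.array([[1.5, 0.3], [7.0, 0.2]]), sigma=0.9, theta=np.array([0.4])
        )
        ll = mixture_loglik(params, panel, self.SPEC2)
        # direct summation per child over groups
        pi = params.pi
        total = 0.0
        for cid, sub in panel.groupby("child_id"):
            per_group = []
            for j in range(2):
                lij = sum(
                    cnorm_log_density(
                        y, params.beta[j, 0] + params.beta[j, 1] * (a - 10.0) / 2.0, 0.9
                    )
                    for y, a in zip(sub["y"], sub["age"])
                )
                per_group.append(pi[j] * np.exp(lij))
            total += np.log(sum(per_group))
        assert ll == pytest.approx(total, abs=1e-12)

    def test_single_group_collapses(self):
        panel = _toy_panel()
        spec1 = TrajectorySpec(1, order=1, age_center=10.0, age_scale=2.0)
        params = GbtmParams(beta=np.array([[3.0, 0.5]]), sigma=1.0, theta=np.zeros(0))
        ll = mixture_loglik(params, panel, spec1)
        direct = sum(
            cnorm_log_density(y, 3.0 + 0.5 * (a - 10) / 2.0, 1.0)
            for y, a in zip(panel["y"], panel["age"])
        )
        assert ll == pytest.approx(direct, abs=1e-12)

    def test_label_symmetry(self):
        # two identical groups at pi = (1/2, 1/2) match the one-group model
        panel = _toy_panel()
        beta = np.array([[3.0, 0.5], [3.0, 0.5]])
        params2 = GbtmParams(beta=beta, sigma=1.0, theta=np.array([0.0]))
        spec1 = TrajectorySpec(1, order=1, age_center=10.0, age_scale=2.0)
        params1 = GbtmParams(beta=beta[:1], sigma=1.0, theta=np.zeros(0))
        assert mixture_loglik(params2, panel, self.SPEC2) == pytest.approx(
            mixture_loglik(params1, panel, spec1), abs=1e-10
        )

    def test_label_permutation_invariance(self):
        panel = _toy_panel()
        params = GbtmParams(
            beta=np.array([[1.5, 0.3], [7.0, 0.2]]), sigma=0.9, theta=np.array([0.4])
        )
        pi = params.pi[::-1]
        swapped = GbtmParams(
            beta=params.beta[::-1].copy(), sigma=0.9,
            theta=np.array([np.log(pi[1] / pi[0])]),
        )
        assert mixture_loglik(params, panel, self.SPEC2) == pytest.approx(
            mixture_loglik(swapped, panel, self.SPEC2), abs=1e-10
        )

    def test_empty_panel_rejected(self):
        params = GbtmParams(beta=np.array([[1.0, 0.0]]), sigma=1.0, theta=np.zeros(0))
        with pytest.raises(ValueError):
            mixture_loglik(params, pd.DataFrame(columns=["child_id", "age", "y"]),
                           TrajectorySpec(1, order=1, age_center=0, age_scale=1))


class TestPosteriorProbs:
    SPEC2 = TrajectorySpec(2, order=0, age_center=10.0, age_scale=2.0)

    def test_equal_likelihood_gives_prior(self):
        panel = _toy_panel()
        params = GbtmParams(
            beta=np.array([[4.0], [4.0]]), sigma=1.0, theta=np.array([np.log(0.3 / 0.7)])
        )
        w = posterior_probs(params, panel, self.SPEC2)
        assert np.allclose(w.to_numpy(), [[0.7, 0.3], [0.7, 0.3]])

    def test_dominance(self):
        panel = pd.DataFrame({"child_id": ["a"] * 5, "age": [10.0] * 5, "y": [7.5] * 5})
        params = GbtmParams(
            beta=np.array([[0.5], [7.5]]), sigma=0.5, theta=np.array([0.0])
        )
        w = posterior_probs(params, panel, self.SPEC2)
        assert w.iloc[0, 1] > 1 - 1e-10

    def test_hand_bayes(self):
        panel = pd.DataFrame({"child_id": ["a"], "age": [10.0], "y": [3.0]})
        params = GbtmParams(
            beta=np.array([[2.0], [5.0]]), sigma=1.0, theta=np.array([np.log(0.4 / 0.6)])
        )
        l1 = np.exp(cnorm_log_density(3.0, 2.0, 1.0))
        l2 = np.exp(cnorm_log_density(3.0, 5.0, 1.0))
        expected = 0.6 * l1 / (0.6 * l1 + 0.4 * l2)
        w = posterior_probs(params, panel, self.SPEC2)
        assert w.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-10)


class TestCountParameters:
    @pytest.mark.parametrize("G, order, expected", [
        (1, 3, 5), (2, 3, 10), (5, 3, 25), (10, 3, 50), (2, 0, 4),
    ])
    def test_counts(self, G, order, expected):
        assert count_parameters(TrajectorySpec(G, order=order)) == expected

    def test_cubic_shared_sigma_is_5g(self):
        for G in range(1, 11):
            assert count_parameters(TrajectorySpec(G)) == 5 * G


class TestFitGbtm:
    def test_uncensored_single_group_matches_ols(self):
        # interior data only: the censored fit is ordinary ML regression
        rng = np.random.default_rng(5)
        ages = np.linspace(6, 16, 30)
        n = 40
        X_nat = np.vander((np.tile(ages, n) - 11) / 5, 3, increasing=True)
        coef = np.array([4.0, 0.8, -0.3])
        y = X_nat @ coef + rng.normal(0, 0.35, size=n * len(ages))
        y = np.clip(y, 0.1, 7.9)  # keep strictly inside the limits
        panel = pd.DataFrame({
            "child_id": np.repeat(np.arange(n), len(ages)),
            "age": np.tile(ages, n), "y": y,
        })
        fit = fit_gbtm(panel, TrajectorySpec(1, order=2), n_starts=1, seed=0)
        ols_coef, *_ = np.linalg.lstsq(X_nat, y, rcond=None)
        resid = y - X_nat @ ols_coef
        sigma_ml = np.sqrt(np.mean(resid**2))
        assert np.allclose(fit.params.beta[0], ols_coef, atol=1e-6)
        assert fit.params.sigma == pytest.approx(sigma_ml, abs=1e-6)

    def test_em_monotone_and_deterministic(self, small_panel):
        panel, _ = small_panel
        fit1 = fit_gbtm(panel, TrajectorySpec(3), n_starts=2, seed=11)
        fit2 = fit_gbtm(panel, TrajectorySpec(3), n_starts=2, seed=11)
        hist = np.array(fit1.loglik_history)
        assert np.all(np.diff(hist) >= -1e-7)
        assert fit1.loglik == fit2.loglik
        assert np.array_equal(fit1.assignment, fit2.assignment)
        assert np.allclose(fit1.params.beta, fit2.params.beta)

    def test_loglik_dominates_truth(self, small_panel, separated_3group_params):
        spec, params = separated_3group_params
        panel, _ = small_panel
        fit = fit_gbtm(panel, TrajectorySpec(3), n_starts=2, seed=0)
        assert fit.loglik >= mixture_loglik(params, panel, spec) - 1e-6

    def test_posterior_rows_sum_to_one(self, small_panel):
        panel, _ = small_panel
        fit = fit_gbtm(panel, TrajectorySpec(3), n_starts=1, seed=0)
        assert np.allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(fit.params.pi > 0)
        assert fit.params.pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(fit.assignment, fit.posterior.argmax(axis=1) + 1)

    def test_groups_labelled_by_increasing_trajectory(self, small_panel):
        panel, _ = small_panel
        fit = fit_gbtm(panel, TrajectorySpec(3), n_starts=1, seed=0)
        grid = np.linspace(6, 16, 10)
        curves = predict_trajectory(fit, grid, compute_bands=False)
        means = curves.groupby("group")["curve"].mean()
        assert means.is_monotonic_increasing

    def test_beats_dense_grid_on_tiny_instance(self):
        # 3 children, one-group intercept-only model: optimizer must beat a
        # dense parameter grid
        panel = pd.DataFrame({
            "child_id": ["a", "a", "b", "b", "c", "c"],
            "age": [8.0, 12.0] * 3,
            "y": [0.0, 1.0, 2.0, 3.5, 5.0, 8.0],
        })
        spec = TrajectorySpec(1, order=0)
        fit = fit_gbtm(panel, spec, n_starts=1, seed=0)
        best_grid = -np.inf
        for mu in np.linspace(-1, 9, 201):
            for sig in np.linspace(0.5, 5, 90):
                p = GbtmParams(beta=np.array([[mu]]), sigma=sig, theta=np.zeros(0))
                best_grid = max(best_grid, mixture_loglik(p, panel, fit.spec))
        assert fit.loglik >= best_grid - 1e-6


class TestPredictTrajectory:
    def test_noiseless_limit_is_clipped_polynomial(self, small_panel):
        panel, _ = small_panel
        fit = fit_gbtm(panel, TrajectorySpec(3), n_starts=1, seed=0)
        grid = np.linspace(6, 16, 9)
        curves = predict_trajectory(fit, grid, compute_bands=False)
        assert curves["curve"].between(0, 8).all()
        # curve equals the censored-normal expectation of the group polynomial
        t = fit.spec.scale_age(grid)
        mu1 = _design_matrix(t, 3) @ fit.params.beta[0]
        expected = cnorm_expected_observed(mu1, fit.params.sigma)
        got = curves[curves["group"] == 1].sort_values("age")["curve"].to_numpy()
        assert np.allclose(got, expected, atol=1e-12)

    def test_curve_matches_monte_carlo(self, separated_3group_params):
        spec, params = separated_3group_params
        rng = np.random.default_rng(3)
        age = 12.0
        mu = float((_design_matrix(spec.scale_age([age]), 3) @ params.beta[1])[0])
        sims = np.clip(rng.normal(mu, params.sigma, size=200_000), 0, 8)
        assert cnorm_expected_observed(mu, params.sigma) == pytest.approx(
            sims.mean(), abs=4 * sims.std() / np.sqrt(len(sims))
        )

    def test_bands_shrink_with_information(self, separated_3group_params):
        from champs_traj.synthetic_cohort import generate_model_faithful_panel

        spec, params = separated_3group_params
        ages = np.linspace(6, 16, 12)
        widths = []
        for n in (50, 400):
            panel, _ = generate_model_faithful_panel(params, spec, ages, n, seed=9)
            fit = fit_gbtm(panel, TrajectorySpec(3), n_starts=1, seed=0)
            curves = predict_trajectory(fit, np.linspace(7, 15, 5), _panel=panel)
            widths.append((curves["upper"] - curves["lower"]).mean())
        assert widths[1] < widths[0]
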