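"""Regression models, breakpoint search, model comparison, influence."""

import math

import numpy as np
import pytest

from biochromtox.regime import (
    GridSearch,
    SegmentedModel,
    compare_models,
    cooks_distance,
    fit_linear,
    fit_quadratic,
    fit_segmented,
    ftest_nested,
    split_regimes,
)


def normal_equation_ols(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


class TestLinearQuadratic:
    def test_exact_line(self):
        x = np.arange(5, dtype=float)
        fit = fit_linear(x, 2.0 + 3.0 * x)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.r2_adj == pytest.approx(1.0)

    def test_linear_matches_normal_equations(self, rng):
        x = rng.uniform(0, 10, 5)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, 5)
        fit = fit_linear(x, y)
        X = np.column_stack([np.ones_like(x), x])
        assert fit.coefficients == pytest.approx(normal_equation_ols(X, y))

    def test_linear_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 10, 12)
        y = 3.0 - 0.7 * x + rng.normal(0, 2, 12)
        fit = fit_linear(x, y)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.coefficients == pytest.approx(sm_fit.params)
        assert fit.rss == pytest.approx(sm_fit.ssr)
        assert fit.r2 == pytest.approx(sm_fit.rsquared)
        assert fit.r2_adj == pytest.approx(sm_fit.rsquared_adj)
        assert fit.aic == pytest.approx(sm_fit.aic + 2.0)  # sm omits the
        # variance parameter from the AIC penalty; only the constant differs

    def test_exact_quadratic_and_nesting(self, rng):
        x = np.linspace(-3, 3, 8)
        y = 1.0 - 2.0 * x + 0.5 * x**2
        qfit = fit_quadratic(x, y)
        assert qfit.rss == pytest.approx(0.0, abs=1e-16)
        y_noisy = y + rng.normal(0, 1, len(x))
        assert fit_quadratic(x, y_noisy).rss <= fit_linear(x, y_noisy).rss + 1e-12

    def test_quadratic_matches_normal_equations(self, rng):
        x = rng.uniform(-5, 5, 6)
        y = rng.normal(0, 3, 6)
        X = np.column_stack([np.ones_like(x), x, x**2])
        assert fit_quadratic(x, y).coefficients == pytest.approx(
            normal_equation_ols(X, y)
        )

    def test_degenerate_x_is_hard_error(self):
        with pytest.raises(ValueError):
            fit_linear(np.ones(5), np.arange(5.0))


class TestSegmented:
    def test_noiseless_hinge_recovered_exactly(self):
        x = np.arange(1.0, 21.0)
        y = 2.0 + 3.0 * x - 5.0 * np.maximum(x - 10.0, 0.0)
        fit = fit_segmented(x, y)
        assert fit.psi == pytest.approx(10.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)
        assert fit.beta1 == pytest.approx(3.0)
        assert fit.beta2 == pytest.approx(-5.0)
        assert fit.right_slope == pytest.approx(-2.0)

    def test_grid_search_matches_exhaustive_enumeration(self, rng):
        """Profile search equals a flat 0.001-resolution enumeration on
        random 8-point datasets, to within the refinement resolution."""
        for _ in range(10):
            x = np.sort(rng.uniform(0, 10, 8))
            y = rng.normal(0, 2, 8) + 0.5 * x
            model = SegmentedModel(y, x)
            fit = model.fit()
            exhaustive = model.profile_rss(np.arange(x.min(), x.max(), 0.001))
            # the profile search refines to 0.01 resolution; the flat
            # enumeration runs at 0.001, so allow that resolution gap
            assert fit.rss <= exhaustive.min() * (1 + 1e-3) + 1e-9
            assert abs(fit.psi - float(exhaustive.idxmin())) <= 0.011

    def test_segmented_never_worse_than_linear(self, rng):
        for _ in range(5):
            x = np.sort(rng.uniform(0, 50, 12))
            y = rng.normal(0, 5, 12)
            assert fit_segmented(x, y).rss <= fit_linear(x, y).rss + 1e-9

    def test_breakpoint_interior_and_sides_populated(self, rng):
        x = np.sort(rng.uniform(0, 10, 15))
        y = rng.normal(0, 1, 15)
        fit = fit_segmented(x, y)
        assert x.min() < fit.psi < x.max()
        assert (np.unique(x) < fit.psi).sum() >= 2
        assert (np.unique(x) > fit.psi).sum() >= 2

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 6"):
            fit_segmented(np.arange(5.0), np.arange(5.0))

    def test_parameter_recovery_on_synthetic_hinge(self, rng):
        """Median |psi_hat - psi_true| <= 1.0 over seeded noisy replicates
        (response scale 0-100, noise sd 5)."""
        errors = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            x = np.sort(r.uniform(30, 60, 30))
            y = 80 + 3.3 * (x - 47.0) - 11.3 * np.maximum(x - 47.0, 0.0)
            y = y + r.normal(0, 5, len(x))
            errors.append(abs(fit_segmented(x, y).psi - 47.0))
        assert np.median(errors) <= 1.0


class TestComparison:
    def test_identical_nested_models_give_f_zero_p_one(self):
        x = np.arange(8.0)
        y = 1.0 + x
        fit = fit_linear(x, y + np.sin(x))
        out = ftest_nested(fit, fit)
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_f_test_matches_hand_computed_sums_of_squares(self, rng):
        from scipy import stats

        x = rng.uniform(-3, 3, 15)
        y = 1.0 + x + 0.3 * x**2 + rng.normal(0, 1, 15)
        lin, quad = fit_linear(x, y), fit_quadratic(x, y)
        out = ftest_nested(lin, quad)
        F = ((lin.rss - quad.rss) / 1) / (quad.rss / (15 - 3))
        assert out["F"] == pytest.approx(F)
        assert out["p"] == pytest.approx(float(stats.f.sf(F, 1, 12)))

    def test_fits_on_different_data_rejected(self, rng):
        x = rng.uniform(0, 1, 10)
        with pytest.raises(ValueError, match="identical"):
            compare_models([
                fit_linear(x, rng.normal(size=10)),
                fit_linear(x, rng.normal(size=10)),
            ])

    def test_aic_bic_differ_only_in_penalty(self, rng):
        x = rng.uniform(0, 10, 14)
        y = rng.normal(0, 1, 14)
        for fit in (fit_linear(x, y), fit_quadratic(x, y), fit_segmented(x, y)):
            expected = (math.log(fit.n) - 2.0) * (fit.n_params + 1)
            assert fit.bic - fit.aic == pytest.approx(expected)

    def test_segmented_best_on_fixture(self, vaso_xy):
        x, y, _ = vaso_xy
        comp = compare_models(
            [fit_linear(x, y), fit_quadratic(x, y), fit_segmented(x, y)]
        )
        assert comp.best_by_aic == "segmented"
        assert comp.table.loc["segmented", "aic"] < comp.table.loc["linear", "aic"]
        assert comp.f_test["p"] < 0.05  # quadratic beats plain linear too


class TestInfluence:
    def leave_one_out_cooks(self, X, y):
        beta = normal_equation_ols(X, y)
        fitted = X @ beta
        n, p = X.shape
        s2 = float((y - fitted) @ (y - fitted)) / (n - p)
        out = []
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = normal_equation_ols(X[keep], y[keep])
            out.append(float((X @ beta - X @ beta_i) @ (X @ beta - X @ beta_i)) / (p * s2))
        return np.array(out)

    def test_cooks_matches_leave_one_out_definition(self, rng):
        x = rng.uniform(0, 10, 6)
        y = 1.0 + x + rng.normal(0, 1, 6)
        fit = fit_linear(x, y)
        report = cooks_distance(fit)
        oracle = self.leave_one_out_cooks(fit.design, fit.y)
        assert report.frame["cook_d"].to_numpy() == pytest.approx(oracle)

    def test_cooks_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 10, 12)
        y = 2.0 - x + rng.normal(0, 2, 12)
        fit = fit_linear(x, y)
        report = cooks_distance(fit)
        sm_d = sm.OLS(y, sm.add_constant(x)).fit().get_influence().cooks_distance[0]
        assert report.frame["cook_d"].to_numpy() == pytest.approx(sm_d)

    def test_leverages_sum_to_parameter_count(self, rng):
        x = rng.uniform(0, 10, 9)
        fit = fit_quadratic(x, rng.normal(size=9))
        report = cooks_distance(fit)
        assert report.frame["leverage"].sum() == pytest.approx(fit.design.shape[1])

    def test_balanced_symmetric_design_gives_equal_distances(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        d = cooks_distance(fit_linear(x, y)).frame["cook_d"]
        assert np.allclose(d, d.iloc[0])

    def test_threshold_is_four_over_n(self, vaso_xy):
        x, y, ids = vaso_xy
        report = cooks_distance(fit_segmented(x, y), index=ids)
        assert report.threshold == pytest.approx(4.0 / 13.0)
        assert round(report.threshold, 3) == 0.308


class TestSplitRegimes:
    def test_fixture_threshold_50(self, descriptors):
        low, high = split_regimes(descriptors.descriptors["chi_iam"], 50.0)
        assert sorted(high) == ["BPBP", "BPG", "BPP", "BPPH", "BPZ"]
        vaso_low = [c for c in low if c not in ("BPS_MAE", "BPF_22", "BPF_24", "BPFL", "BADGE")]
        assert len(vaso_low) == 8  # compounds with vasodilation data below 50

    def test_threshold_below_min_warns_with_empty_low_side(self, descriptors):
        x = descriptors.descriptors["chi_iam"]
        with pytest.warns(UserWarning, match="empty"):
            low, high = split_regimes(x, x.min() - 1.0)
        assert low == [] and len(high) == len(x.dropna())

    def test_subset_sizes_monotone_in_threshold(self, descriptors):
        x = descriptors.descriptors["chi_iam"]
        sizes = [len(split_regimes(x, t)[0]) for t in np.linspace(25, 60, 15)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_explicit_exclusion_list_rule(self, descriptors):
        from biochromtox.datasets import VASODILATION_EXCLUSIONS

        low, high = split_regimes(
            descriptors.descriptors["chi_iam"], VASODILATION_EXCLUSIONS
        )
        assert sorted(high) == sorted(VASODILATION_EXCLUSIONS)
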