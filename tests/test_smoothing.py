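"""Penalized-spline mixed model: oracles, invariants and band behavior."""

import numpy as np
import pytest

from trajalign import (
    SmoothFitError,
    derivative_windows,
    fdr_adjust,
    fit_smooth,
    fit_smooth_xy,
    predict_grid,
)
from trajalign.basis import ConstrainedBasis, CubicSplineBasis, place_knots


def _two_subject_design(n=25, lo=-20.0, hi=15.0):
    ages = np.tile(np.linspace(lo, hi, n), 2)
    subj = np.repeat(["a", "b"], n)
    return ages, subj


class TestBasis:
    def test_penalty_annihilates_linear_functions(self):
        """The curvature penalty has zero quadratic form on straight lines:
        a natural cubic spline through collinear knot values is a line."""
        kn = np.array([-20.0, -8.0, 0.0, 7.0, 15.0])
        b = CubicSplineBasis(kn)
        beta_lin = 2.0 + 0.5 * kn
        assert beta_lin @ b.penalty @ beta_lin == pytest.approx(0.0, abs=1e-10)
        beta_curv = kn**2
        assert beta_curv @ b.penalty @ beta_curv > 1.0

    def test_basis_interpolates_knot_values(self):
        kn = np.array([-20.0, -8.0, 0.0, 7.0, 15.0])
        b = CubicSplineBasis(kn)
        np.testing.assert_allclose(b.design(kn), np.eye(5), atol=1e-10)

    def test_linear_extrapolation_beyond_knots(self):
        kn = np.linspace(-10, 10, 5)
        b = CubicSplineBasis(kn)
        beta = 1.0 + 0.3 * kn  # a line stays a line outside the knots
        outside = np.array([-30.0, 25.0])
        np.testing.assert_allclose(b.design(outside) @ beta, 1.0 + 0.3 * outside,
                                   rtol=1e-10)

    def test_constrained_basis_is_centered_and_shrinkable(self):
        ages = np.linspace(-20, 15, 40)
        cb = ConstrainedBasis(CubicSplineBasis(place_knots(ages, 5)), ages)
        X = cb.design(ages)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-10)
        w = np.linalg.eigvalsh(cb.S)
        assert w.min() > 0  # shrinkage ridge makes the penalty full rank


class TestFitOracles:
    def test_constant_data_gives_constant_curve(self):
        ages, subj = _two_subject_design()
        f = fit_smooth_xy(ages, np.full(ages.size, 7.0), subj)
        c = predict_grid(f, -20, 15, 100)
        np.testing.assert_allclose(c.values, 7.0, atol=1e-8)
        w = derivative_windows(f, c, n_sim=500, seed=0)
        np.testing.assert_allclose(w.derivative, 0.0, atol=1e-8)
        assert w.intervals == []

    def test_noiseless_line_recovered_unpenalized(self):
        """lambda=0, no random effects: exact least-squares line."""
        ages, subj = _two_subject_design()
        y = 2.0 + 0.3 * ages
        f = fit_smooth_xy(ages, y, subj, lam=0, random_effects=False)
        c = predict_grid(f, -20, 15, 100)
        ref = 2.0 + 0.3 * c.grid
        assert np.max(np.abs(c.values - ref) / np.maximum(np.abs(ref), 1)) < 1e-6

    def test_lambda_zero_matches_ols_spline(self, rng):
        """With lambda=0 and no random effects the fit is the unpenalized
        regression-spline least-squares solution (independent lstsq oracle)."""
        ages = np.tile(np.sort(rng.uniform(-20, 15, 25)), 2)
        subj = np.repeat(["a", "b"], 25)
        y = np.sin(ages / 6.0) + 0.1 * rng.standard_normal(ages.size)
        f = fit_smooth_xy(ages, y, subj, lam=0, random_effects=False)
        X = np.column_stack([np.ones(ages.size), f.basis.design(ages)])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        grid = np.linspace(-20, 15, 50)
        Xg = np.column_stack([np.ones(50), f.basis.design(grid)])
        pred_ols = Xg @ beta_ols
        pred_fit = predict_grid(f, -20, 15, 50).values
        assert np.max(np.abs(pred_fit - pred_ols)) < 1e-6 * np.max(np.abs(pred_ols))

    def test_infinite_smoothing_shrinks_to_flat(self, rng):
        """Shrinkage basis: huge lambda collapses the smooth to zero, so
        the curve approaches the grand intercept, not a fitted line."""
        ages, subj = _two_subject_design()
        y = 5.0 + 0.4 * ages + rng.standard_normal(ages.size)
        f = fit_smooth_xy(ages, y, subj, lam=1e12, random_effects=False)
        c = predict_grid(f, -20, 15, 100)
        assert np.ptp(c.values) < 0.05 * np.ptp(y)

    def test_affine_equivariance(self, rng):
        """fit(a*y + b) predicts a*fit(y) + b to 1e-8 relative."""
        ages, subj = _two_subject_design()
        y = np.sin(ages / 5.0) + 0.2 * rng.standard_normal(ages.size)
        c1 = predict_grid(fit_smooth_xy(ages, y, subj), -20, 15, 100)
        c2 = predict_grid(fit_smooth_xy(ages, 3.0 * y + 10.0, subj), -20, 15, 100)
        scale = np.max(np.abs(3.0 * c1.values + 10.0))
        np.testing.assert_allclose(c2.values, 3.0 * c1.values + 10.0,
                                   atol=1e-8 * scale)

    def test_pointwise_ci_coverage(self):
        """Average pointwise 95% CI coverage of a known smooth truth is
        nominal within Monte-Carlo error over 500 replicates."""
        from scipy.special import expit

        def truth(t):
            return 10 + 15 * expit((t + 10) / 6)

        cover = []
        for rep in range(500):
            r = np.random.default_rng(40_000 + rep)
            ages = np.tile(np.linspace(-24, 17, 20), 4)
            subj = np.repeat(list("ABCD"), 20)
            y = truth(ages) + 0.75 * r.standard_normal(ages.size)
            f = fit_smooth_xy(ages, y, subj, random_effects=False)
            c = predict_grid(f, -24, 17, 100)
            cover.append(
                np.mean((truth(c.grid) >= c.ci_lower) & (truth(c.grid) <= c.ci_upper))
            )
        assert abs(np.mean(cover) - 0.95) < 0.03


class TestFitContracts:
    def test_all_ages_equal_is_an_error(self):
        with pytest.raises(SmoothFitError):
            fit_smooth_xy(np.zeros(20), np.arange(20.0), ["a", "b"] * 10)

    def test_too_few_distinct_ages_is_an_error(self):
        ages = np.tile([0.0, 1.0, 2.0], 4)
        with pytest.raises(SmoothFitError, match="distinct"):
            fit_smooth_xy(ages, np.arange(12.0), ["a", "b"] * 6, k=5)

    def test_random_effect_estimates_exposed(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        assert set(f.random_effects) == {"S01", "S02", "S03", "S04"}
        assert f.lam >= 0
        # V_beta symmetric PSD
        w = np.linalg.eigvalsh(f.V_beta)
        assert w.min() > -1e-10 * max(w.max(), 1)
        assert f.beta.size == 1 + (f.k - 1) + 2 * 4

    def test_missing_values_dropped(self, rate_cohort):
        _, _, ds = rate_cohort
        df = ds.df.copy()
        df.loc[df.index[:5], "value"] = np.nan
        f = fit_smooth(df, "firing_rate")
        assert f.n_obs == len(df) - 5


class TestPredictGrid:
    def test_even_spacing_exact(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        c = predict_grid(f, -24, 18, 100)
        assert c.grid.size == 100
        np.testing.assert_allclose(np.diff(c.grid), (18 - (-24)) / 99, rtol=1e-12)
        assert np.all(c.ci_lower <= c.values) and np.all(c.values <= c.ci_upper)

    def test_monotone_fit_extremes_at_grid_ends(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        sub = ds.subset("firing_rate")["aligned_age_months"]
        c = predict_grid(f, float(sub.min()), float(sub.max()), 100)
        assert c.argmin_age == pytest.approx(c.grid[0])
        assert c.argmax_age == pytest.approx(c.grid[-1])

    def test_extrapolation_is_flagged(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        with pytest.warns(UserWarning, match="extrapolate"):
            c = predict_grid(f, -60, 40, 100)
        assert c.extrapolated.any()

    def test_bad_grid_rejected(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        with pytest.raises(ValueError):
            predict_grid(f, 10, -10)


class TestDerivativeWindows:
    def test_sign_agrees_with_numerical_slope(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        c = predict_grid(f, -24, 17, 100)
        w = derivative_windows(f, c, n_sim=2000, seed=3)
        grad = np.gradient(c.values, c.grid)
        for (s, e, sign) in w.intervals:
            mask = (c.grid >= s - 1e-9) & (c.grid <= e + 1e-9)
            assert np.all(np.sign(grad[mask]) == sign)

    def test_rising_trajectory_is_detected(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        c = predict_grid(f, -24, 17, 100)
        w = derivative_windows(f, c, n_sim=2000, seed=3)
        assert any(sign == 1 for (_, _, sign) in w.intervals)

    def test_small_n_sim_rejected(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        c = predict_grid(f, -24, 17, 100)
        with pytest.raises(ValueError):
            derivative_windows(f, c, n_sim=50)

    def test_windows_are_disjoint_and_in_range(self, rate_cohort):
        _, _, ds = rate_cohort
        f = fit_smooth(ds, "firing_rate")
        c = predict_grid(f, -24, 17, 100)
        w = derivative_windows(f, c, n_sim=2000, seed=5)
        prev_end = -np.inf
        for (s, e, sign) in w.intervals:
            assert s <= e and sign in (-1, 1)
            assert s > prev_end
            assert c.grid[0] <= s and e <= c.grid[-1]
            prev_end = e


def _bh_reference(p):
    """Brute-force BH step-up, written independently of the package."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFdrAdjust:
    def test_worked_triple(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_empty_list(self):
        assert fdr_adjust([]).size == 0

    def test_matches_brute_force_reference(self, rng):
        p = rng.uniform(size=40)
        np.testing.assert_allclose(fdr_adjust(p), _bh_reference(p), rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])
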