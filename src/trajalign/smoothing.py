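"""Penalized-spline mixed-model trajectory fitting.

Each outcome is modelled as

    y_ij = alpha + f(t_ij) + a_i + b_i * t_ij + e_ij

where t is marker-aligned age (months), f is a cubic regression spline
with k basis functions and a shrinkage curvature penalty, (a_i, b_i) are
subject-specific random intercepts and slopes, and e_ij is Gaussian
noise.  The smoothing parameter and the random-effect variance ratios
are estimated by REML (the fixed coefficients are profiled out
analytically); the coefficient posterior covariance gives pointwise
confidence bands on the fitted trajectory and, via posterior simulation,
simultaneous bands on its finite-difference derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .basis import ConstrainedBasis, CubicSplineBasis, place_knots

__all__ = [
    "SmoothFit",
    "TrajectoryCurve",
    "ChangeWindows",
    "SmoothFitError",
    "fit_smooth",
    "fit_smooth_xy",
    "predict_grid",
    "derivative_windows",
    "fdr_adjust",
]

_Z95 = stats.norm.ppf(0.975)


class SmoothFitError(RuntimeError):
    """Raised when the penalized-spline mixed model cannot be fitted."""


@dataclass
class SmoothFit:
    """Fitted penalized-spline mixed model for one outcome."""

    outcome: str
    k: int
    basis: ConstrainedBasis
    lam: float
    beta: np.ndarray            # full coefficient vector (alpha, spline, RE)
    V_beta: np.ndarray          # Bayesian posterior covariance of beta
    sigma2: float               # residual variance
    sd_intercept: float         # random-intercept SD (0 if disabled)
    sd_slope: float             # random-slope SD per month (0 if disabled)
    subjects: list
    n_obs: int
    data_range: tuple
    edf: float
    p_smooth: float             # Wald-type p-value for the smooth term
    converged: bool
    warnings_: list = field(default_factory=list)
    _age_scale: float = 1.0
    _n_spline: int = 0
    _n_re: int = 0

    @property
    def random_effects(self) -> dict:
        """Per-subject (intercept, slope) BLUP estimates."""
        m = len(self.subjects)
        out = {}
        off = 1 + self._n_spline
        for i, s in enumerate(self.subjects):
            a = self.beta[off + i] if self._n_re else 0.0
            b = self.beta[off + m + i] / self._age_scale if self._n_re == 2 else 0.0
            out[s] = (float(a), float(b))
        return out

    def design_row(self, ages: np.ndarray) -> np.ndarray:
        """Population-level design rows (random effects set to zero)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        Xs = self.basis.design(ages)
        X = np.zeros((ages.size, self.beta.size))
        X[:, 0] = 1.0
        X[:, 1 : 1 + self._n_spline] = Xs
        return X

    def summary(self) -> str:
        lines = [
            f"outcome:            {self.outcome}",
            f"n_obs / subjects:   {self.n_obs} / {len(self.subjects)}",
            f"basis dim k:        {self.k}",
            f"lambda (REML):      {self.lam:.6g}",
            f"sigma (residual):   {np.sqrt(self.sigma2):.6g}",
            f"sd intercept/slope: {self.sd_intercept:.6g} / {self.sd_slope:.6g}",
            f"effective df:       {self.edf:.3f}",
            f"smooth Wald p:      {self.p_smooth:.4g}",
            f"converged:          {self.converged}",
        ]
        for w in self.warnings_:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


@dataclass
class TrajectoryCurve:
    """Predictions of a SmoothFit on a fixed, evenly spaced age grid."""

    outcome: str
    grid: np.ndarray
    values: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    argmin_age: float
    argmax_age: float
    extrapolated: np.ndarray    # bool mask: grid point beyond observed ages

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        d = np.diff(g)
        if g.size < 2 or np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-8):
            raise ValueError("grid must be strictly increasing and evenly spaced")


@dataclass
class ChangeWindows:
    """Aligned-age intervals where the trajectory derivative is
    significantly non-zero at simultaneous level alpha."""

    outcome: str
    intervals: list             # (start_age, end_age, sign)
    alpha: float
    derivative: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    critical_value: float


def _reml_design(ages, y, subject_codes, m, basis, random_effects, random_slopes, age_scale):
    n = y.size
    Xs = basis.design(ages)
    blocks = [np.ones((n, 1)), Xs]
    if random_effects:
        Zi = np.zeros((n, m))
        Zi[np.arange(n), subject_codes] = 1.0
        blocks.append(Zi)
        if random_slopes:
            blocks.append(Zi * (ages / age_scale)[:, None])
    return np.hstack(blocks)


def fit_smooth_xy(
    ages,
    y,
    subjects,
    outcome: str = "y",
    k: int = 5,
    lam: float | None = None,
    random_effects: bool = True,
    random_slopes: bool = True,
    shrink_eps: float = 1e-6,
) -> SmoothFit:
    """Fit the penalized-spline mixed model from raw arrays.

    Parameters
    ----------
    ages, y, subjects
        Aligned ages (months), outcome values and subject labels, one
        entry per observation.  Rows with missing values are dropped
        (complete-case analysis).
    lam
        Smoothing parameter; ``None`` (default) selects it by REML,
        a fixed value (e.g. 0) bypasses selection.
    random_effects, random_slopes
        Include subject random intercepts / random slopes on aligned age.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    ok = np.isfinite(ages) & np.isfinite(y)
    ages, y, subjects = ages[ok], y[ok], subjects[ok]
    n = y.size
    subj_list = sorted(set(subjects.tolist()))
    m = len(subj_list)
    codes = np.array([subj_list.index(s) for s in subjects])

    if m < 2 and random_effects:
        random_effects = False
    n_distinct = np.unique(ages).size
    if n_distinct < k + 2:
        raise SmoothFitError(
            f"need at least k+2={k + 2} distinct aligned ages, got {n_distinct}"
        )
    if np.ptp(ages) == 0:
        raise SmoothFitError("all aligned ages are equal: design is rank deficient")

    knots = place_knots(ages, k)
    basis = ConstrainedBasis(CubicSplineBasis(knots), ages, shrink_eps=shrink_eps)
    age_scale = max(np.std(ages), 1e-8)

    # standardize the response so the REML surface (and hence the selected
    # smoothing/variance parameters) is exactly invariant to affine maps
    # of y; estimates are transformed back on exit
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=0)) or 1.0
    y = (y - y_mean) / y_scale

    warns: list[str] = []
    yty = float(y @ y)
    _cache: dict = {}

    def _design_for(re, slopes):
        key = (re, slopes)
        if key not in _cache:
            M = _reml_design(ages, y, codes, m, basis, re, slopes, age_scale)
            _cache[key] = (M, M.T @ M, M.T @ y)
        return _cache[key]

    def _solve_at(log_lam, log_gi, log_gs, re, slopes):
        M, MtM, Mty = _design_for(re, slopes)
        p = M.shape[1]
        ns = basis.ncol
        A = MtM.copy()
        lam_eff = np.exp(log_lam)
        A[1 : 1 + ns, 1 : 1 + ns] += lam_eff * basis.S
        off = 1 + ns
        if re:
            idx = np.arange(off, off + m)
            A[idx, idx] += np.exp(-log_gi)
            if slopes:
                idx = np.arange(off + m, off + 2 * m)
                A[idx, idx] += np.exp(-log_gs)
        try:
            L = linalg.cholesky(A, lower=True)
        except linalg.LinAlgError:
            return None
        c = linalg.cho_solve((L, True), Mty)
        Dp = max(yty - float(c @ Mty), 1e-300)
        logdetA = 2.0 * np.sum(np.log(np.diag(L)))
        return M, MtM, A, L, c, Dp, logdetA

    sign_S, logdet_S = np.linalg.slogdet(basis.S)
    if sign_S <= 0:
        raise SmoothFitError("shrinkage penalty is not positive definite")

    def objective(theta, re, slopes, fixed_lam):
        i = 0
        if fixed_lam is None:
            log_lam = theta[i]
            i += 1
        else:
            log_lam = np.log(max(fixed_lam, 1e-300)) if fixed_lam > 0 else -np.inf
        log_gi = theta[i] if re else 0.0
        i += 1 if re else 0
        log_gs = theta[i] if (re and slopes) else 0.0
        if fixed_lam == 0:
            # unpenalized smooth: drop the lambda term entirely
            sol = _solve_at(-np.inf, log_gi, log_gs, re, slopes)
            ns_term = 0.0
        else:
            sol = _solve_at(log_lam, log_gi, log_gs, re, slopes)
            ns_term = basis.ncol * log_lam + logdet_S
        if sol is None:
            return 1e12
        _, _, _, _, _, Dp, logdetA = sol
        logdetP = ns_term
        if re:
            logdetP += -m * log_gi
            if slopes:
                logdetP += -m * log_gs
        return (n - 1) * np.log(Dp) + logdetA - logdetP

    def _optimize(re, slopes):
        nfree = (1 if lam is None else 0) + (1 if re else 0) + (1 if re and slopes else 0)
        if nfree == 0:
            return np.array([]), True, ""
        x0 = np.zeros(nfree)
        bounds = []
        i = 0
        if lam is None:
            bounds.append((-12.0, 20.0))
            i += 1
        for _ in range(nfree - i):
            bounds.append((-12.0, 8.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                objective,
                x0,
                args=(re, slopes, lam),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
            )
            if not res.success:
                # quasi-Newton line searches can fail when a variance
                # component runs to its bound; polish with Nelder-Mead
                res2 = optimize.minimize(
                    objective,
                    res.x,
                    args=(re, slopes, lam),
                    method="Nelder-Mead",
                    bounds=bounds,
                    options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9},
                )
                if res2.success or res2.fun <= res.fun:
                    return res2.x, True, str(res2.message)
        return res.x, bool(res.success), str(res.message)

    use_slopes = random_effects and random_slopes
    theta, ok_opt, msg = _optimize(random_effects, use_slopes)
    if not ok_opt and use_slopes:
        warns.append("REML with random slopes did not converge; refitting with "
                     "random intercepts only")
        use_slopes = False
        theta, ok_opt, msg = _optimize(random_effects, use_slopes)
    if not ok_opt and lam is None:
        raise SmoothFitError(f"REML optimization failed: {msg}")

    i = 0
    if lam is None:
        log_lam = theta[i]
        lam_hat = float(np.exp(log_lam))
        i += 1
    else:
        lam_hat = float(lam)
        log_lam = np.log(lam_hat) if lam_hat > 0 else -np.inf
    log_gi = theta[i] if random_effects else 0.0
    i += 1 if random_effects else 0
    log_gs = theta[i] if use_slopes else 0.0

    sol = _solve_at(log_lam, log_gi, log_gs, random_effects, use_slopes)
    if sol is None:
        raise SmoothFitError("final penalized system is not positive definite")
    M, MtM, A, L, c, Dp, _ = sol
    sigma2 = Dp / (n - 1)
    Ainv = linalg.cho_solve((L, True), np.eye(A.shape[0]))
    V = sigma2 * Ainv
    V = 0.5 * (V + V.T)
    edf = float(np.trace(Ainv @ MtM))

    ns = basis.ncol
    u = c[1 : 1 + ns]
    Vu = V[1 : 1 + ns, 1 : 1 + ns]
    try:
        T = float(u @ np.linalg.solve(Vu, u))
        p_smooth = float(stats.chi2.sf(T, df=ns))
    except np.linalg.LinAlgError:
        p_smooth = float("nan")

    # back-transform to the original response scale
    c = c * y_scale
    c[0] += y_mean
    V = V * y_scale**2
    sigma2 = sigma2 * y_scale**2

    sd_int = float(np.sqrt(sigma2 * np.exp(log_gi))) if random_effects else 0.0
    sd_slp = (
        float(np.sqrt(sigma2 * np.exp(log_gs)) / age_scale) if use_slopes else 0.0
    )
    n_re = (2 if use_slopes else 1) if random_effects else 0

    return SmoothFit(
        outcome=outcome,
        k=k,
        basis=basis,
        lam=lam_hat,
        beta=c,
        V_beta=V,
        sigma2=float(sigma2),
        sd_intercept=sd_int,
        sd_slope=sd_slp,
        subjects=subj_list,
        n_obs=n,
        data_range=(float(ages.min()), float(ages.max())),
        edf=edf,
        p_smooth=p_smooth,
        converged=ok_opt or lam is not None,
        warnings_=warns,
        _age_scale=age_scale,
        _n_spline=ns,
        _n_re=n_re,
    )


def fit_smooth(data, outcome: str, k: int = 5, **kwargs) -> SmoothFit:
    """Fit one outcome from a long-format dataset.

    ``data`` is a LongitudinalDataset or a DataFrame with columns
    ``subject_id``, ``aligned_age_months``, ``outcome``, ``value``.
    """
    df = getattr(data, "df", data)
    sub = df[df["outcome"] == outcome]
    if sub.empty:
        raise SmoothFitError(f"outcome {outcome!r} not present in data")
    return fit_smooth_xy(
        sub["aligned_age_months"].to_numpy(),
        sub["value"].to_numpy(),
        sub["subject_id"].to_numpy(),
        outcome=outcome,
        k=k,
        **kwargs,
    )


def predict_grid(
    fit: SmoothFit, grid_lo: float, grid_hi: float, n_grid: int = 100
) -> TrajectoryCurve:
    """Evaluate the population trajectory on an even grid with pointwise
    95% confidence bounds; extrapolation beyond the data is flagged."""
    if not grid_lo < grid_hi:
        raise ValueError("grid_lo must be < grid_hi")
    grid = np.linspace(grid_lo, grid_hi, n_grid)
    X = fit.design_row(grid)
    values = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.V_beta, X), 0.0))
    lo, hi = values - _Z95 * se, values + _Z95 * se
    extra = (grid < fit.data_range[0]) | (grid > fit.data_range[1])
    if extra.any():
        warnings.warn(
            f"{outcome_name(fit)}: {int(extra.sum())} grid points extrapolate "
            "beyond the fitted age range",
            stacklevel=2,
        )
    return TrajectoryCurve(
        outcome=fit.outcome,
        grid=grid,
        values=values,
        ci_lower=lo,
        ci_upper=hi,
        argmin_age=float(grid[int(np.argmin(values))]),
        argmax_age=float(grid[int(np.argmax(values))]),
        extrapolated=extra,
    )


def outcome_name(fit: SmoothFit) -> str:
    return fit.outcome


def _fd_matrix(grid: np.ndarray) -> np.ndarray:
    """Finite-difference derivative operator on an even grid: central
    differences in the interior, one-sided at the ends."""
    n = grid.size
    h = grid[1] - grid[0]
    D = np.zeros((n, n))
    for i in range(1, n - 1):
        D[i, i - 1], D[i, i + 1] = -1.0 / (2 * h), 1.0 / (2 * h)
    D[0, 0], D[0, 1] = -1.0 / h, 1.0 / h
    D[-1, -2], D[-1, -1] = -1.0 / h, 1.0 / h
    return D


def derivative_windows(
    fit: SmoothFit,
    curve: TrajectoryCurve,
    n_sim: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ChangeWindows:
    """Locate aligned-age windows of significant developmental change.

    The derivative of the fitted trajectory is approximated by finite
    differences on the prediction grid.  A simultaneous (1-alpha) band is
    calibrated by drawing coefficient vectors from the posterior
    N(beta, V_beta) and taking the (1-alpha) quantile of the maximum
    standardized deviation of the simulated derivatives; intervals where
    the band excludes zero are reported with the derivative's sign.
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives an unreliable simultaneous band")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = fit.design_row(curve.grid)
    D = _fd_matrix(curve.grid)
    L = D @ X
    d_hat = L @ fit.beta
    Vd = L @ fit.V_beta @ L.T
    sd = np.sqrt(np.maximum(np.diag(Vd), 0.0))
    scale = max(np.max(np.abs(curve.values)), 1.0)
    degenerate = sd < 1e-12 * scale
    sd_safe = np.where(degenerate, 1.0, sd)

    # posterior simulation of the max standardized deviation
    w, Q = np.linalg.eigh(0.5 * (fit.V_beta + fit.V_beta.T))
    R = Q @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    G = (L @ R) / sd_safe[:, None]
    Z = rng.standard_normal((R.shape[1], n_sim))
    maxdev = np.max(np.abs(G @ Z), axis=0)
    crit = float(np.quantile(maxdev, 1.0 - alpha))

    lower = d_hat - crit * sd
    upper = d_hat + crit * sd
    sign = np.zeros(curve.grid.size, dtype=int)
    sign[(lower > 0) & ~degenerate] = 1
    sign[(upper < 0) & ~degenerate] = -1

    intervals = []
    start = None
    for i, s in enumerate(sign):
        if s != 0 and (start is None or s != cur_sign):
            if start is not None:
                intervals.append((float(curve.grid[start]), float(curve.grid[i - 1]), int(cur_sign)))
            start, cur_sign = i, s
        elif s == 0 and start is not None:
            intervals.append((float(curve.grid[start]), float(curve.grid[i - 1]), int(cur_sign)))
            start = None
    if start is not None:
        intervals.append((float(curve.grid[start]), float(curve.grid[-1]), int(cur_sign)))

    return ChangeWindows(
        outcome=fit.outcome,
        intervals=intervals,
        alpha=alpha,
        derivative=d_hat,
        band_lower=lower,
        band_upper=upper,
        critical_value=crit,
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
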