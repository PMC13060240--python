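"""Trajectory-similarity statistics with maxT permutation inference.

Two fitted trajectories sampled on a shared age grid are compared by
(i) the Pearson correlation of their z-scored values and (ii) the RMSE
of their *folded* versions: each z-scored curve is shifted so its first
point is zero and then taken in absolute value, which maps positively
and negatively correlated curves onto a common, non-negative shape
scale.  Family-wise significance of the correlations is assessed with a
maxT permutation test: in each permutation every pair's second curve is
independently re-ordered, the maximum |r| over the family forms the
null distribution, and each observed |r| is referred to it.

Caveat: smooth trajectories are strongly autocorrelated along the grid,
so index permutation breaks that structure and the null is
anti-conservative for smooth curves; p-values should be read as a
family-calibrated ranking rather than exact error rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedCurve",
    "SimilarityResult",
    "zscore_curve",
    "shift_abs",
    "trajectory_rmse",
    "trajectory_corr",
    "maxt_permutation",
    "family_summary",
    "compare_curves",
]


@dataclass
class NormalizedCurve:
    """A trajectory on the shared grid in z-scored and folded form."""

    grid: np.ndarray
    z: np.ndarray
    folded: np.ndarray

    @classmethod
    def from_values(cls, grid, values) -> "NormalizedCurve":
        z = zscore_curve(values)
        return cls(np.asarray(grid, dtype=float), z, shift_abs(z))


@dataclass
class SimilarityResult:
    pair: tuple
    r: float
    rmse: float
    p_maxT: float | None = None


def zscore_curve(values) -> np.ndarray:
    """Z-score a curve to mean 0, unit sample SD (divisor n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points to z-score")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant curve: z-score (and similarity) undefined")
    return (x - x.mean()) / sd


def shift_abs(z) -> np.ndarray:
    """Fold a curve: subtract its first value, then take absolute values.

    The output starts at exactly 0 and is non-negative; a monotone curve
    and its negation fold onto the same shape.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 points")
    return np.abs(z - z[0])


def trajectory_rmse(x_folded, y_folded) -> float:
    """Root-mean-square difference between two folded curves."""
    x = np.asarray(x_folded, dtype=float)
    y = np.asarray(y_folded, dtype=float)
    if x.shape != y.shape:
        raise ValueError("folded curves must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def trajectory_corr(x_z, y_z) -> float:
    """Pearson correlation of two z-scored curves on the shared grid."""
    x = np.asarray(x_z, dtype=float)
    y = np.asarray(y_z, dtype=float)
    if x.shape != y.shape:
        raise ValueError("curves must have equal length")
    n = x.size
    return float(x @ y / (n - 1))


def compare_curves(grid, x_values, y_values, pair=("X", "Y")) -> SimilarityResult:
    """r and folded RMSE for one raw curve pair (no permutation p)."""
    cx = NormalizedCurve.from_values(grid, x_values)
    cy = NormalizedCurve.from_values(grid, y_values)
    return SimilarityResult(
        pair=tuple(pair),
        r=trajectory_corr(cx.z, cy.z),
        rmse=trajectory_rmse(cx.folded, cy.folded),
    )


def maxt_permutation(
    pairs: list,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    return_unadjusted: bool = False,
) -> np.ndarray:
    """Family-wise adjusted permutation p-values for |r| of each pair.

    ``pairs`` is a list of (X_z, Y_z) z-scored curves on a common grid
    length.  For each of ``n_perm`` permutations the grid indices of
    every pair's Y are independently shuffled and r recomputed; the
    permutation statistic is T_b = max over pairs of |r|, and each
    pair's p is (1 + #{T_b >= |r_obs|}) / (n_perm + 1).  A single pair
    degenerates to an unadjusted permutation test.

    With ``return_unadjusted`` the per-pair unadjusted permutation p
    (from the same permutation draws, so p_maxT >= p_unadjusted holds
    by construction) is returned as a second array.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not pairs:
        raise ValueError("empty family")
    Xs = [np.asarray(x, dtype=float) for x, _ in pairs]
    Ys = [np.asarray(y, dtype=float) for _, y in pairs]
    n = Xs[0].size
    if any(x.size != n or y.size != n for x, y in zip(Xs, Ys)):
        raise ValueError("all pairs must share the grid length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    r_obs = np.array([abs(trajectory_corr(x, y)) for x, y in zip(Xs, Ys)])
    npairs = len(pairs)
    r_null = np.empty((npairs, n_perm))
    for b in range(n_perm):
        for j in range(npairs):
            perm = rng.permutation(n)
            r_null[j, b] = abs(float(Xs[j] @ Ys[j][perm]) / (n - 1))
    tmax = r_null.max(axis=0)
    # tolerate float round-off when the observed statistic is attainable
    p = (1.0 + np.sum(tmax[None, :] >= r_obs[:, None] - 1e-12, axis=1)) / (n_perm + 1.0)
    if return_unadjusted:
        p_un = (1.0 + np.sum(r_null >= r_obs[:, None] - 1e-12, axis=1)) / (n_perm + 1.0)
        return p, p_un
    return p


def family_summary(results: list) -> dict:
    """Median |r| and median RMSE over a family, plus a table sorted by
    |r| descending (strongest trajectory alignment first)."""
    if not results:
        raise ValueError("empty family")
    abs_r = np.array([abs(res.r) for res in results])
    rmse = np.array([res.rmse for res in results])
    order = np.argsort(-abs_r, kind="stable")
    table = [results[i] for i in order]
    return {
        "median_abs_r": float(np.median(abs_r)),
        "median_r": float(np.median([res.r for res in results])),
        "median_rmse": float(np.median(rmse)),
        "table": table,
    }
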