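"""Cubic regression spline basis with a shrinkage curvature penalty.

The smooth f(x) is parameterized by its values at k knots and constrained
to be a natural cubic spline (linear beyond the boundary knots).  The
wiggliness penalty is the integrated squared second derivative, which is a
quadratic form in the knot values.  A small ridge on the penalty null
space (the linear functions) turns the basis into a *shrinkage* basis:
as the smoothing parameter grows the fit collapses to zero rather than to
an unpenalized straight line.
"""

from __future__ import annotations

import numpy as np
from numpy.linalg import solve
from dataclasses import dataclass, field


def place_knots(x: np.ndarray, k: int) -> np.ndarray:
    """k knots at evenly spaced quantiles of the unique values of x."""
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise ValueError(f"need at least {k} distinct covariate values, got {ux.size}")
    q = np.linspace(0.0, 1.0, k)
    knots = np.quantile(ux, q)
    # quantiles of heavily tied data can still coincide; nudge to strict order
    if np.any(np.diff(knots) <= 0):
        knots = np.linspace(ux[0], ux[-1], k)
    return knots


def _crs_matrices(knots: np.ndarray):
    """Return (F_full, S) for a natural cubic spline through `knots`.

    F_full maps knot values to second derivatives at every knot (zero at
    the boundaries); S is the integrated-squared-second-derivative
    penalty, S = D' B^{-1} D.
    """
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    F = solve(B, D)
    S = D.T @ F
    F_full = np.vstack([np.zeros(k), F, np.zeros(k)])
    return F_full, S


@dataclass
class CubicSplineBasis:
    """Natural cubic regression spline basis over fixed knots.

    ``design(x)`` evaluates the k cardinal basis functions (one per knot
    value); outside the knot range the spline extends linearly, and the
    caller can detect extrapolation via ``in_range``.
    """

    knots: np.ndarray
    F: np.ndarray = field(init=False, repr=False)
    penalty: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.size < 4:
            raise ValueError("cubic regression spline needs at least 4 knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.F, self.penalty = _crs_matrices(self.knots)

    @property
    def k(self) -> int:
        return self.knots.size

    def _row(self, x: float, deriv: bool = False) -> np.ndarray:
        kn = self.knots
        j = int(np.clip(np.searchsorted(kn, x, side="right") - 1, 0, kn.size - 2))
        h = kn[j + 1] - kn[j]
        xm, xp = kn[j + 1] - x, x - kn[j]
        row = np.zeros(kn.size)
        if not deriv:
            am, ap = xm / h, xp / h
            cm = (xm**3 / h - h * xm) / 6.0
            cp = (xp**3 / h - h * xp) / 6.0
        else:
            am, ap = -1.0 / h, 1.0 / h
            cm = (-3.0 * xm**2 / h + h) / 6.0
            cp = (3.0 * xp**2 / h - h) / 6.0
        row[j] += am
        row[j + 1] += ap
        row += cm * self.F[j] + cp * self.F[j + 1]
        return row

    def design(self, x: np.ndarray) -> np.ndarray:
        """n x k design matrix; linear extrapolation beyond the knots."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        kn = self.knots
        X = np.empty((x.size, kn.size))
        for i, xi in enumerate(x):
            if xi < kn[0]:
                X[i] = self._row(kn[0]) + (xi - kn[0]) * self._row(kn[0], deriv=True)
            elif xi > kn[-1]:
                X[i] = self._row(kn[-1]) + (xi - kn[-1]) * self._row(kn[-1], deriv=True)
            else:
                X[i] = self._row(xi)
        return X

    def in_range(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return (x >= self.knots[0]) & (x <= self.knots[-1])


@dataclass
class ConstrainedBasis:
    """Sum-to-zero constrained, shrinkage-penalized spline basis.

    The raw k-function basis contains the constant, which would be
    confounded with the model intercept.  We absorb the constraint
    ``mean(f(x_i)) = 0`` by reparameterizing onto k-1 columns (the null
    space of the constraint, found by QR).  The curvature penalty is
    transformed accordingly and a ridge of size ``shrink_eps * tr(S)`` is
    added on its null space (the linear component), giving mgcv-style
    shrinkage-spline semantics.
    """

    base: CubicSplineBasis
    constraint_x: np.ndarray
    shrink_eps: float = 1e-6
    Z: np.ndarray = field(init=False, repr=False)
    S: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        Xc = self.base.design(self.constraint_x)
        c = Xc.mean(axis=0)  # constraint vector: c' beta = 0
        # null space of c' via full QR
        Q, _ = np.linalg.qr(c[:, None], mode="complete")
        self.Z = Q[:, 1:]
        S = self.Z.T @ self.base.penalty @ self.Z
        S = 0.5 * (S + S.T)
        w, V = np.linalg.eigh(S)
        null = w < 1e-10 * max(w.max(), 1.0)
        if null.any():
            U0 = V[:, null]
            S = S + self.shrink_eps * np.trace(S) * (U0 @ U0.T)
        self.S = 0.5 * (S + S.T)

    @property
    def ncol(self) -> int:
        return self.base.k - 1

    def design(self, x: np.ndarray) -> np.ndarray:
        return self.base.design(x) @ self.Z
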