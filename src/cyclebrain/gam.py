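"""Penalized-spline generalized additive temporal model.

Each retained component's standardized temporal scores are modeled as
``score = beta0 + f(test day)`` where ``f`` is a cubic regression spline with
basis dimension ``k = 10`` (knots at quantiles of the observed days) and a
wiggliness penalty equal to the integrated squared second derivative.  The
smoothing parameter is chosen by generalized cross-validation (GCV) over a
fixed log-spaced grid and the effective degrees of freedom (EDF) is the trace
of the smoother matrix.  The presence of temporal fluctuation is tested with
an F test of the full (unpenalized) spline family against the intercept-only
model, whose null distribution is exact; see the methods note for why the
test does not condition on the data-chosen smoothing parameter.

The cubic regression spline follows the standard value/second-derivative
parameterization: the coefficients are the spline's values at the knots, the
natural-spline second derivatives at interior knots are ``B^{-1} D beta``,
and the penalty matrix is ``S = D' B^{-1} D`` (banded D and B built from knot
spacings).  Its null space is exactly the constant + linear functions, so the
infinite-smoothing limit of the fit is the least-squares straight line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "build_spline_basis",
    "PenalizedSplineGAM",
    "GamFit",
    "fit_gam",
    "fdr_adjust",
]

#: GCV smoothing-parameter grid: 61 log-spaced values spanning near
#: interpolation to an effectively linear fit.
LAMBDA_GRID = np.logspace(-4, 6, 61)


def _cr_penalty(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """D (k-2 x k) and B (k-2 x k-2) matrices of the cubic regression spline."""
    h = np.diff(knots)
    k = knots.size
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    return D, B


def _choose_knots(days: np.ndarray, k: int) -> np.ndarray:
    uniq = np.unique(days.astype(float))
    if uniq.size < 5:
        raise ValueError(f"need >= 5 distinct days, got {uniq.size}")
    k_eff = min(k, uniq.size)
    knots = np.quantile(uniq, np.linspace(0, 1, k_eff))
    # quantiles of sparse designs can coincide; enforce strict increase
    return np.unique(knots)


def build_spline_basis(
    days: np.ndarray, k: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cubic regression-spline basis and wiggliness penalty.

    Returns ``(X, S, knots)`` where ``X`` is n x k (columns = spline values
    parameterized by its values at the k knots), ``S`` is the k x k penalty
    (integrated squared second derivative, PSD with a 2-dimensional null
    space: constant + linear), and ``knots`` are the quantile knots used.
    """
    days = np.asarray(days, dtype=float)
    knots = _choose_knots(days, k)
    kk = knots.size
    D, B = _cr_penalty(knots)
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0

    # second derivatives at the knots under the natural boundary condition
    F = np.zeros((kk, kk))
    F[1:-1] = Binv_D

    x = np.clip(days, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, kk - 2)
    h = knots[j + 1] - knots[j]
    dxm = knots[j + 1] - x
    dxp = x - knots[j]
    a_m = dxm / h
    a_p = dxp / h
    c_m = (dxm**3 / h - h * dxm) / 6.0
    c_p = (dxp**3 / h - h * dxp) / 6.0

    X = np.zeros((days.size, kk))
    rows = np.arange(days.size)
    X[rows, j] += a_m
    X[rows, j + 1] += a_p
    X += c_m[:, None] * F[j] + c_p[:, None] * F[j + 1]
    return X, S, knots


@dataclass
class GamFit:
    """Penalized-spline temporal fit for one component and individual."""

    individual_id: str
    component: int
    basis_size: int
    smoothing_parameter: float
    coefficients: np.ndarray
    fitted: np.ndarray
    edf: float
    f_stat: float
    p_value: float
    p_fdr: float | None = None


class PenalizedSplineGAM(RegressorMixin, BaseEstimator):
    """Cubic regression-spline smoother with GCV-selected penalty.

    Parameters
    ----------
    k : int
        Basis dimension (number of quantile knots), default 10.
    lambda_grid : array-like or None
        Candidate smoothing parameters; None uses the 61-point default grid.
    smoothing_parameter : float or None
        Fix the penalty instead of selecting it by GCV.

    Attributes (after ``fit``)
    --------------------------
    lambda_ : selected smoothing parameter
    edf_ : effective degrees of freedom (trace of the smoother matrix)
    coef_ : spline coefficients (values at the knots)
    f_stat_, p_value_ : approximate F test of the smooth vs intercept-only
    """

    def __init__(self, k: int = 10, lambda_grid=None, smoothing_parameter=None):
        self.k = k
        self.lambda_grid = lambda_grid
        self.smoothing_parameter = smoothing_parameter

    def fit(self, X, y):
        days = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if days.size != y.size:
            raise ValueError("days and scores must have equal length")
        if y.size < 8:
            raise ValueError("need at least 8 sessions")
        n = y.size

        if np.ptp(y) == 0:
            # degenerate: constant response, no fluctuation by definition
            self.knots_ = None
            self.lambda_ = np.inf
            self.coef_ = None
            self.edf_ = 1.0
            self.fitted_ = np.full(n, y[0])
            self.f_stat_ = 0.0
            self.p_value_ = 1.0
            self._days = days
            return self

        B, S, knots = build_spline_basis(days, self.k)
        kk = knots.size
        # square root of the penalty: S = L'L with L = Lb^{-1} D, B_pen = Lb Lb'
        D, Bpen = _cr_penalty(knots)
        Lb = np.linalg.cholesky(Bpen)
        L = solve_triangular(Lb, D, lower=True)

        if self.smoothing_parameter is not None:
            grid = [float(self.smoothing_parameter)]
        elif self.lambda_grid is not None:
            grid = list(np.asarray(self.lambda_grid, dtype=float))
        else:
            grid = list(LAMBDA_GRID)

        # penalized solve via augmented QR: stable from near-interpolation to
        # the straight-line (lambda -> inf) limit
        y_aug = np.concatenate([y, np.zeros(kk - 2)])
        best = None
        for lam in grid:
            aug = np.vstack([B, np.sqrt(lam) * L])
            Q, R = np.linalg.qr(aug)
            coef = solve_triangular(R, Q.T @ y_aug)
            BRinv = solve_triangular(R.T, B.T, lower=True)
            edf = float(np.sum(BRinv**2))
            fitted = B @ coef
            rss = float(np.sum((y - fitted) ** 2))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, coef, edf, fitted, rss)
        _, lam, coef, edf, fitted, rss = best

        # Significance of the smooth: exact F test of the full (unpenalized)
        # spline family against the intercept-only model.  Conditioning on a
        # data-chosen smoothing parameter would invalidate the F reference
        # distribution, so the test projects onto the fixed k-dimensional
        # basis where the null distribution is exact.
        Qb, _ = np.linalg.qr(B)
        proj = Qb @ (Qb.T @ y)
        rss_full = float(np.sum((y - proj) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        df1 = kk - 1.0
        df2 = n - kk
        if df2 <= 0:
            raise ValueError(f"need more sessions than basis functions ({kk})")
        if rss_full <= 1e-300 * max(rss0, 1.0):
            f_stat, p_value = np.inf, 0.0
        else:
            f_stat = ((rss0 - rss_full) / df1) / (rss_full / df2)
            f_stat = max(f_stat, 0.0)
            p_value = float(stats.f.sf(f_stat, df1, df2))

        self.knots_ = knots
        self.lambda_ = float(lam)
        self.coef_ = coef
        self.edf_ = edf
        self.fitted_ = fitted
        self.f_stat_ = float(f_stat)
        self.p_value_ = p_value
        self._days = days
        return self

    def predict(self, X):
        days = np.asarray(X, dtype=float).reshape(-1)
        if self.coef_ is None:  # degenerate constant fit
            return np.full(days.size, self.fitted_[0])
        B, _, _ = _basis_at(days, self.knots_)
        return B @ self.coef_

    def fit_predict(self, X, y):
        return self.fit(X, y).fitted_


def _basis_at(days: np.ndarray, knots: np.ndarray):
    """Evaluate the fitted spline basis at new days (same knots)."""
    kk = knots.size
    D, B = _cr_penalty(knots)
    F = np.zeros((kk, kk))
    F[1:-1] = np.linalg.solve(B, D)
    x = np.clip(days, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, kk - 2)
    h = knots[j + 1] - knots[j]
    dxm, dxp = knots[j + 1] - x, x - knots[j]
    X = np.zeros((days.size, kk))
    rows = np.arange(days.size)
    X[rows, j] += dxm / h
    X[rows, j + 1] += dxp / h
    X += ((dxm**3 / h - h * dxm) / 6.0)[:, None] * F[j]
    X += ((dxp**3 / h - h * dxp) / 6.0)[:, None] * F[j + 1]
    return X, None, knots


def fit_gam(
    days, scores, k: int = 10, individual_id: str = "", component: int = 0
) -> GamFit:
    """Fit the penalized-spline temporal model to one score series."""
    model = PenalizedSplineGAM(k=k).fit(days, scores)
    return GamFit(
        individual_id=individual_id,
        component=component,
        basis_size=k,
        smoothing_parameter=model.lambda_,
        coefficients=model.coef_,
        fitted=model.fitted_,
        edf=model.edf_,
        f_stat=model.f_stat_,
        p_value=model.p_value_,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted p_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted
    p-values; order-preserving and always >= the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
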