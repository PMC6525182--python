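"""Linear, allometry-form nonlinear, and standardized major axis regression.

Three estimators in the scikit-learn idiom (``fit`` / ``predict`` /
``get_params``, fitted attributes with a trailing underscore):

* :class:`LinearOLS` — closed-form ordinary least squares on one predictor,
  with slope standard error and a two-sided t-test on the slope.
* :class:`AllometricCurve` — nonlinear least squares for the allometry-form
  curve ``y = (a + b/x)**2 + d``, the functional family the two-tissue
  root model predicts for trait-diameter relationships.  Fitted by
  Levenberg-Marquardt with an analytic Jacobian from a multi-start grid;
  the sign symmetry ``(a, b) <-> (-a, -b)`` is resolved by reporting
  ``a >= 0`` so the sign of ``b`` carries the biological direction.
* :class:`StandardizedMajorAxis` — SMA line fitting, the symmetric
  alternative to OLS used for slope comparisons; slope is
  ``sign(r) * sd(y)/sd(x)`` with the standard likelihood-based confidence
  interval.

Module-level functions (:func:`ols_fit`, :func:`nls_allometric_fit`,
:func:`sma_fit`, :func:`sma_common_slope_test`,
:func:`fit_anatomy_allometry`) are thin wrappers returning plain result
records.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .allometry import AllometryParams

__all__ = [
    "LinearFit",
    "NonlinearFit",
    "SMAFit",
    "CommonSlopeTest",
    "LinearOLS",
    "AllometricCurve",
    "StandardizedMajorAxis",
    "ols_fit",
    "nls_allometric_fit",
    "sma_fit",
    "sma_common_slope_test",
    "fit_anatomy_allometry",
]


# --------------------------------------------------------------------------
# result records


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    p_slope: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NonlinearFit:
    """Parameters of ``y = (a + b/x)**2 + d`` with fit diagnostics."""

    a: float
    b: float
    d: float
    r2: float
    n_iterations: int
    converged: bool
    residual_ss: float
    n: int
    degenerate: bool = False

    def predict(self, x: ArrayLike) -> NDArray[np.float64]:
        x_arr = np.asarray(x, dtype=float)
        return (self.a + self.b / x_arr) ** 2 + self.d

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SMAFit:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CommonSlopeTest:
    """Likelihood-ratio test of a shared SMA slope across groups."""

    statistic: float
    p_value: float
    common_slope: float
    df: int
    n_groups: int
    method: str  # "chi2" or "permutation"
    n_permutations: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_xy(x: ArrayLike, y: ArrayLike, min_n: int = 3):
    x_arr = np.asarray(x, dtype=float).ravel()
    y_arr = np.asarray(y, dtype=float).ravel()
    if x_arr.shape != y_arr.shape:
        raise ValueError("x and y must have the same length")
    if x_arr.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x_arr.size}")
    if not (np.all(np.isfinite(x_arr)) and np.all(np.isfinite(y_arr))):
        raise ValueError("x and y must be finite")
    return x_arr, y_arr


def _column(X: ArrayLike) -> NDArray[np.float64]:
    """Accept a 1-D array or an (n, 1) design matrix; return 1-D."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2:
        if arr.shape[1] != 1:
            raise ValueError("these estimators take a single predictor column")
        arr = arr[:, 0]
    return arr


# --------------------------------------------------------------------------
# ordinary least squares


class LinearOLS(BaseEstimator, RegressorMixin):
    """Closed-form simple linear regression with slope inference.

    Fitted attributes: ``slope_``, ``intercept_``, ``slope_se_``,
    ``intercept_se_``, ``r2_``, ``p_slope_``, ``n_``, ``residuals_``.
    """

    def fit(self, X: ArrayLike, y: ArrayLike) -> "LinearOLS":
        x_arr, y_arr = _validate_xy(_column(X), y)
        n = x_arr.size
        xm, ym = x_arr.mean(), y_arr.mean()
        sxx = float(((x_arr - xm) ** 2).sum())
        if sxx == 0.0:
            raise ValueError("degenerate predictor: zero variance in x")
        sxy = float(((x_arr - xm) * (y_arr - ym)).sum())
        slope = sxy / sxx
        intercept = ym - slope * xm
        resid = y_arr - (intercept + slope * x_arr)
        ss_res = float((resid**2).sum())
        ss_tot = float(((y_arr - ym) ** 2).sum())
        df = n - 2
        mse = ss_res / df if df > 0 else np.nan
        slope_se = float(np.sqrt(mse / sxx))
        intercept_se = float(np.sqrt(mse * (1.0 / n + xm**2 / sxx)))
        if slope_se > 0:
            t_stat = slope / slope_se
            p_slope = float(2.0 * stats.t.sf(abs(t_stat), df))
        else:  # exact fit: zero residual variance
            p_slope = 0.0 if slope != 0.0 else 1.0
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.slope_se_ = slope_se
        self.intercept_se_ = intercept_se
        self.r2_ = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
        self.p_slope_ = p_slope
        self.n_ = n
        self.residuals_ = resid
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        return self.intercept_ + self.slope_ * _column(X)

    def result(self) -> LinearFit:
        return LinearFit(
            slope=self.slope_,
            intercept=self.intercept_,
            slope_se=self.slope_se_,
            intercept_se=self.intercept_se_,
            r2=self.r2_,
            p_slope=self.p_slope_,
            n=self.n_,
        )


def ols_fit(x: ArrayLike, y: ArrayLike) -> LinearFit:
    """OLS of ``y`` on ``x``; see :class:`LinearOLS`."""
    return LinearOLS().fit(x, y).result()


def fit_anatomy_allometry(
    x: ArrayLike, ttos: ArrayLike
) -> tuple[AllometryParams, LinearFit]:
    """OLS of tToS on diameter, packaged as allometry parameters.

    The fitted slope becomes ``k`` and the intercept ``c`` of the
    tToS-diameter line, ready to predict PRS curves.  A fitted slope
    outside (0, 0.5) — anatomically impossible under the cylinder model —
    raises rather than returning unusable parameters.
    """
    fit = ols_fit(x, ttos)
    return AllometryParams(k=fit.slope, c=fit.intercept), fit


# --------------------------------------------------------------------------
# allometry-form nonlinear least squares


class AllometricCurve(BaseEstimator, RegressorMixin):
    """NLS fit of the allometry-form curve ``y = (a + b/x)**2 + d``.

    Levenberg-Marquardt with analytic Jacobian, started from a grid of
    ``n_starts`` points spanning both signs and two magnitudes of ``b``
    and two offsets ``d`` (the residual surface has a sign symmetry and a
    shallow valley in ``d``, so a single start is unreliable).  Convergence
    tolerance 1e-10 on the relative reduction of the sum of squares,
    at most ``max_iter`` function evaluations per start.

    Parameters
    ----------
    n_starts : int
        Size of the multi-start grid (default 8).
    tol : float
        ``ftol`` for the underlying least-squares solver.
    max_iter : int
        Maximum function evaluations per start.

    Fitted attributes: ``a_``, ``b_``, ``d_``, ``r2_``, ``n_iter_``,
    ``converged_``, ``residual_ss_``, ``degenerate_``, ``n_``.
    """

    _MIN_N = 10

    def __init__(
        self,
        n_starts: int = 8,
        tol: float = 1e-10,
        max_iter: int = 500,
        fix_b: float | None = None,
    ):
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.fix_b = fix_b

    @staticmethod
    def _model(theta, x):
        a, b, d = theta
        return (a + b / x) ** 2 + d

    @staticmethod
    def _residuals(theta, x, y):
        return AllometricCurve._model(theta, x) - y

    @staticmethod
    def _jacobian(theta, x, y):
        a, b, _ = theta
        base = 2.0 * (a + b / x)
        return np.column_stack([base, base / x, np.ones_like(x)])

    def _starts(self, x, y) -> list[NDArray[np.float64]]:
        d0 = float(np.min(y))
        spread = float(np.mean(y) - d0)
        a0 = float(np.sqrt(max(spread, 1e-6)))
        xs = float(np.median(x))
        starts = []
        for d_start in (d0, 0.0):
            for scale in (0.1, 1.0):
                for sign in (1.0, -1.0):
                    starts.append(np.array([a0, sign * scale * a0 * xs, d_start]))
        return starts[: max(self.n_starts, 1)]

    @staticmethod
    def _cubic_projection(x, y):
        """Least squares on the expanded basis {1, 1/x, 1/x^2}.

        The curve family expands exactly to c0 + c1/x + c2/x^2 with the
        single constraint c2 = b^2 >= 0, so this unconstrained fit gives
        (i) a strict lower bound on the attainable residual SS and (ii),
        whenever c2 > 0, the global optimum itself, mapped back through
        b = sqrt(c2), a = c1/(2b), d = c0 - a^2.
        """
        A = np.column_stack([np.ones_like(x), 1.0 / x, 1.0 / x**2])
        c, *_ = np.linalg.lstsq(A, y, rcond=None)
        ss3 = float(((A @ c - y) ** 2).sum())
        theta = None
        boundary = c[2] <= 0
        if not boundary:
            b = float(np.sqrt(c[2]))
            a = float(c[1] / (2.0 * b))
            if a < 0:
                a, b = -a, -b
            theta = np.array([a, b, float(c[0] - a**2)])
            ss_attainable = ss3
        else:
            # in-family infimum sits on the b -> 0 boundary: c2 = 0.  It
            # is approached (a -> inf with 2ab fixed) but never attained,
            # so the fit there is flagged ridge-degenerate; a large-a
            # point far down the ridge serves as the start.
            A2 = A[:, :2]
            c2, *_ = np.linalg.lstsq(A2, y, rcond=None)
            ss_attainable = float(((A2 @ c2 - y) ** 2).sum())
            scale = float(np.sqrt(np.mean(y**2))) or 1.0
            a = 2000.0 * scale
            theta = np.array([a, float(c2[1]) / (2.0 * a), float(c2[0]) - a**2])
        return theta, ss_attainable, boundary

    def fit(self, X: ArrayLike, y: ArrayLike) -> "AllometricCurve":
        x_arr, y_arr = _validate_xy(_column(X), y, min_n=self._MIN_N)
        if np.any(x_arr <= 0):
            raise ValueError("x must be strictly positive")
        n = x_arr.size
        ss_tot = float(((y_arr - y_arr.mean()) ** 2).sum())
        if ss_tot == 0.0:
            # constant response: d = mean(y); a, b unidentified
            self.a_, self.b_, self.d_ = 0.0, 0.0, float(y_arr.mean())
            self.r2_ = float("nan")
            self.n_iter_ = 0
            self.converged_ = True
            self.degenerate_ = True
            self.residual_ss_ = 0.0
            self.n_ = n
            return self

        if self.fix_b is not None:
            return self._fit_fixed_b(x_arr, y_arr, ss_tot)

        theta_exact, ss_lb, boundary = self._cubic_projection(x_arr, y_arr)
        starts = self._starts(x_arr, y_arr)
        if theta_exact is not None:
            starts.insert(0, theta_exact)
        best = None
        best_ss = np.inf
        best_status = 0
        total_nfev = 0
        for theta0 in starts:
            try:
                res = optimize.least_squares(
                    self._residuals,
                    theta0,
                    jac=self._jacobian,
                    args=(x_arr, y_arr),
                    method="lm",
                    ftol=self.tol,
                    xtol=self.tol,
                    gtol=self.tol,
                    max_nfev=self.max_iter,
                )
            except Exception:
                continue
            total_nfev += res.nfev
            ss = float(2.0 * res.cost)
            if ss < best_ss:
                best_ss = ss
                best = res
                best_status = res.status
        if best is None:
            self.a_ = self.b_ = self.d_ = float("nan")
            self.r2_ = float("nan")
            self.n_iter_ = total_nfev
            self.converged_ = False
            self.degenerate_ = False
            self.residual_ss_ = float("nan")
            self.n_ = n
            return self

        a, b, d = best.x
        if a < 0:  # resolve the (a, b) <-> (-a, -b) symmetry
            a, b = -a, -b
        # global-optimality certificate: the expanded-basis SS bounds any
        # in-family fit from below, so sitting on it proves convergence
        # even when the solver stops on the iteration cap (the b -> 0
        # ridge, where the optimum is approached but never attained).
        at_optimum = best_ss <= ss_lb * (1.0 + 1e-4) + 1e-12
        self.a_, self.b_, self.d_ = float(a), float(b), float(d)
        self.residual_ss_ = best_ss
        self.r2_ = float(1.0 - best_ss / ss_tot)
        self.n_iter_ = total_nfev
        self.converged_ = bool((best_status > 0 and not boundary) or at_optimum)
        self.degenerate_ = bool(boundary)
        self.n_ = n
        return self

    def _fit_fixed_b(self, x_arr, y_arr, ss_tot) -> "AllometricCurve":
        """Profile fit with b frozen (mainly b = 0: a shifted constant)."""
        b0 = float(self.fix_b)

        def residuals(theta):
            a, d = theta
            return (a + b0 / x_arr) ** 2 + d - y_arr

        res = optimize.least_squares(
            residuals,
            np.array([0.0, float(y_arr.mean())]),
            method="lm",
            ftol=self.tol,
            xtol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iter,
        )
        a, d = res.x
        if a < 0:
            a = -a
            b0 = -b0
        ss = float(2.0 * res.cost)
        self.a_, self.b_, self.d_ = float(a), b0, float(d)
        self.residual_ss_ = ss
        self.r2_ = float(1.0 - ss / ss_tot)
        self.n_iter_ = int(res.nfev)
        self.converged_ = bool(res.status > 0)
        self.degenerate_ = False
        self.n_ = x_arr.size
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        x_arr = _column(X)
        return (self.a_ + self.b_ / x_arr) ** 2 + self.d_

    def result(self) -> NonlinearFit:
        return NonlinearFit(
            a=self.a_,
            b=self.b_,
            d=self.d_,
            r2=self.r2_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            residual_ss=self.residual_ss_,
            n=self.n_,
            degenerate=self.degenerate_,
        )


def nls_allometric_fit(x: ArrayLike, y: ArrayLike, **kwargs) -> NonlinearFit:
    """Fit ``y = (a + b/x)**2 + d``; see :class:`AllometricCurve`."""
    return AllometricCurve(**kwargs).fit(x, y).result()


# --------------------------------------------------------------------------
# standardized major axis


class StandardizedMajorAxis(BaseEstimator):
    """SMA line fitting with the likelihood-based slope interval.

    The SMA slope is ``sign(cor(x, y)) * sd(y) / sd(x)``; unlike OLS it is
    symmetric in x and y (swapping them inverts the slope), which is why it
    is the standard tool for comparing allometric slopes.  The confidence
    interval follows the usual construction from the correlation:
    ``B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2)`` and
    ``slope * (sqrt(B + 1) ± sqrt(B))``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: ArrayLike, y: ArrayLike) -> "StandardizedMajorAxis":
        x_arr, y_arr = _validate_xy(_column(X), y)
        n = x_arr.size
        sx = float(x_arr.std(ddof=1))
        sy = float(y_arr.std(ddof=1))
        if sx == 0.0 or sy == 0.0:
            raise ValueError("zero variance in x or y")
        r = float(np.corrcoef(x_arr, y_arr)[0, 1])
        sign = 1.0 if r >= 0 else -1.0
        slope = sign * sy / sx
        intercept = float(y_arr.mean() - slope * x_arr.mean())
        b_term = (
            stats.f.ppf(1.0 - self.alpha, 1, n - 2) * (1.0 - r**2) / (n - 2)
        )
        lo = slope * (np.sqrt(b_term + 1.0) - np.sqrt(b_term))
        hi = slope * (np.sqrt(b_term + 1.0) + np.sqrt(b_term))
        self.slope_ = float(slope)
        self.intercept_ = intercept
        self.slope_ci_low_ = float(min(lo, hi))
        self.slope_ci_high_ = float(max(lo, hi))
        self.correlation_ = r
        self.n_ = n
        return self

    def result(self) -> SMAFit:
        return SMAFit(
            slope=self.slope_,
            intercept=self.intercept_,
            slope_ci_low=self.slope_ci_low_,
            slope_ci_high=self.slope_ci_high_,
            n=self.n_,
        )


def sma_fit(x: ArrayLike, y: ArrayLike, alpha: float = 0.05) -> SMAFit:
    """SMA fit of y on x; see :class:`StandardizedMajorAxis`."""
    return StandardizedMajorAxis(alpha=alpha).fit(x, y).result()


def _sma_lr_statistic(
    groups: Sequence[tuple[NDArray[np.float64], NDArray[np.float64]]],
    slope: float,
) -> float:
    """-sum (n_i - 2.5) log(1 - r_i^2) at a candidate common slope.

    ``r_i`` is the within-group correlation between the residual axis
    ``y - slope*x`` and the fitted axis ``y + slope*x``: under a shared
    SMA slope these axes are uncorrelated in every group.  The n - 2.5
    factor is the standard small-sample (Bartlett-type) correction.
    """
    stat = 0.0
    for x_arr, y_arr in groups:
        u = y_arr - slope * x_arr
        v = y_arr + slope * x_arr
        su, sv = u.std(ddof=1), v.std(ddof=1)
        if su == 0.0 or sv == 0.0:
            continue
        r = np.corrcoef(u, v)[0, 1]
        r2 = min(r * r, 1.0 - 1e-15)
        stat += -(x_arr.size - 2.5) * np.log1p(-r2)
    return float(stat)


def sma_common_slope_test(
    groups: Sequence[tuple[ArrayLike, ArrayLike]],
    n_permutations: int = 999,
    seed: int | None = None,
    force_permutation: bool | None = None,
) -> CommonSlopeTest:
    """Likelihood-ratio test of a common SMA slope across groups.

    The common slope minimizes the LR statistic; under the null of equal
    slopes the minimized statistic is asymptotically chi-squared with
    ``n_groups - 1`` degrees of freedom.  When any group has fewer than 20
    observations the chi-squared approximation is poor, so the p-value
    falls back to a permutation null built by shuffling group labels
    (seeded, ``n_permutations >= 999`` recommended).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = []
    for i, (gx, gy) in enumerate(groups):
        x_arr, y_arr = _validate_xy(np.asarray(gx), gy)
        if x_arr.std(ddof=1) == 0.0 or y_arr.std(ddof=1) == 0.0:
            raise ValueError(f"group {i} is degenerate (zero variance)")
        clean.append((x_arr, y_arr))

    def minimized_stat(gs):
        slopes = [sma_fit(gx, gy).slope for gx, gy in gs]
        lo, hi = min(slopes), max(slopes)
        if lo == hi:
            return _sma_lr_statistic(gs, lo), lo
        res = optimize.minimize_scalar(
            lambda b: _sma_lr_statistic(gs, b),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.fun), float(res.x)

    stat, common = minimized_stat(clean)
    df = len(clean) - 1
    min_n = min(x_arr.size for x_arr, _ in clean)
    use_perm = force_permutation if force_permutation is not None else min_n < 20
    if not use_perm:
        p = float(stats.chi2.sf(stat, df))
        return CommonSlopeTest(
            statistic=stat, p_value=p, common_slope=common, df=df,
            n_groups=len(clean), method="chi2",
        )
    rng = np.random.default_rng(seed)
    pooled_x = np.concatenate([g[0] for g in clean])
    pooled_y = np.concatenate([g[1] for g in clean])
    sizes = [g[0].size for g in clean]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled_x.size)
        gs, start = [], 0
        for sz in sizes:
            idx = perm[start : start + sz]
            gs.append((pooled_x[idx], pooled_y[idx]))
            start += sz
        try:
            perm_stat, _ = minimized_stat(gs)
        except ValueError:
            continue
        if perm_stat >= stat:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return CommonSlopeTest(
        statistic=stat, p_value=p, common_slope=common, df=df,
        n_groups=len(clean), method="permutation",
        n_permutations=n_permutations,
    )
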