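"""Error-rate estimators on (n, s) shadow pairs.

Two routes from the read-shadow relationship to a per-sample error rate:

* **SRER** — robust (Huber) linear regression of shadows on error-free
  counts, ``s = alpha + beta * n + eps``; the rate is ``beta / (1 + beta)``.
* **EER** — a cubic (or iteratively reweighted robust) smoothing spline
  ``S(n)`` fitted by minimizing the penalized residual sum of squares
  ``sum_i (s_i - S(n_i))^2 + lambda * int S''(n)^2 dn``; the per-read error
  rate at count x is the ratio of cumulative fitted shadows to cumulative
  fitted shadows plus cumulative error-free counts over observations with
  n_j <= x, and the sample-level EER is the median of that rate over 1000
  counts drawn uniformly from [n_1, n_m].

The spline solver is the classic Reinsch banded algorithm for the weighted
natural cubic smoothing spline; "auto" smoothing selects lambda by
generalized cross-validation, with the hat-matrix trace obtained from the
Takahashi band-inverse recursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import CubicSpline
from scipy.linalg import cholesky_banded, solve_banded, solveh_banded
from scipy.optimize import minimize_scalar

from .shadows import ShadowPairs

__all__ = [
    "LinearFit",
    "SplineConfig",
    "FittedCurve",
    "ErrorRateEstimate",
    "fit_shadow_linear",
    "srer",
    "fit_cubic_spline",
    "fit_robust_spline",
    "per_read_error_rate",
    "sample_eer",
]


@dataclass
class LinearFit:
    """Huber robust-regression line s = intercept + slope * n."""

    intercept: float
    slope: float
    converged: bool = True
    iterations: int = 0


@dataclass
class SplineConfig:
    """Tuning knobs for the smoothing-spline fits.

    ``lam`` is the roughness penalty weight (units: shadows^2 * reads^3);
    "auto" selects it by generalized cross-validation.  ``residual_floor``
    bounds the robust weights 1/|residual| away from infinity; ``None``
    means 1e-6 times the shadow-count range.
    """

    method: str = "cubic"
    lam: Union[float, str] = "auto"
    max_iter: int = 50
    tol: float = 1e-6
    residual_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in ("cubic", "robust"):
            raise ValueError(f"unknown spline method {self.method!r}")
        if isinstance(self.lam, str):
            if self.lam != "auto":
                raise ValueError("lam must be a non-negative number or 'auto'")
        elif self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.residual_floor is not None and self.residual_floor <= 0:
            raise ValueError("residual_floor must be positive")


class FittedCurve:
    """A fitted shadow-vs-count curve S(n) with two continuous derivatives.

    Evaluation is restricted to the observed range [n_1, n_m].  ``fitted``
    holds S at every observed n_i (ties included), in the pairs' order.
    """

    def __init__(
        self,
        method: str,
        lam: Union[float, str],
        lam_value: float,
        knots: np.ndarray,
        values: np.ndarray,
        fitted: np.ndarray,
        converged: bool = True,
        iterations: int = 0,
    ):
        self.method = method
        self.lam = lam
        self.lam_value = float(lam_value)
        self.converged = converged
        self.iterations = iterations
        self.fitted = np.asarray(fitted, dtype=float)
        self._x_min = float(knots[0])
        self._x_max = float(knots[-1])
        # the minimizer of the penalized criterion is the natural cubic
        # spline interpolating its own fitted values at the design points
        self._spline = CubicSpline(knots, values, bc_type="natural")

    @property
    def domain(self) -> tuple[float, float]:
        return (self._x_min, self._x_max)

    def __call__(self, x, nu: int = 0) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < self._x_min) or np.any(x > self._x_max):
            raise ValueError(
                f"evaluation outside the fitted range [{self._x_min}, {self._x_max}]"
            )
        return self._spline(x, nu=nu)


@dataclass
class ErrorRateEstimate:
    """Per-sample error rates and, for simulations, their absolute biases."""

    srer: Optional[float] = None
    eer_cs: Optional[float] = None
    eer_rs: Optional[float] = None
    expected_er: Optional[float] = None
    per_count_samples: dict = field(default_factory=dict)
    biases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("srer", "eer_cs", "eer_rs", "expected_er"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")

    def compute_biases(self) -> None:
        if self.expected_er is None:
            return
        for name in ("srer", "eer_cs", "eer_rs"):
            val = getattr(self, name)
            if val is not None:
                self.biases[name] = abs(val - self.expected_er)


# ---------------------------------------------------------------------------
# Robust linear regression -> SRER


def fit_shadow_linear(pairs: ShadowPairs) -> LinearFit:
    """Huber M-estimation fit of s on n (tuning constant 1.345, MAD scale).

    Iterated to relative coefficient change < 1e-8 or 100 iterations.
    Noiseless collinear data short-circuits to the exact least-squares line
    (a fixed point of the reweighting with zero scale).
    """
    n, s = pairs.n, pairs.s
    if pairs.m < 3:
        raise ValueError("need at least 3 observations for the linear fit")
    if np.ptp(n) == 0:
        raise ValueError("degenerate design: all error-free counts are equal")
    X = sm.add_constant(n)
    ols = sm.OLS(s, X).fit()
    resid_scale = max(1.0, float(np.abs(s).max()))
    if np.abs(ols.resid).max() <= 1e-10 * resid_scale:
        return LinearFit(float(ols.params[0]), float(ols.params[1]), True, 0)
    rlm = sm.RLM(s, X, M=sm.robust.norms.HuberT(t=1.345))
    res = rlm.fit(maxiter=100, tol=1e-8, conv="coefs")
    iterations = len(res.fit_history.get("params", [])) or 0
    converged = iterations < 100
    if not converged:
        warnings.warn("robust linear regression did not converge; last iterate returned")
    return LinearFit(float(res.params[0]), float(res.params[1]), converged, iterations)


def srer(fit: LinearFit) -> float:
    """Shadow-regression error rate beta/(1+beta); negative slopes clamp to 0."""
    beta = max(fit.slope, 0.0)
    return beta / (1.0 + beta)


# ---------------------------------------------------------------------------
# Weighted natural cubic smoothing spline (Reinsch algorithm)


def _reinsch_system(x: np.ndarray, w: np.ndarray, lam: float):
    """Banded matrices of the Reinsch formulation.

    Returns (ab, q0, q1, q2, R0, R1) where ab is A = R + lam * Qt W^-1 Q in
    upper banded form, Q the second-difference matrix and R the penalty
    Gram matrix of the natural spline basis.
    """
    h = np.diff(x)
    inv_h = 1.0 / h
    winv = 1.0 / w
    mm = x.size - 2
    q0 = inv_h[:-1]
    q1 = -(inv_h[:-1] + inv_h[1:])
    q2 = inv_h[1:]
    B0 = q0**2 * winv[:-2] + q1**2 * winv[1:-1] + q2**2 * winv[2:]
    R0 = (h[:-1] + h[1:]) / 3.0
    R1 = h[1:-1] / 6.0
    ab = np.zeros((3, mm))
    ab[2] = R0 + lam * B0
    if mm > 1:
        B1 = q1[:-1] * q0[1:] * winv[1:-2] + q2[:-1] * q1[1:] * winv[2:-1]
        ab[1, 1:] = R1 + lam * B1
    if mm > 2:
        B2 = q2[:-2] * q0[2:] * winv[2:-2]
        ab[0, 2:] = lam * B2
    return ab, q0, q1, q2, R0, R1


def _solve_spd_banded(ab: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve the SPD pentadiagonal system; LU fallback when extreme
    penalty/spacing ratios defeat the Cholesky factorization."""
    try:
        return solveh_banded(ab, rhs)
    except np.linalg.LinAlgError:
        n = ab.shape[1]
        full = np.zeros((5, n))
        full[0] = ab[0]
        full[1] = ab[1]
        full[2] = ab[2]
        full[3, :-1] = ab[1, 1:]
        full[4, :-2] = ab[0, 2:]
        return solve_banded((2, 2), full, rhs)


def _spline_fit_values(x: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Fitted values of the weighted natural cubic smoothing spline."""
    if lam == 0.0:
        return y.copy()
    ab, q0, q1, q2, _, _ = _reinsch_system(x, w, lam)
    qty = q0 * y[:-2] + q1 * y[1:-1] + q2 * y[2:]
    gamma = _solve_spd_banded(ab, qty)
    Qg = np.zeros_like(y)
    Qg[:-2] += q0 * gamma
    Qg[1:-1] += q1 * gamma
    Qg[2:] += q2 * gamma
    return y - lam * Qg / w


def _band_inverse_diags(ab: np.ndarray):
    """Central three bands of inv(A) for SPD pentadiagonal A (upper banded form).

    Takahashi recursion on the banded LDL^T factor; O(m)."""
    n = ab.shape[1]
    U = cholesky_banded(ab)
    d = U[2] ** 2
    l1 = np.zeros(n)
    l2 = np.zeros(n)
    l1[: n - 1] = U[1, 1:] / U[2, : n - 1]
    l2[: n - 2] = U[0, 2:] / U[2, : n - 2]
    z0 = np.zeros(n)
    z1 = np.zeros(n)
    z2 = np.zeros(n)
    for i in range(n - 1, -1, -1):
        a1 = l1[i]
        a2 = l2[i]
        if i + 2 < n:
            z2[i] = -(a1 * z1[i + 1] + a2 * z0[i + 2])
        if i + 1 < n:
            t = a1 * z0[i + 1]
            if i + 2 < n:
                t += a2 * z1[i + 1]
            z1[i] = -t
        t = 1.0 / d[i]
        if i + 1 < n:
            t -= a1 * z1[i]
        if i + 2 < n:
            t -= a2 * z2[i]
        z0[i] = t
    return z0, z1, z2


def _gcv_score(x: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> float:
    m = x.size
    ab, q0, q1, q2, R0, R1 = _reinsch_system(x, w, lam)
    qty = q0 * y[:-2] + q1 * y[1:-1] + q2 * y[2:]
    try:
        gamma = solveh_banded(ab, qty)
    except np.linalg.LinAlgError:
        return np.inf
    Qg = np.zeros_like(y)
    Qg[:-2] += q0 * gamma
    Qg[1:-1] += q1 * gamma
    Qg[2:] += q2 * gamma
    f = y - lam * Qg / w
    rss = float(np.sum(w * (y - f) ** 2))
    # trace of the hat matrix: 2 + tr(A^-1 R)
    try:
        z0, z1, _ = _band_inverse_diags(ab)
    except np.linalg.LinAlgError:
        return np.inf
    tr = float(np.sum(z0 * R0))
    if R1.size:
        tr += 2.0 * float(np.sum(z1[:-1] * R1))
    tr_h = 2.0 + tr
    denom = 1.0 - tr_h / m
    if denom <= 1e-12:
        return np.inf
    return (rss / m) / denom**2


def _select_lambda_gcv(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Minimize the GCV score over a broad log-spaced lambda range."""
    scale = float(np.ptp(x)) ** 3
    grid = np.logspace(-8, 2, 13) * scale
    scores = [_gcv_score(x, y, w, lam) for lam in grid]
    best = int(np.argmin(scores))
    lo = np.log10(grid[max(best - 1, 0)])
    hi = np.log10(grid[min(best + 1, len(grid) - 1)])
    res = minimize_scalar(
        lambda t: _gcv_score(x, y, w, 10.0**t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(10.0**res.x)


def _collapse_ties(n: np.ndarray, s: np.ndarray, obs_weights: np.ndarray):
    """Group equal n; the solver sees each distinct n once with the
    weight-sum and weighted-mean shadow count of its group."""
    x, inverse = np.unique(n, return_inverse=True)
    wsum = np.bincount(inverse, weights=obs_weights)
    ymean = np.bincount(inverse, weights=obs_weights * s) / wsum
    return x, ymean, wsum, inverse


def _fit_spline_once(
    pairs: ShadowPairs, lam: Union[float, str], obs_weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    x, ymean, wsum, inverse = _collapse_ties(pairs.n, pairs.s, obs_weights)
    if x.size < 4:
        raise ValueError(
            f"only {x.size} distinct n values; the smoothing spline needs >= 4 "
            "(consider the linear shadow-regression model instead)"
        )
    lam_value = _select_lambda_gcv(x, ymean, wsum) if lam == "auto" else float(lam)
    values = _spline_fit_values(x, ymean, wsum, lam_value)
    return x, values, values[inverse], lam_value, inverse


def fit_cubic_spline(pairs: ShadowPairs, config: Optional[SplineConfig] = None) -> FittedCurve:
    """Natural cubic smoothing spline of s on n.

    Minimizes ``sum (s_i - S(n_i))^2 + lam * int S''^2``; ties in n are
    collapsed to their mean with multiplicity weights, which leaves the
    criterion unchanged.  ``lam="auto"`` selects by generalized
    cross-validation.
    """
    config = config or SplineConfig(method="cubic")
    weights = np.ones(pairs.m)
    x, values, fitted, lam_value, _ = _fit_spline_once(pairs, config.lam, weights)
    return FittedCurve("cubic", config.lam, lam_value, x, values, fitted)


def fit_robust_spline(pairs: ShadowPairs, config: Optional[SplineConfig] = None) -> FittedCurve:
    """Iteratively reweighted smoothing spline, weights 1/|residual|.

    Starts from the plain cubic fit, then re-fits with per-observation
    weights ``1 / max(|s_i - S(n_i)|, delta)`` until the fitted values move
    by less than ``config.tol`` (relative) or ``config.max_iter`` is hit.
    The residual floor delta defaults to 1e-6 times the shadow-count range.
    When smoothing is "auto", lambda is chosen by GCV on the initial fit
    and held fixed through the reweighting.
    """
    config = config or SplineConfig(method="robust")
    n, s = pairs.n, pairs.s
    delta = config.residual_floor
    if delta is None:
        span = float(np.ptp(s))
        delta = 1e-6 * (span if span > 0 else 1.0)

    weights = np.ones(pairs.m)
    x, values, fitted, lam_value, inverse = _fit_spline_once(pairs, config.lam, weights)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        resid = s - fitted
        weights = 1.0 / np.maximum(np.abs(resid), delta)
        x, values, new_fitted, _, inverse = _fit_spline_once(pairs, lam_value, weights)
        denom = max(float(np.abs(fitted).max()), 1e-12)
        rel_change = float(np.abs(new_fitted - fitted).max()) / denom
        fitted = new_fitted
        if rel_change < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn("robust spline did not converge; last iterate returned")
    return FittedCurve("robust", config.lam, lam_value, x, values, fitted, converged, iterations)


# ---------------------------------------------------------------------------
# Per-read and sample-level error rates


def _cumulative_rates(curve: FittedCurve, pairs: ShadowPairs):
    s_hat = np.clip(curve.fitted, 0.0, None)
    cum_s = np.cumsum(s_hat)
    cum_n = np.cumsum(pairs.n)
    return cum_s / (cum_s + cum_n)


def per_read_error_rate(curve: FittedCurve, pairs: ShadowPairs, x: float) -> float:
    """ER(x) = sum of fitted shadows over sum of fitted shadows plus
    error-free counts, cumulated over observations with n_j <= x.

    Fitted shadow counts are clamped at zero before summation; the result
    is always in [0, 1).  ``x`` must lie within [n_1, n_m].
    """
    n = pairs.n
    if x < n[0] or x > n[-1]:
        raise ValueError(f"x={x} outside the observed count range [{n[0]}, {n[-1]}]")
    rates = _cumulative_rates(curve, pairs)
    t = int(np.searchsorted(n, x, side="right"))
    return float(rates[t - 1])


def sample_eer(
    curve: FittedCurve,
    pairs: ShadowPairs,
    draws: int = 1000,
    rng=None,
    scheme: str = "integer-range",
) -> tuple[float, list[tuple[float, float]]]:
    """Sample-level empirical error rate: median of ER at random counts.

    Draws ``draws`` counts from [n_1, n_m] — uniformly over the integers in
    that range by default, or resampling the observed counts with
    ``scheme="observed"`` — evaluates the per-read error rate at each, and
    returns the median (midpoint convention) with the sample list.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(rng)
    n = pairs.n
    if scheme == "integer-range":
        lo = int(np.ceil(n[0]))
        hi = int(np.floor(n[-1]))
        if hi >= lo:
            xs = rng.integers(lo, hi + 1, size=draws).astype(float)
        else:  # no integer inside a narrow continuous range
            xs = rng.uniform(n[0], n[-1], size=draws)
    elif scheme == "observed":
        xs = rng.choice(n, size=draws, replace=True)
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    rates = _cumulative_rates(curve, pairs)
    t = np.searchsorted(n, xs, side="right")
    ers = rates[t - 1]
    return float(np.median(ers)), list(zip(xs.tolist(), ers.tolist()))
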