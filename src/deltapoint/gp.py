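"""Gaussian-process time-series (GPTS) predictive model.

The model is ``y_t = f(t) + eps_t`` with ``f ~ GP(0, k)`` and
``eps_t ~ N(0, sigma^2)``; the kernel ``k`` is the rational quadratic

    k(t, t') = s^2 * (1 + |t - t'|^2 / (2 * alpha * ell^2)) ** (-alpha)

on *time indices*.  ``alpha`` is the scale-mixture shape (``alpha -> inf``
recovers the squared exponential), ``ell`` the input length scale, ``s^2`` the
signal variance and ``sigma^2`` the observation-noise variance.

The one-step-ahead predictive distribution of the next observation given the
observations since the last change point is Gaussian,

    mu    = k_*^T (K + sigma^2 I)^{-1} y
    var   = k_** - k_*^T (K + sigma^2 I)^{-1} k_* + sigma^2,

with the noise term included so the predictive scores the *observation* rather
than the latent function value.  Hyperparameters are set by Type-II maximum
likelihood (marginal-likelihood maximisation) on a training prefix with
analytic gradients in log-parameter space.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import linalg, optimize

from .errors import FittingError, NumericalError, ParameterError
from .series import TimeSeries

__all__ = [
    "KernelParams",
    "PredictiveDistribution",
    "rq_kernel",
    "gp_predictive",
    "log_marginal_likelihood",
    "fit_hyperparameters",
    "SegmentPredictorTable",
]

_LOG_2PI = math.log(2.0 * math.pi)
# Bounds for log-space optimisation: every hyperparameter stays in
# [e^-9.2, e^9.2] ~ [1e-4, 1e4], keeping the Gram matrix well conditioned.
_LOG_BOUND = 9.2


@dataclasses.dataclass(frozen=True)
class KernelParams:
    """Rational-quadratic kernel hyperparameters (all strictly positive)."""

    alpha: float = 1.0
    length_scale: float = 1.0
    signal_variance: float = 1.0
    noise_variance: float = 0.1

    def __post_init__(self):
        for name in ("alpha", "length_scale", "signal_variance", "noise_variance"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be a strictly positive real, got {v!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelParams":
        return cls(**{k: float(v) for k, v in d.items()})

    def as_log_vector(self) -> np.ndarray:
        return np.log(
            [self.alpha, self.length_scale, self.signal_variance, self.noise_variance]
        )

    @classmethod
    def from_log_vector(cls, theta: np.ndarray) -> "KernelParams":
        a, l, s, n = np.exp(theta)
        return cls(alpha=float(a), length_scale=float(l),
                   signal_variance=float(s), noise_variance=float(n))


@dataclasses.dataclass(frozen=True)
class PredictiveDistribution:
    """Gaussian one-step-ahead predictive (mean mu_t, variance sigma_t^2)."""

    mean: float
    variance: float

    def logpdf(self, y: float) -> float:
        return -0.5 * ((y - self.mean) ** 2 / self.variance
                       + math.log(self.variance) + _LOG_2PI)


def _rq_of_sqdist(d2: np.ndarray, params: KernelParams) -> np.ndarray:
    """Kernel value from squared distance, stable for very large alpha."""
    q = d2 / (2.0 * params.alpha * params.length_scale ** 2)
    return params.signal_variance * np.exp(-params.alpha * np.log1p(q))


def rq_kernel(t1: float, t2: float, params: KernelParams) -> float:
    """Rational quadratic covariance between two time indices."""
    return float(_rq_of_sqdist(np.asarray((t1 - t2) ** 2, dtype=float), params))


def _gram(times: np.ndarray, params: KernelParams) -> np.ndarray:
    d = times[:, None] - times[None, :]
    return _rq_of_sqdist(d.astype(float) ** 2, params)


def _cross(times: np.ndarray, t_new: float, params: KernelParams) -> np.ndarray:
    return _rq_of_sqdist((times.astype(float) - t_new) ** 2, params)


def gp_predictive(
    segment: TimeSeries, next_time: int, params: KernelParams
) -> PredictiveDistribution:
    """Predictive distribution of ``y_{next_time}`` given a run segment.

    An empty segment returns the prior predictive
    ``N(0, signal_variance + noise_variance)``.
    """
    n = len(segment)
    s2 = params.signal_variance
    sig2 = params.noise_variance
    if n == 0:
        return PredictiveDistribution(0.0, s2 + sig2)
    times = segment.times
    A = _gram(times, params)
    A[np.diag_indices_from(A)] += sig2
    kstar = _cross(times, float(next_time), params)
    try:
        cf = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:  # pragma: no cover - PD for sigma^2 > 0
        raise NumericalError(f"Cholesky factorization failed: {exc}") from exc
    w = linalg.cho_solve(cf, kstar, check_finite=False)
    mean = float(w @ segment.values)
    var = float(s2 - kstar @ w + sig2)
    # Latent variance is >= 0 mathematically; guard round-off.
    var = max(var, sig2)
    return PredictiveDistribution(mean, var)


def log_marginal_likelihood(train: TimeSeries, params: KernelParams) -> float:
    """``log N(y; 0, K + sigma^2 I)`` of a training series."""
    if len(train) == 0:
        raise ParameterError("log marginal likelihood requires a non-empty series")
    A = _gram(train.times, params)
    A[np.diag_indices_from(A)] += params.noise_variance
    try:
        cf = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise NumericalError(f"Cholesky factorization failed: {exc}") from exc
    alpha_vec = linalg.cho_solve(cf, train.values, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    n = len(train)
    return float(-0.5 * train.values @ alpha_vec - 0.5 * logdet - 0.5 * n * _LOG_2PI)


def _nll_and_grad(theta: np.ndarray, times: np.ndarray, y: np.ndarray, d2: np.ndarray):
    """Negative log marginal likelihood and its gradient in log-parameter space.

    Gradient uses d/dtheta_j L = 1/2 tr((aa^T - A^{-1}) dA/dtheta_j) with
    a = A^{-1} y.  Returns a large penalty on factorisation failure so the
    optimiser can back off.
    """
    alpha, ell, s2, sig2 = np.exp(theta)
    n = len(y)
    q = d2 / (2.0 * alpha * ell ** 2)
    log1pq = np.log1p(q)
    K = s2 * np.exp(-alpha * log1pq)
    A = K + sig2 * np.eye(n)
    try:
        cf = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e25, np.zeros(4)
    a = linalg.cho_solve(cf, y, check_finite=False)
    Ainv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    nll = 0.5 * float(y @ a) + 0.5 * logdet + 0.5 * n * _LOG_2PI

    B = np.outer(a, a) - Ainv  # d(lml)/dA kernel-side factor
    u = 1.0 + q
    dK_dlog_alpha = alpha * K * (-log1pq + q / u)
    dK_dlog_ell = K * (2.0 * alpha * q / u)
    dK_dlog_s2 = K
    grad_lml = 0.5 * np.array([
        np.sum(B * dK_dlog_alpha),
        np.sum(B * dK_dlog_ell),
        np.sum(B * dK_dlog_s2),
        sig2 * np.trace(B),
    ])
    return nll, -grad_lml


def fit_hyperparameters(
    train: TimeSeries,
    init: KernelParams | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
) -> KernelParams:
    """Type-II maximum likelihood fit of the kernel hyperparameters.

    Multi-start L-BFGS-B ascent of the log marginal likelihood in log-parameter
    space: the first start is ``init``, the remaining ``n_restarts - 1`` are
    seeded log-normal perturbations of it.  The returned parameters never score
    below ``init`` (monotone-improvement contract) and the whole procedure is
    deterministic given ``seed``.
    """
    if len(train) < 4:
        raise ParameterError("hyperparameter fitting requires at least 4 observations")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    init = init or KernelParams()
    times = train.times.astype(float)
    y = np.asarray(train.values, dtype=float)
    d2 = (times[:, None] - times[None, :]) ** 2

    theta0 = np.clip(init.as_log_vector(), -_LOG_BOUND, _LOG_BOUND)
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(n_restarts - 1):
        starts.append(np.clip(theta0 + rng.normal(0.0, 1.0, size=4),
                              -_LOG_BOUND, _LOG_BOUND))

    bounds = [(-_LOG_BOUND, _LOG_BOUND)] * 4
    best_theta, best_nll = None, np.inf
    n_failed = 0
    for th in starts:
        try:
            res = optimize.minimize(
                _nll_and_grad, th, args=(times, y, d2), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
        except Exception:
            n_failed += 1
            continue
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
            n_failed += 1
            continue
        if res.fun < best_nll:
            best_nll, best_theta = float(res.fun), res.x.copy()
    if best_theta is None:
        raise FittingError(
            "all optimisation restarts failed",
            diagnostics={"n_restarts": n_restarts, "n_failed": n_failed},
        )
    nll_init, _ = _nll_and_grad(theta0, times, y, d2)
    if best_nll > nll_init:
        return KernelParams.from_log_vector(theta0)
    return KernelParams.from_log_vector(best_theta)


class SegmentPredictorTable:
    """Precomputed one-step-ahead predictive weights for unit-spaced runs.

    For a stationary kernel on contiguous integer times, the predictive for a
    run of length ``r`` depends on the times only through ``r``: the Gram
    matrix of the last ``r`` points and the cross-covariances to the next point
    are the same wherever the run sits.  This table therefore precomputes, for
    every ``r`` up to ``max_runlength``,

        w_r = (K_r + sigma^2 I)^{-1} k_*       (weights on the window, oldest first)
        v_r = s^2 - k_*^T w_r + sigma^2        (predictive variance),

    growing the Cholesky factor by one bordered row per ``r`` (O(r^2) each).
    ``mean(r, y_window)`` is then a single dot product, which makes a full
    BOCPD sweep cheap without changing any numbers relative to the dense path.
    """

    def __init__(self, params: KernelParams, max_runlength: int):
        self.params = params
        R = int(max_runlength)
        s2 = params.signal_variance
        sig2 = params.noise_variance
        kvals = _rq_of_sqdist(np.arange(R + 1, dtype=float) ** 2, params)

        L = np.zeros((R, R))
        self.weights: list[np.ndarray] = [np.empty(0)]
        self.variances = np.empty(R + 1)
        self.variances[0] = s2 + sig2
        for r in range(1, R + 1):
            # Border the Cholesky factor with the point at position r-1
            # (times 0..r-1); column against previous points has distances
            # r-1, r-2, ..., 1.
            c = kvals[np.arange(r - 1, 0, -1)]
            if r == 1:
                L[0, 0] = math.sqrt(s2 + sig2)
            else:
                z = linalg.solve_triangular(L[: r - 1, : r - 1], c,
                                            lower=True, check_finite=False)
                d2 = s2 + sig2 - float(z @ z)
                if d2 <= 0:  # pragma: no cover - PD guard
                    raise NumericalError("bordered Cholesky lost positive definiteness")
                L[r - 1, : r - 1] = z
                L[r - 1, r - 1] = math.sqrt(d2)
            # Predict time r from times 0..r-1: distances r, r-1, ..., 1.
            kstar = kvals[np.arange(r, 0, -1)]
            tmp = linalg.solve_triangular(L[:r, :r], kstar, lower=True,
                                          check_finite=False)
            w = linalg.solve_triangular(L[:r, :r], tmp, trans="T", lower=True,
                                        check_finite=False)
            self.weights.append(w)
            self.variances[r] = max(s2 - float(kstar @ w) + sig2, sig2)

    @property
    def max_runlength(self) -> int:
        return len(self.weights) - 1

    def mean(self, r: int, values: np.ndarray, at: int) -> float:
        """Predictive mean for run length ``r`` at positional index ``at``.

        ``values[at - r:at]`` is the conditioning window, oldest first.
        """
        if r == 0:
            return 0.0
        return float(self.weights[r] @ values[at - r:at])
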