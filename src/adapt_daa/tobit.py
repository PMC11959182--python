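"""Left-censored Gaussian (Tobit) regression with Firth penalization.

Each taxon's log-scale abundance quantity (log relative abundance or log
reference-normalized count ratio) is modeled as a linear function of the
sample covariates with Gaussian noise, where values below a known
detection bound are only observed as "censored at the bound".  The
log-likelihood for sample i with response v_i, censoring indicator
delta_i and standardized residual r_i = (v_i - x_i' beta) / sigma is

    delta_i * [log phi(r_i) - log sigma] + (1 - delta_i) * log Phi(r_i).

Rare taxa can exhibit complete separation (detected in one condition
only), under which the unpenalized fold-change estimate diverges.  A
Jeffreys-prior penalty — half the log-determinant of the expected Fisher
information of the censored model, taken jointly over (beta, log sigma) —
keeps estimates finite and tests valid.  Significance of the condition
coefficient is assessed by a likelihood-ratio test against the fit with
that coefficient constrained to zero (penalty dimension unchanged),
referred to a small-sample F calibration of the 1-df chi-square
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from joblib import Parallel, delayed
from scipy import optimize, special, stats

from .data_io import CensoredCountTable, CovariateDesign

__all__ = [
    "TobitConfig",
    "CensoredResponse",
    "TobitFit",
    "tobit_loglik",
    "expected_information",
    "firth_penalty",
    "fit_tobit",
    "fit_all_taxa",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class TobitConfig:
    """Numerical knobs for the censored-regression optimizer."""

    gradient_tol: float = 1e-8
    max_iter: int = 200
    log_sigma_bounds: tuple[float, float] = (-12.0, 12.0)
    #: value returned by the penalty when the information matrix is singular
    singular_guard: float = -1e6


@dataclass
class CensoredResponse:
    """A per-sample log-scale response with left-censoring indicators.

    ``indicators`` is 1 for an observed value, 0 for a value censored below
    ``values`` (which then records the censoring bound).  ``bounds`` gives
    the censoring threshold of *every* sample, observed or not, on the
    response scale; it is what the expected Fisher information integrates
    over.  When omitted, observed samples are treated as uncensorable
    (bound of -inf), which reduces their information contribution to the
    ordinary Gaussian one.
    """

    values: np.ndarray
    indicators: np.ndarray
    bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.indicators = np.asarray(self.indicators, dtype=np.int8)
        if self.values.shape != self.indicators.shape or self.values.ndim != 1:
            raise ValueError("values and indicators must be matching 1-D arrays")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("censored responses must be finite")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)
            if self.bounds.shape != self.values.shape:
                raise ValueError("bounds must match values in shape")

    def filled_bounds(self) -> np.ndarray:
        if self.bounds is not None:
            return self.bounds
        return np.where(self.indicators == 0, self.values, -np.inf)


@dataclass
class TobitFit:
    """Result of one penalized censored-regression fit and its LRT."""

    coefficients: np.ndarray
    scale: float
    penalized_loglik: float
    tested_estimate: float
    lrt_stat: float
    p_value: float
    converged: bool
    iterations: int
    tested_index: int = 1
    error: str | None = None


def _design_matrix(design: CovariateDesign | np.ndarray) -> np.ndarray:
    if isinstance(design, CovariateDesign):
        return design.matrix
    return np.asarray(design, dtype=float)


def tobit_loglik(
    beta: np.ndarray,
    sigma: float,
    resp: CensoredResponse,
    design: CovariateDesign | np.ndarray,
) -> float:
    """Tobit log-likelihood at (beta, sigma).

    Censored terms use an underflow-safe evaluation of log Phi, so the
    value stays finite even for extreme standardized censoring points.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    X = _design_matrix(design)
    beta = np.asarray(beta, dtype=float)
    r = (resp.values - X @ beta) / sigma
    d = resp.indicators
    obs = -0.5 * _LOG_2PI - 0.5 * r * r - np.log(sigma)
    cens = special.log_ndtr(r)
    return float(np.sum(np.where(d == 1, obs, cens)))


def _information_weights(alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-observation expected-information weights at standardized bound alpha.

    In the (mu, sigma) parameterization the information contribution of an
    observation with censoring point alpha is
        I_mumu = w1 / sigma^2,  I_musig = w2 / sigma^2,  I_sigsig = w3 / sigma^2
    with w1 -> 1, w2 -> 0, w3 -> 2 as alpha -> -inf (never censored) and all
    weights -> 0 as alpha -> +inf (always censored).
    """
    alpha = np.asarray(alpha, dtype=float)
    w1 = np.ones_like(alpha)
    w2 = np.zeros_like(alpha)
    w3 = np.full_like(alpha, 2.0)
    finite = np.isfinite(alpha)
    if finite.any():
        a = alpha[finite]
        Phi = special.ndtr(a)
        log_phi = -0.5 * a * a - 0.5 * _LOG_2PI
        phi = np.exp(log_phi)
        # lambda = phi/Phi computed in log space: stable for very negative a
        lam = np.exp(log_phi - special.log_ndtr(a))
        Pq = phi * (a + lam)  # Phi * lambda * (a + lambda)
        w1[finite] = (1.0 - Phi) + Pq
        w2[finite] = phi + a * Pq
        w3[finite] = 2.0 * (1.0 - Phi) + a * phi + a * a * Pq
    return w1, w2, w3


def _information_weights_and_derivs(
    alpha: np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Weights w1..w3 plus their derivatives in alpha.

    With lam the inverse Mills ratio and Pq = phi (alpha + lam), the
    derivative of Pq is phi (1 - (alpha + lam)^2), from which
        w1' = -phi (alpha + lam)^2
        w2' = Pq - alpha phi + alpha Pq'
        w3' = -phi - alpha^2 phi + 2 alpha Pq + alpha^2 Pq'.
    All derivatives vanish where censoring is out of reach.
    """
    alpha = np.asarray(alpha, dtype=float)
    shape = alpha.shape
    w1, w2, w3 = (np.ones(shape), np.zeros(shape), np.full(shape, 2.0))
    d1, d2, d3 = (np.zeros(shape), np.zeros(shape), np.zeros(shape))
    finite = np.isfinite(alpha)
    if finite.any():
        a = alpha[finite]
        Phi = special.ndtr(a)
        log_phi = -0.5 * a * a - 0.5 * _LOG_2PI
        phi = np.exp(log_phi)
        lam = np.exp(log_phi - special.log_ndtr(a))
        al = a + lam
        Pq = phi * al
        dPq = phi * (1.0 - al * al)
        w1[finite] = (1.0 - Phi) + Pq
        w2[finite] = phi + a * Pq
        w3[finite] = 2.0 * (1.0 - Phi) + a * phi + a * a * Pq
        d1[finite] = -phi * al * al
        d2[finite] = Pq - a * phi + a * dPq
        d3[finite] = -phi - a * a * phi + 2.0 * a * Pq + a * a * dPq
    return w1, w2, w3, d1, d2, d3


def expected_information(
    beta: np.ndarray,
    sigma: float,
    resp: CensoredResponse,
    design: CovariateDesign | np.ndarray,
) -> np.ndarray:
    """Expected Fisher information over (beta, log sigma).

    With no censoring in reach this is block-diagonal: X'X/sigma^2 for beta
    and 2n for log sigma.
    """
    X = _design_matrix(design)
    beta = np.asarray(beta, dtype=float)
    alpha = (resp.filled_bounds() - X @ beta) / sigma
    w1, w2, w3 = _information_weights(alpha)
    k = X.shape[1]
    info = np.empty((k + 1, k + 1))
    info[:k, :k] = (X * (w1 / sigma**2)[:, None]).T @ X
    cross = X.T @ (w2 / sigma)
    info[:k, k] = cross
    info[k, :k] = cross
    info[k, k] = float(np.sum(w3))
    return info


def firth_penalty(
    beta: np.ndarray,
    sigma: float,
    resp: CensoredResponse,
    design: CovariateDesign | np.ndarray,
    config: TobitConfig = TobitConfig(),
) -> float:
    """Jeffreys-style penalty: half the log-determinant of the information.

    Returns a large negative guard value (never NaN) when the information
    matrix is numerically singular, so the penalized objective steers away
    from degenerate parameter regions instead of crashing.
    """
    info = expected_information(beta, sigma, resp, design)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        return config.singular_guard
    return 0.5 * float(logdet)


def _penalty_and_grad(
    params: np.ndarray,
    X: np.ndarray,
    resp: CensoredResponse,
    config: TobitConfig,
) -> tuple[float, np.ndarray]:
    """Firth penalty and its analytic gradient over (beta, log sigma).

    Uses d logdet M / d theta = tr(M^-1 dM/d theta); because every block of
    the information is a per-observation sum, each trace collapses to one
    weighted pass over the observations.  A singular information matrix
    returns the guard value with a zero gradient (a flat plateau the
    optimizer immediately leaves).
    """
    k = X.shape[1]
    beta, t = params[:k], params[k]
    sigma = np.exp(t)
    alpha = (resp.filled_bounds() - X @ beta) / sigma
    w1, w2, w3, d1, d2, d3 = _information_weights_and_derivs(alpha)
    sig2 = sigma * sigma
    M = np.empty((k + 1, k + 1))
    M[:k, :k] = (X * (w1 / sig2)[:, None]).T @ X
    cross = X.T @ (w2 / sigma)
    M[:k, k] = cross
    M[k, :k] = cross
    M[k, k] = float(np.sum(w3))
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        return config.singular_guard, np.zeros(k + 1)
    S = np.linalg.inv(M)
    Sbb, Sbt, Stt = S[:k, :k], S[:k, k], S[k, k]
    q = np.einsum("ij,jk,ik->i", X, Sbb, X)  # x_i' Sbb x_i
    u = X @ Sbt
    finite = np.isfinite(alpha)
    a_d1 = np.zeros_like(d1)
    a_d2 = np.zeros_like(d2)
    a_d3 = np.zeros_like(d3)
    a_d1[finite] = alpha[finite] * d1[finite]
    a_d2[finite] = alpha[finite] * d2[finite]
    a_d3[finite] = alpha[finite] * d3[finite]
    g = -(d1 * q) / (sigma * sig2) - 2.0 * d2 * u / sig2 - d3 * Stt / sigma
    grad = np.empty(k + 1)
    grad[:k] = 0.5 * (X.T @ g)
    grad[k] = 0.5 * (
        float(np.sum((-a_d1 - 2.0 * w1) / sig2 * q))
        + 2.0 * float(np.sum((-a_d2 - w2) / sigma * u))
        - float(np.sum(a_d3)) * Stt
    )
    return 0.5 * float(logdet), grad


def _neg_objective_and_grad(
    params: np.ndarray,
    X: np.ndarray,
    resp: CensoredResponse,
    penalized: bool,
    config: TobitConfig,
) -> tuple[float, np.ndarray]:
    """Negative (penalized) log-likelihood and its gradient over (beta, log sigma).

    The likelihood gradient is analytic; the penalty gradient uses central
    differences on the (cheap, low-dimensional) log-determinant.
    """
    k = X.shape[1]
    beta, log_sigma = params[:k], params[k]
    sigma = np.exp(log_sigma)
    v, d = resp.values, resp.indicators
    r = (v - X @ beta) / sigma
    logcdf = special.log_ndtr(r)
    ll = float(
        np.sum(
            np.where(
                d == 1,
                -0.5 * _LOG_2PI - 0.5 * r * r - log_sigma,
                logcdf,
            )
        )
    )
    lam = np.exp(-0.5 * r * r - 0.5 * _LOG_2PI - logcdf)
    score_common = np.where(d == 1, r, -lam)
    grad = np.empty(k + 1)
    grad[:k] = X.T @ score_common / sigma
    grad[k] = float(np.sum(np.where(d == 1, r * r - 1.0, -lam * r)))
    if not penalized:
        return -ll, -grad
    pen0, pgrad = _penalty_and_grad(params, X, resp, config)
    return -(ll + pen0), -(grad + pgrad)


def _start_values(X: np.ndarray, resp: CensoredResponse) -> np.ndarray:
    """Deterministic start: least squares on proxied responses, log residual RMS."""
    beta0, *_ = np.linalg.lstsq(X, resp.values, rcond=None)
    resid = resp.values - X @ beta0
    rms = float(np.sqrt(np.mean(resid**2)))
    log_sigma0 = np.log(max(rms, 1e-3))
    return np.concatenate([beta0, [log_sigma0]])


def _maximize(
    X: np.ndarray,
    resp: CensoredResponse,
    penalized: bool,
    config: TobitConfig,
    start: np.ndarray | None = None,
    fixed_index: int | None = None,
) -> tuple[np.ndarray, float, bool, int]:
    """Maximize the (penalized) log-likelihood; returns (params, value, ok, nit).

    With ``fixed_index`` the corresponding coefficient is pinned to zero
    while the objective (including the penalty's information matrix) keeps
    the full parameterization.  Keeping the penalty dimension identical
    between the full and constrained fits is what makes the penalized
    likelihood-ratio statistic chi-square(1) calibrated.
    """
    k = X.shape[1]
    x0 = _start_values(X, resp) if start is None else start.copy()
    lo, hi = config.log_sigma_bounds
    x0[k] = float(np.clip(x0[k], lo + 1e-6, hi - 1e-6))
    if fixed_index is None:
        free = np.arange(k + 1)
    else:
        free = np.array([j for j in range(k + 1) if j != fixed_index])

    def fun(p_free: np.ndarray) -> tuple[float, np.ndarray]:
        p = np.zeros(k + 1)
        p[free] = p_free
        val, grad = _neg_objective_and_grad(p, X, resp, penalized, config)
        return val, grad[free]

    bounds = [(None, None)] * (len(free) - 1) + [(lo, hi)]
    res = optimize.minimize(
        fun,
        x0[free],
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={
            "maxiter": config.max_iter,
            "gtol": config.gradient_tol,
            "ftol": 1e-12,
        },
    )
    params = np.zeros(k + 1)
    params[free] = res.x
    return params, -float(res.fun), bool(res.success), int(res.nit)


def _lrt_p_value(lrt: float, n: int, k: int) -> float:
    """Small-sample calibrated tail probability for a 1-df LRT.

    The raw chi-square(1) reference is anti-conservative at the sample
    sizes typical of microbiome studies (measured size ~0.07 at n=50 even
    with no censoring).  The statistic is instead mapped to the F scale
    via F = (n - k) (exp(T/n) - 1) and referred to F(1, n - k) — exactly
    the classical F test in the uncensored Gaussian limit, and a close
    approximation under censoring.  It converges to chi-square(1) as
    n grows.
    """
    if lrt <= 0:
        return 1.0
    df2 = max(n - k, 1)
    f_stat = df2 * np.expm1(min(lrt / n, 500.0))
    return float(stats.f.sf(f_stat, 1, df2))


def fit_tobit(
    resp: CensoredResponse,
    design: CovariateDesign | np.ndarray,
    penalized: bool = True,
    tested_index: int | None = None,
    config: TobitConfig = TobitConfig(),
) -> TobitFit:
    """Fit the (optionally Firth-penalized) Tobit model and test one coefficient.

    The full model and the null model (tested column removed) are each
    maximized by quasi-Newton iterations from a deterministic least-squares
    start; the likelihood-ratio statistic of the tested coefficient is
    referred to a small-sample F calibration of the 1-df chi-square test.
    Under penalization the null fit constrains the tested coefficient to
    zero within the full model (penalty dimension unchanged), the standard
    construction for Firth-type likelihood-ratio tests.  Non-convergence
    yields a flagged fit (``converged=False``) rather than an exception.
    """
    X = _design_matrix(design)
    if tested_index is None:
        tested_index = design.tested_index if isinstance(design, CovariateDesign) else 1
    k = X.shape[1]
    if not 0 <= tested_index < k:
        raise ValueError(f"tested_index {tested_index} out of range for {k} columns")

    params, full_obj, ok_full, nit_full = _maximize(X, resp, penalized, config)
    null_start = params.copy()
    null_start[tested_index] = 0.0
    _, null_obj, ok_null, nit_null = _maximize(
        X, resp, penalized, config, start=null_start, fixed_index=tested_index
    )
    lrt = max(0.0, 2.0 * (full_obj - null_obj))
    p_value = _lrt_p_value(lrt, n=X.shape[0], k=k)
    return TobitFit(
        coefficients=params[:k].copy(),
        scale=float(np.exp(params[k])),
        penalized_loglik=full_obj,
        tested_estimate=float(params[tested_index]),
        lrt_stat=lrt,
        p_value=p_value,
        converged=ok_full and ok_null,
        iterations=nit_full + nit_null,
        tested_index=tested_index,
    )


def _failed_fit(k: int, tested_index: int, message: str) -> TobitFit:
    return TobitFit(
        coefficients=np.full(k, np.nan),
        scale=np.nan,
        penalized_loglik=np.nan,
        tested_estimate=np.nan,
        lrt_stat=0.0,
        p_value=1.0,
        converged=False,
        iterations=0,
        tested_index=tested_index,
        error=message,
    )


def fit_all_taxa(
    cct: CensoredCountTable,
    design: CovariateDesign,
    responses: Iterable[CensoredResponse] | Callable[[int], CensoredResponse],
    penalized: bool = True,
    config: TobitConfig = TobitConfig(),
    n_jobs: int = 1,
) -> list[TobitFit]:
    """Fit one Tobit model per taxon; failures become flagged fits, not aborts.

    Output order follows taxon order regardless of worker count, so results
    are identical for any ``n_jobs``.
    """
    if callable(responses):
        resp_list = [responses(j) for j in range(cct.n_taxa)]
    else:
        resp_list = list(responses)
    k = design.matrix.shape[1]

    def _one(resp: CensoredResponse) -> TobitFit:
        try:
            return fit_tobit(resp, design, penalized=penalized, config=config)
        except Exception as exc:  # noqa: BLE001 - one bad taxon must not kill the batch
            warnings.warn(f"tobit fit failed: {exc}", RuntimeWarning, stacklevel=2)
            return _failed_fit(k, design.tested_index, str(exc))

    if n_jobs == 1:
        return [_one(r) for r in resp_list]
    return Parallel(n_jobs=n_jobs)(delayed(_one)(r) for r in resp_list)
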