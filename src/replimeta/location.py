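"""Location meta-regressions with multiplicative or additive heterogeneity.

Two flavors of residual between-study-pair heterogeneity are supported
for the model ``Delta_i ~ N(x_i' beta, variance_i)``:

* multiplicative — ``variance_i = v_i * phi`` with ``v_i`` the known
  squared SE of the difference; ``phi`` is the (df-corrected) mean
  squared error of the inverse-variance weighted regression and is
  clamped at 1 for reporting (no under-dispersion);
* additive — ``variance_i = v_i + tau2`` with ``tau2 >= 0`` estimated by
  restricted maximum likelihood (REML), as in a random-effects
  meta-regression.

The reported log-likelihood is restricted by default (the estimator that
performs best for information-criterion model selection in this setting);
the multiplicative flavor also offers plain ML, under which the scale
estimate is ``RSS_w / n`` instead of ``RSS_w / (n - p - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import InvalidInputError, ReplicationDataset
from .design import ModelData, prepare_model_data

__all__ = [
    "HeterogeneityEstimate",
    "Coefficient",
    "MetaRegressionFit",
    "fit_location_multiplicative",
    "fit_location_additive",
    "Z_95",
]

Z_95 = float(stats.norm.ppf(0.975))

_LOG2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """Raised when a variance-component optimization fails to converge."""


@dataclass(frozen=True)
class HeterogeneityEstimate:
    """A heterogeneity parameter: phi (multiplicative) or tau2 (additive).

    ``raw_value`` is the unconstrained optimum; ``value`` is the reported
    one after the phi >= 1 clamp (multiplicative) or tau2 >= 0
    truncation (additive).
    """

    flavor: str
    value: float
    raw_value: float
    clamped: bool = False


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_wald(cls, estimate: float, se: float, z: float = Z_95) -> "Coefficient":
        return cls(float(estimate), float(se), float(estimate - z * se), float(estimate + z * se))


@dataclass(frozen=True)
class MetaRegressionFit:
    """Result of a location meta-regression."""

    flavor: str
    coefficients: dict[str, Coefficient]
    residual_heterogeneity: HeterogeneityEstimate
    loglik: float
    loglik_method: str
    k: int
    aic: float
    bic: float
    n_used: int
    column_names: tuple[str, ...]
    residuals: np.ndarray = field(repr=False, default=None)
    pair_ids: tuple[str, ...] = ()
    n_dropped: int = 0

    @property
    def location_covariates(self) -> tuple[str, ...]:
        return tuple(n for n in self.column_names if n != "intercept")


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (beta, weighted RSS, XtWX)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    return beta, float(resid @ resid), Xw.T @ Xw


def _logdet_xtx(X: np.ndarray) -> float:
    _, logdet = np.linalg.slogdet(X.T @ X)
    return float(logdet)


def reml_loglik_scaled(y: np.ndarray, X: np.ndarray, v: np.ndarray, phi: float) -> float:
    """Restricted log-likelihood of ``y ~ N(X beta, phi * diag(v))``.

    Includes the ``+ 1/2 ln|X'X|`` term so that the restricted
    likelihood is invariant to reparametrization of the fixed effects
    and comparable across covariate sets.
    """
    n, m = X.shape
    beta, rss_w, xtwx = _wls(y, X, 1.0 / v)
    _, logdet = np.linalg.slogdet(xtwx)
    return -0.5 * (
        (n - m) * _LOG2PI
        + (n - m) * math.log(phi)
        + float(np.sum(np.log(v)))
        + logdet
        - _logdet_xtx(X)
        + rss_w / phi
    )


def reml_loglik_hetero(y: np.ndarray, X: np.ndarray, sigma2: np.ndarray):
    """Restricted log-likelihood for ``y ~ N(X beta, diag(sigma2))``.

    Same ``+ 1/2 ln|X'X|`` convention as :func:`reml_loglik_scaled`.
    Returns ``(loglik, beta, XtWX)`` with ``beta`` the GLS estimate.
    """
    n, m = X.shape
    w = 1.0 / sigma2
    beta, rss_w, xtwx = _wls(y, X, w)
    _, logdet = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        (n - m) * _LOG2PI
        + float(np.sum(np.log(sigma2)))
        + logdet
        - _logdet_xtx(X)
        + rss_w
    )
    return ll, beta, xtwx


def ml_loglik_hetero(y: np.ndarray, mu: np.ndarray, sigma2: np.ndarray) -> float:
    """Full normal log-likelihood with per-observation variances."""
    r = y - mu
    return -0.5 * float(np.sum(_LOG2PI + np.log(sigma2) + r * r / sigma2))


def _finish(flavor, data: ModelData, beta, cov, het, loglik, method, residual_var):
    names = ("intercept", *data.location.column_names)
    se = np.sqrt(np.diag(cov))
    coefficients = {
        nm: Coefficient.from_wald(b, s) for nm, b, s in zip(names, beta, se)
    }
    p = data.location.p
    k = p + 2
    n = data.n
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * math.log(n)
    residuals = (data.y - data.X @ beta) / np.sqrt(residual_var)
    return MetaRegressionFit(
        flavor=flavor,
        coefficients=coefficients,
        residual_heterogeneity=het,
        loglik=float(loglik),
        loglik_method=method,
        k=k,
        aic=float(aic),
        bic=float(bic),
        n_used=n,
        column_names=names,
        residuals=residuals,
        pair_ids=data.pair_ids,
        n_dropped=data.n_dropped,
    )


def fit_location_multiplicative(
    dataset: ReplicationDataset,
    covariates: Sequence[str] = (),
    method: str = "reml",
) -> MetaRegressionFit:
    """Weighted least squares with multiplicative heterogeneity phi.

    ``beta`` is the inverse-variance weighted estimate; phi is the
    weighted mean squared error (df-corrected under ``method="reml"``,
    ``RSS_w/n`` under ``method="ml"``), clamped at 1 for reporting.  The
    coefficient covariance is ``phi_reported * (X'WX)^-1`` so that
    under-dispersion never shrinks standard errors.
    """
    if method not in ("reml", "ml"):
        raise InvalidInputError(f"unknown method {method!r}")
    data = prepare_model_data(dataset, covariates)
    n, m = data.X.shape
    if n < m + 1:
        raise InvalidInputError(
            f"need more than p+1={m} pairs to estimate phi, got n={n}"
        )
    beta, rss_w, xtwx = _wls(data.y, data.X, 1.0 / data.v)
    df = (n - m) if method == "reml" else n
    raw_phi = rss_w / df
    phi = max(raw_phi, 1.0)
    het = HeterogeneityEstimate("multiplicative", phi, raw_phi, clamped=raw_phi < 1.0)
    cov = phi * np.linalg.inv(xtwx)
    if method == "reml":
        loglik = reml_loglik_scaled(data.y, data.X, data.v, max(raw_phi, 1e-12))
    else:
        loglik = ml_loglik_hetero(data.y, data.X @ beta, data.v * max(raw_phi, 1e-12))
    return _finish("multiplicative", data, beta, cov, het, loglik, method, data.v * phi)


def fit_location_additive(
    dataset: ReplicationDataset,
    covariates: Sequence[str] = (),
) -> MetaRegressionFit:
    """Random-effects meta-regression: REML estimate of tau2, GLS beta.

    The restricted likelihood is maximized over ``u = ln(tau2 + eps)``
    with a bounded 1-D search whose upper bracket is widened until the
    optimum is interior; a boundary solution at the lower end reports
    tau2 = 0.
    """
    data = prepare_model_data(dataset, covariates)
    n, m = data.X.shape
    if n < m + 1:
        raise InvalidInputError(
            f"need more than p+1={m} pairs to estimate tau2, got n={n}"
        )
    eps = 1e-12
    y, X, v = data.y, data.X, data.v

    def neg_rll(u: float) -> float:
        tau2 = math.exp(u) - eps
        ll, _, _ = reml_loglik_hetero(y, X, v + max(tau2, 0.0))
        return -ll

    lo = math.log(eps)
    hi = math.log(10.0 * (float(np.var(y)) + float(np.max(v))) + eps)
    for _ in range(60):
        res = optimize.minimize_scalar(
            neg_rll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        if not res.success:
            raise ConvergenceError(f"REML search for tau2 failed: {res.message}")
        if res.x < hi - 1e-6 or hi > 700.0:
            break
        hi += math.log(4.0)
    else:  # pragma: no cover
        raise ConvergenceError("REML bracket widening for tau2 did not terminate")

    tau2 = max(math.exp(res.x) - eps, 0.0)
    if tau2 < 1e-10:  # boundary solution: no between-pair variance
        tau2 = 0.0
    loglik, beta, xtwx = reml_loglik_hetero(y, X, v + tau2)
    het = HeterogeneityEstimate("additive", tau2, tau2, clamped=False)
    cov = np.linalg.inv(xtwx)
    return _finish("additive", data, beta, cov, het, loglik, "reml", v + tau2)
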