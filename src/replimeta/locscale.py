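"""Location-scale meta-regression: covariate-dependent heterogeneity.

Beyond the location model ``Delta_i ~ N(x_i' beta, variance_i)``, the
scale submodel makes the residual heterogeneity itself log-linear in a
set of scale covariates ``z_i``:

* multiplicative — ``variance_i = v_i * exp(z_i' alpha)``, i.e. the
  per-pair log standard deviation is ``ln(se_Delta_i) + z_i' alpha / 2``
  (the known difference SE enters as an offset);
* additive — ``variance_i = v_i + exp(z_i' alpha)``.

The log link keeps every per-pair heterogeneity positive; the
multiplicative parameter ``phi_i = exp(z_i' alpha)`` is additionally
clamped at 1 when reported (the model tolerates no under-dispersion in
its interpretation, though the likelihood itself is unconstrained).

Estimation: the multiplicative model is fitted by full maximum
likelihood with an alternating scheme (weighted least squares for beta
given alpha, quasi-Newton for alpha given beta); the additive model by
REML with beta profiled out by generalized least squares, the standard
route for random-effects location-scale meta-regression.  Wald standard
errors come from the numerically differentiated Hessian at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .datamodel import InvalidInputError, ReplicationDataset
from .design import ModelData, prepare_model_data
from .location import (
    Coefficient,
    ConvergenceError,
    HeterogeneityEstimate,
    MetaRegressionFit,
    Z_95,
    fit_location_additive,
    fit_location_multiplicative,
    ml_loglik_hetero,
    reml_loglik_hetero,
)

__all__ = [
    "LocationScaleFit",
    "fit_ls_multiplicative",
    "fit_ls_additive",
    "evaluate_scale",
    "evaluate_scale_coefficients",
]

_MAX_RESTARTS = 5
_LL_TOL = 1e-9


@dataclass(frozen=True)
class LocationScaleFit(MetaRegressionFit):
    """A location fit augmented with scale coefficients.

    ``per_pair_heterogeneity`` holds the reported per-pair values
    (multiplicative phi_i clamped at 1); ``per_pair_heterogeneity_raw``
    the unconstrained ``exp(z_i' alpha)``.
    """

    scale_coefficients: dict[str, Coefficient] = field(default_factory=dict)
    scale_column_names: tuple[str, ...] = ()
    per_pair_heterogeneity: np.ndarray = field(repr=False, default=None)
    per_pair_heterogeneity_raw: np.ndarray = field(repr=False, default=None)

    @property
    def scale_covariates(self) -> tuple[str, ...]:
        return tuple(n for n in self.scale_column_names if n != "intercept")


def _numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    d = x.size
    h = 1e-4 * np.maximum(np.abs(x), 1.0)
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _wald_from_hessian(neg_ll, x_opt, what: str) -> np.ndarray:
    H = _numeric_hessian(neg_ll, x_opt)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ConvergenceError(f"{what}: singular Hessian at the optimum") from exc
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise ConvergenceError(f"{what}: Hessian not positive definite at the optimum")
    return np.sqrt(diag)


def _coef_dict(names, est, se) -> dict[str, Coefficient]:
    return {n: Coefficient.from_wald(b, s) for n, b, s in zip(names, est, se)}


def _assemble(flavor, data: ModelData, beta, beta_se, alpha, alpha_se, loglik,
              method, raw_het, reported_het, resid_var) -> LocationScaleFit:
    loc_names = ("intercept", *data.location.column_names)
    scale_names = ("intercept", *data.scale.column_names)
    p, q = data.location.p, data.scale.p
    k = p + q + 2
    n = data.n
    intercept_raw = math.exp(alpha[0])
    het = HeterogeneityEstimate(
        flavor,
        max(intercept_raw, 1.0) if flavor == "multiplicative" else intercept_raw,
        intercept_raw,
        clamped=(flavor == "multiplicative" and intercept_raw < 1.0),
    )
    return LocationScaleFit(
        flavor=flavor,
        coefficients=_coef_dict(loc_names, beta, beta_se),
        residual_heterogeneity=het,
        loglik=float(loglik),
        loglik_method=method,
        k=k,
        aic=float(-2.0 * loglik + 2.0 * k),
        bic=float(-2.0 * loglik + k * math.log(n)),
        n_used=n,
        column_names=loc_names,
        residuals=(data.y - data.X @ beta) / np.sqrt(resid_var),
        pair_ids=data.pair_ids,
        n_dropped=data.n_dropped,
        scale_coefficients=_coef_dict(scale_names, alpha, alpha_se),
        scale_column_names=scale_names,
        per_pair_heterogeneity=reported_het,
        per_pair_heterogeneity_raw=raw_het,
    )


def _init_alpha(q1: int, log_het0: float) -> np.ndarray:
    alpha0 = np.zeros(q1)
    alpha0[0] = max(log_het0, math.log(1e-8))
    return alpha0


def fit_ls_multiplicative(
    dataset: ReplicationDataset,
    location_covariates: Sequence[str] = (),
    scale_covariates: Sequence[str] = (),
) -> LocationScaleFit:
    """Full-ML location-scale fit with multiplicative heterogeneity.

    The response standard deviation is ``se_Delta_i * exp(z_i'alpha/2)``:
    the log of the known difference SE acts as an offset in the scale
    predictor.  beta and alpha are updated alternately until the joint
    log-likelihood is stable to 1e-9.
    """
    data = prepare_model_data(dataset, location_covariates, scale_covariates)
    y, v, X, Z = data.y, data.v, data.X, data.Z
    n = data.n
    if n <= data.location.p + data.scale.p + 1:
        raise InvalidInputError("not enough pairs for the requested location-scale model")

    log_v = np.log(v)

    def loglik(beta: np.ndarray, alpha: np.ndarray) -> float:
        return ml_loglik_hetero(y, X @ beta, v * np.exp(np.clip(Z @ alpha, -700, 700)))

    def alpha_objective(alpha: np.ndarray, r2_over_v: np.ndarray):
        eta = np.clip(Z @ alpha, -700, 700)
        e = np.exp(-eta)
        val = 0.5 * float(np.sum(eta + r2_over_v * e))
        grad = 0.5 * Z.T @ (1.0 - r2_over_v * e)
        return val, grad

    start = fit_location_multiplicative(dataset, location_covariates, method="ml")
    # restrict the warm start to the pairs actually used here
    beta = np.array([start.coefficients[nm].estimate for nm in ("intercept", *data.location.column_names)])
    alpha = _init_alpha(Z.shape[1], math.log(max(start.residual_heterogeneity.raw_value, 1e-8)))

    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(_MAX_RESTARTS + 1):
        try:
            ll_old = loglik(beta, alpha)
            for _ in range(500):
                # beta step: WLS at current alpha
                w = 1.0 / (v * np.exp(np.clip(Z @ alpha, -700, 700)))
                sw = np.sqrt(w)
                beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
                # alpha step: quasi-Newton at current beta
                r2_over_v = (y - X @ beta) ** 2 / v
                res = optimize.minimize(
                    alpha_objective, alpha, args=(r2_over_v,), jac=True,
                    method="BFGS", options={"gtol": 1e-10, "maxiter": 500},
                )
                alpha = res.x
                ll_new = loglik(beta, alpha)
                if abs(ll_new - ll_old) < _LL_TOL:
                    break
                ll_old = ll_new
            else:
                raise ConvergenceError(
                    "alternating ML did not stabilize within 500 sweeps"
                )
            m = X.shape[1]

            def neg_joint(theta: np.ndarray) -> float:
                return -loglik(theta[:m], theta[m:])

            theta = np.concatenate([beta, alpha])
            se = _wald_from_hessian(neg_joint, theta, "multiplicative location-scale fit")
            break
        except (ConvergenceError, np.linalg.LinAlgError) as err:
            last_err = err
            beta = beta + rng.normal(scale=0.05, size=beta.size)
            alpha = alpha + rng.normal(scale=0.1, size=alpha.size)
    else:
        raise ConvergenceError(
            f"multiplicative location-scale fit failed after {_MAX_RESTARTS} restarts: {last_err}"
        )

    raw = np.exp(np.clip(Z @ alpha, -700, 700))
    return _assemble(
        "multiplicative", data, beta, se[: X.shape[1]], alpha, se[X.shape[1]:],
        loglik(beta, alpha), "ml", raw, np.maximum(raw, 1.0), v * raw,
    )


def fit_ls_additive(
    dataset: ReplicationDataset,
    location_covariates: Sequence[str] = (),
    scale_covariates: Sequence[str] = (),
) -> LocationScaleFit:
    """REML location-scale fit with additive heterogeneity.

    The per-pair variance is ``v_i + exp(z_i' alpha)``; the restricted
    likelihood (beta profiled out by GLS) is maximized over alpha.
    """
    data = prepare_model_data(dataset, location_covariates, scale_covariates)
    y, v, X, Z = data.y, data.v, data.X, data.Z
    if data.n <= data.location.p + data.scale.p + 1:
        raise InvalidInputError("not enough pairs for the requested location-scale model")

    def neg_rll(alpha: np.ndarray) -> float:
        tau2 = np.exp(np.clip(Z @ alpha, -700, 700))
        ll, _, _ = reml_loglik_hetero(y, X, v + tau2)
        return -ll

    start = fit_location_additive(dataset, location_covariates)
    alpha = _init_alpha(
        Z.shape[1], math.log(max(start.residual_heterogeneity.value, 1e-8))
    )

    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(_MAX_RESTARTS + 1):
        try:
            res = optimize.minimize(
                neg_rll, alpha, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000, "maxfev": 10000},
            )
            res = optimize.minimize(
                neg_rll, res.x, method="BFGS", options={"gtol": 1e-9, "maxiter": 500}
            )
            alpha_hat = res.x
            se_alpha = _wald_from_hessian(neg_rll, alpha_hat, "additive location-scale fit")
            break
        except (ConvergenceError, np.linalg.LinAlgError, FloatingPointError) as err:
            last_err = err
            alpha = alpha + rng.normal(scale=0.2, size=alpha.size)
    else:
        raise ConvergenceError(
            f"additive location-scale fit failed after {_MAX_RESTARTS} restarts: {last_err}"
        )

    tau2 = np.exp(np.clip(Z @ alpha_hat, -700, 700))
    loglik, beta, xtwx = reml_loglik_hetero(y, X, v + tau2)
    beta_se = np.sqrt(np.diag(np.linalg.inv(xtwx)))
    return _assemble(
        "additive", data, beta, beta_se, alpha_hat, se_alpha,
        loglik, "reml", tau2, tau2, v + tau2,
    )


def evaluate_scale_coefficients(
    flavor: str,
    coefficients: Mapping[str, float],
    z: Mapping[str, float],
    clamp: bool = True,
) -> HeterogeneityEstimate:
    """Evaluate a scale submodel at covariate values ``z``.

    ``coefficients`` maps ``"intercept"`` and scale-column names to the
    (log-scale) coefficients; ``z`` supplies a value for every
    non-intercept coefficient.  Returns the per-pair heterogeneity: for
    the multiplicative flavor the value is clamped at 1 (raw value
    retained), for the additive flavor it is ``exp(eta)`` as is.
    """
    if flavor not in ("multiplicative", "additive"):
        raise InvalidInputError(f"unknown flavor {flavor!r}")
    eta = 0.0
    for name, coef in coefficients.items():
        if name == "intercept":
            eta += float(coef)
        else:
            if name not in z:
                raise InvalidInputError(f"missing scale covariate value for {name!r}")
            eta += float(coef) * float(z[name])
    raw = math.exp(eta)
    if flavor == "multiplicative" and clamp:
        return HeterogeneityEstimate(flavor, max(raw, 1.0), raw, clamped=raw < 1.0)
    return HeterogeneityEstimate(flavor, raw, raw, clamped=False)


def evaluate_scale(fit: LocationScaleFit, z: Mapping[str, float]) -> HeterogeneityEstimate:
    """Per-pair heterogeneity implied by a fitted scale submodel at ``z``."""
    coefficients = {n: c.estimate for n, c in fit.scale_coefficients.items()}
    return evaluate_scale_coefficients(fit.flavor, coefficients, z)
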