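"""Unadjusted (intercept-only) heterogeneity models and prediction intervals.

These quantify shrinkage (the pooled difference between original and
replication effects) and between-study-pair heterogeneity before any
covariate adjustment, and are the baselines that the meta-regressions
try to reduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .datamodel import InvalidInputError, ReplicationDataset
from .location import (
    HeterogeneityEstimate,
    MetaRegressionFit,
    Z_95,
    fit_location_additive,
    fit_location_multiplicative,
)

__all__ = ["PooledEstimate", "fit_multiplicative", "fit_additive", "prediction_interval"]


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled effect-size difference with its heterogeneity estimate."""

    delta: float
    se: float
    ci_low: float
    ci_high: float
    heterogeneity: HeterogeneityEstimate
    n: int
    fit: MetaRegressionFit

    @property
    def flavor(self) -> str:
        return self.heterogeneity.flavor


def _pooled(fit: MetaRegressionFit) -> PooledEstimate:
    c = fit.coefficients["intercept"]
    return PooledEstimate(
        delta=c.estimate,
        se=c.se,
        ci_low=c.ci_low,
        ci_high=c.ci_high,
        heterogeneity=fit.residual_heterogeneity,
        n=fit.n_used,
        fit=fit,
    )


def fit_multiplicative(dataset: ReplicationDataset, method: str = "reml") -> PooledEstimate:
    """Intercept-only multiplicative model: inverse-variance weighted mean.

    phi is the weighted mean squared error around that mean,
    ``sum w_i (y_i - ybar_w)^2 / (n - 1)``, clamped at 1;
    ``se = sqrt(phi / sum w_i)``.
    """
    if len(dataset) < 2:
        raise InvalidInputError("phi is undefined for fewer than 2 pairs")
    return _pooled(fit_location_multiplicative(dataset, (), method=method))


def fit_additive(dataset: ReplicationDataset) -> PooledEstimate:
    """Intercept-only random-effects model: REML tau2 and weighted mean."""
    if len(dataset) < 2:
        raise InvalidInputError("tau2 is undefined for fewer than 2 pairs")
    return _pooled(fit_location_additive(dataset, ()))


def prediction_interval(
    fit: PooledEstimate,
    level: float = 0.95,
    new_pair_se: float | None = None,
) -> tuple[float, float]:
    """Prediction interval for the effect-size difference of a new pair.

    Additive flavor: ``delta +/- z * sqrt(tau2 + se(delta)^2)``.
    Multiplicative flavor: the new pair's own difference SE must be
    supplied and the half-width is ``z * sqrt(phi * new_pair_se^2 +
    se(delta)^2)``.
    """
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"level must be in (0, 1), got {level!r}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    het = fit.heterogeneity
    if het.flavor == "additive":
        extra = het.value
    else:
        if new_pair_se is None:
            raise InvalidInputError(
                "multiplicative prediction interval needs new_pair_se"
            )
        if not new_pair_se > 0:
            raise InvalidInputError("new_pair_se must be > 0")
        extra = het.value * new_pair_se**2
    half = z * math.sqrt(extra + fit.se**2)
    return (fit.delta - half, fit.delta + half)
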