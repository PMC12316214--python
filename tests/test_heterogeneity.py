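import math

import numpy as np
import pytest

from replimeta import (
    InvalidInputError,
    fit_additive,
    fit_multiplicative,
    prediction_interval,
)
from replimeta.location import Z_95

from conftest import build_dataset


def _reml_oracle_tau2(y, v, grid_upper=5.0):
    """Two-level grid search of the intercept-only restricted likelihood.

    Independent of the package's optimizer: the restricted likelihood is
    written out directly and maximized by brute force.
    """
    y = np.asarray(y)
    v = np.asarray(v)

    def rll(tau2):
        s2 = v + tau2
        w = 1.0 / s2
        mu = np.sum(w * y) / np.sum(w)
        return -0.5 * (
            np.sum(np.log(s2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    grid = np.linspace(0.0, grid_upper, 4001)
    best = grid[np.argmax([rll(t) for t in grid])]
    lo, hi = max(best - 2e-3, 0.0), best + 2e-3
    fine = np.linspace(lo, hi, 40001)
    return float(fine[np.argmax([rll(t) for t in fine])])


class TestMultiplicative:
    def test_equal_weights_reduce_to_sample_variance(self):
        ds = build_dataset([0.0, 2.0], [1.0, 1.0], [1e-9, 1e-9])
        fit = fit_multiplicative(ds)
        assert fit.delta == pytest.approx(1.0, abs=1e-9)
        assert fit.heterogeneity.value == pytest.approx(2.0, rel=1e-9)
        assert not fit.heterogeneity.clamped

    def test_zero_residuals_clamp_phi_to_one(self):
        ds = build_dataset([1.0, 1.0, 1.0], [0.3, 0.1, 0.2])
        fit = fit_multiplicative(ds)
        assert fit.delta == pytest.approx(1.0)
        assert fit.heterogeneity.raw_value == pytest.approx(0.0, abs=1e-12)
        assert fit.heterogeneity.value == 1.0
        assert fit.heterogeneity.clamped

    def test_single_pair_errors(self):
        with pytest.raises(InvalidInputError):
            fit_multiplicative(build_dataset([0.1], [0.1]))

    def test_se_rescaling_invariance(self):
        """Scaling every SE by c leaves delta unchanged, scales raw phi by 1/c^2."""
        rng = np.random.default_rng(11)
        deltas = rng.normal(0.2, 0.3, size=15)
        ses = rng.uniform(0.1, 0.4, size=15)
        base = fit_multiplicative(build_dataset(deltas, ses))
        c = 3.0
        scaled = fit_multiplicative(build_dataset(deltas, c * ses))
        assert scaled.delta == pytest.approx(base.delta, rel=1e-9)
        assert scaled.heterogeneity.raw_value == pytest.approx(
            base.heterogeneity.raw_value / c**2, rel=1e-9
        )

    def test_ci_halfwidth_is_z_times_se(self):
        fit = fit_multiplicative(build_dataset([0.1, 0.5, 0.3], [0.2, 0.1, 0.3]))
        assert fit.ci_high - fit.delta == pytest.approx(Z_95 * fit.se, abs=1e-9)
        assert fit.delta - fit.ci_low == pytest.approx(Z_95 * fit.se, abs=1e-9)


class TestAdditive:
    def test_equal_variance_closed_form(self):
        # equal known variances: REML tau2 = max(0, sample variance - v)
        ds = build_dataset([0.0, 2.0], [1.0, 1.0], [1e-9, 1e-9])
        fit = fit_additive(ds)
        assert fit.delta == pytest.approx(1.0, abs=1e-9)
        assert fit.heterogeneity.value == pytest.approx(1.0, rel=1e-6)

    def test_zero_residuals_truncate_at_zero(self):
        ds = build_dataset([1.0, 1.0], [1.0, 2.0], [1e-9, 1e-9])
        fit = fit_additive(ds)
        assert fit.heterogeneity.value == 0.0
        assert fit.delta == pytest.approx(1.0, abs=1e-9)

    def test_boundary_fits_agree_on_fixed_effect_mean(self):
        """With no heterogeneity both flavors return the IV-weighted mean."""
        ds = build_dataset([0.5, 0.5, 0.5], [0.1, 0.2, 0.4])
        add = fit_additive(ds)
        mult = fit_multiplicative(ds)
        w = 1.0 / np.array([0.1, 0.2, 0.4]) ** 2
        assert add.delta == pytest.approx(0.5, abs=1e-10)
        assert mult.delta == pytest.approx(add.delta, abs=1e-10)
        assert add.heterogeneity.value == 0.0
        assert mult.heterogeneity.value == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_reml_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 15)
        v = rng.uniform(0.01, 0.2, size=n)
        tau2_true = rng.uniform(0.0, 0.3)
        y = rng.normal(0.2, np.sqrt(v + tau2_true))
        ds = build_dataset(y, np.sqrt(v), np.full(n, 1e-9))
        fit = fit_additive(ds)
        oracle = _reml_oracle_tau2(y, v + 1e-18)
        assert fit.heterogeneity.value == pytest.approx(oracle, abs=1e-5)


class TestPredictionInterval:
    def test_additive_collapses_to_ci_when_tau2_zero(self):
        ds = build_dataset([0.0, 0.0], [0.141421356, 0.141421356])
        fit = fit_additive(ds)
        assert fit.heterogeneity.value == 0.0
        low, high = prediction_interval(fit, 0.95)
        assert low == pytest.approx(-Z_95 * fit.se, abs=1e-9)
        assert high == pytest.approx(Z_95 * fit.se, abs=1e-9)

    def test_multiplicative_needs_new_pair_se(self):
        ds = build_dataset([0.1, 0.4], [0.2, 0.2])
        fit = fit_multiplicative(ds)
        with pytest.raises(InvalidInputError):
            prediction_interval(fit, 0.95)

    def test_multiplicative_phi_one_width(self):
        # with phi = 1 and new_pair_se = se(delta), width = 2 z sqrt(2) se
        ds = build_dataset([0.2, 0.2, 0.2], [0.3, 0.3, 0.3])
        fit = fit_multiplicative(ds)
        assert fit.heterogeneity.value == 1.0
        low, high = prediction_interval(fit, 0.95, new_pair_se=fit.se)
        assert high - low == pytest.approx(2 * Z_95 * math.sqrt(2) * fit.se, rel=1e-9)

    def test_level_validation(self):
        ds = build_dataset([0.1, 0.4], [0.2, 0.2])
        fit = fit_additive(ds)
        with pytest.raises(InvalidInputError):
            prediction_interval(fit, 1.2)

    @pytest.mark.parametrize("flavor", ["additive", "multiplicative"])
    def test_prediction_interval_contains_ci(self, flavor):
        rng = np.random.default_rng(5)
        ds = build_dataset(rng.normal(0.2, 0.3, 12), rng.uniform(0.1, 0.3, 12))
        fit = fit_additive(ds) if flavor == "additive" else fit_multiplicative(ds)
        kwargs = {} if flavor == "additive" else {"new_pair_se": 0.2}
        low, high = prediction_interval(fit, 0.95, **kwargs)
        assert low <= fit.ci_low
        assert high >= fit.ci_high
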