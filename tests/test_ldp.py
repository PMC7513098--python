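import numpy as np
import pytest

from memc import (
    EnergyFunction,
    asymptotic_variance,
    build_model,
    cumulants,
    fluctuation_overlay,
    ld_curve,
    legendre,
    model_expectation,
    scgf,
    scgf_value,
    tilted_matrix,
)

from conftest import (
    F_LAG_21,
    F_RATE0,
    F_SYNC,
    make_lagged_pair_model,
    random_iid_model,
    random_memory_model,
)
from _suites import path_oracle_gaps


def lagged_scgf_closed_form(beta1, k):
    """Tilting the lagged-pair chain by its own feature shifts beta."""
    return np.log((np.exp(beta1 + k) + 3) / (np.exp(beta1) + 3))


class TestTiltedMatrix:
    def test_zero_tilt_returns_transition_matrix(self, memory_model):
        assert np.array_equal(tilted_matrix(memory_model, F_SYNC, 0.0), memory_model.P)

    @pytest.mark.parametrize("k", [-1.0, 0.5, 2.0])
    def test_iid_spectral_radius_closed_form(self, bernoulli_quarter_model, k):
        M = tilted_matrix(bernoulli_quarter_model, F_RATE0, k)
        rho = np.linalg.eigvals(M).real.max()
        p = 0.25
        assert rho == pytest.approx(1 - p + p * np.exp(k), rel=1e-12)

    @pytest.mark.parametrize("k", [-2.0, -0.5, 0.5, 1.5])
    def test_tilting_by_model_feature_shifts_its_multiplier(self, k):
        m = make_lagged_pair_model(1.0)
        lam = scgf_value(m, F_LAG_21, k)
        assert lam == pytest.approx(lagged_scgf_closed_form(1.0, k), abs=1e-10)


class TestScgf:
    @pytest.mark.parametrize("seed", range(5))
    def test_vanishes_at_zero_with_mean_slope(self, seed):
        rng = np.random.default_rng(200 + seed)
        model = random_memory_model(rng)
        obs = model.energy.features[seed % len(model.energy.features)]
        assert abs(scgf_value(model, obs, 0.0)) < 1e-12
        h = 1e-6
        slope = (scgf_value(model, obs, h) - scgf_value(model, obs, -h)) / (2 * h)
        assert slope == pytest.approx(model_expectation(model, obs), abs=1e-6)

    def test_grid_evaluation_is_convex(self, lagged_pair_model):
        k = np.linspace(-3, 3, 61)
        lam = scgf(lagged_pair_model, F_LAG_21, k)
        second = np.diff(lam, 2)
        assert (second > -1e-12).all()

    def test_extreme_tilt_remains_finite(self, lagged_pair_model):
        # the log-scaling keeps the eigenproblem in range at large |k|
        val = scgf_value(lagged_pair_model, F_LAG_21, 500.0)
        assert np.isfinite(val)
        # asymptotically lambda(k) ~ k * max(f) + const
        assert val == pytest.approx(500.0 + np.log(np.e / (np.e + 3)), abs=0.1)


class TestLegendre:
    def test_bernoulli_rate_function_matches_kl_form(self, bernoulli_quarter_model):
        s = np.linspace(0.05, 0.9, 35)
        curve = ld_curve(bernoulli_quarter_model, F_RATE0, s_grid=s)
        p = 0.25
        kl = s * np.log(s / p) + (1 - s) * np.log((1 - s) / (1 - p))
        assert np.abs(curve.rate - kl).max() < 1e-6

    def test_rate_vanishes_at_mean_with_curvature_inverse_variance(self, memory_model):
        mean = model_expectation(memory_model, F_SYNC)
        h = 1e-3
        curve = ld_curve(
            memory_model, F_SYNC, s_grid=np.array([mean - h, mean, mean + h])
        )
        assert curve.rate[1] < 1e-8
        second = (curve.rate[0] - 2 * curve.rate[1] + curve.rate[2]) / h**2
        assert second * curve.sigma2 == pytest.approx(1.0, abs=1e-4)
        assert curve.s_star == pytest.approx(mean, abs=1e-8)

    def test_rate_nonnegative_and_infinite_outside_slope_range(self, lagged_pair_model):
        curve = ld_curve(
            lagged_pair_model, F_LAG_21, s_grid=np.array([-0.5, 0.3, 1.5])
        )
        assert np.isinf(curve.rate[0]) and np.isinf(curve.rate[2])
        assert curve.rate[1] >= 0

    def test_conjugation_round_trip_recovers_scgf(self, lagged_pair_model):
        k = np.linspace(-4, 4, 161)
        lam = scgf(lagged_pair_model, F_LAG_21, k)
        s, rate = legendre(k, lam, n_s=401)
        k2, lam2 = legendre(s, rate, s_grid=np.linspace(-2, 2, 41))
        lam_ref = scgf(lagged_pair_model, F_LAG_21, k2)
        assert np.abs(lam2 - lam_ref).max() < 1e-4

    def test_path_enumeration_oracle_approaches_spectral_value(self, memory_model):
        for k in (-1.0, 0.5, 1.0):
            gaps = path_oracle_gaps(memory_model, F_SYNC, k, lengths=(4, 6, 8))
            assert gaps[0] > gaps[1] > gaps[2]
            assert gaps[2] < 1.0 / 8


class TestCumulants:
    def test_first_cumulant_is_the_stationary_mean(self):
        m = make_lagged_pair_model(1.0)
        kap = cumulants(m, F_LAG_21, order=2)
        assert kap[0] == pytest.approx(np.e / (np.e + 3), abs=1e-8)
        assert kap[0] == pytest.approx(0.475, abs=5e-4)

    def test_bernoulli_variance(self, bernoulli_quarter_model):
        kap = cumulants(bernoulli_quarter_model, F_RATE0, order=4)
        p = 0.25
        assert kap[1] == pytest.approx(p * (1 - p), abs=1e-6)
        # third cumulant of an i.i.d. Bernoulli average: p(1-p)(1-2p)
        assert kap[2] == pytest.approx(p * (1 - p) * (1 - 2 * p), abs=1e-3)

    def test_constant_zero_observable_has_no_cumulants(self, memory_model):
        kap = cumulants(memory_model, lambda block: 0.0, order=4)
        # finite differencing of an identically-zero SCGF leaves only
        # eigensolver round-off divided by h^n
        assert np.abs(kap).max() < 1e-6

    def test_covariance_reduces_to_variance(self, memory_model):
        var = asymptotic_variance(memory_model, F_SYNC)
        cov = asymptotic_variance(memory_model, F_SYNC, F_SYNC)
        assert cov == pytest.approx(var, abs=1e-6)


class TestFluctuationOverlay:
    def test_peak_at_stationary_mean(self, memory_model):
        mean = model_expectation(memory_model, F_SYNC)
        s = np.linspace(0.1, 0.6, 101)
        _, y = fluctuation_overlay(memory_model, F_SYNC, 50, s)
        assert s[np.argmax(y)] == pytest.approx(mean, abs=0.01)

    def test_memoryless_model_overestimates_variance(self, memory_model, memoryless_model):
        var_full = asymptotic_variance(memory_model, F_SYNC)
        var_red = asymptotic_variance(memoryless_model, F_SYNC)
        assert var_red > var_full

    def test_larger_window_concentrates_mass(self, memory_model):
        mean = model_expectation(memory_model, F_SYNC)
        s = np.linspace(0.1, 0.6, 201)
        _, y50 = fluctuation_overlay(memory_model, F_SYNC, 50, s)
        _, y500 = fluctuation_overlay(memory_model, F_SYNC, 500, s)
        far = np.abs(s - mean) > 0.1
        assert y500[far].max() < y50[far].max()
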