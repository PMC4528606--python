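"""Tests for the governing equations: closed forms, the ODE oracle, and the
index/rate conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optlens import (
    OPTParams,
    RateParams,
    beta_from_index,
    estimate_k_star,
    ode_profile_oracle,
    predict_N,
    predict_density,
)
from optlens.exceptions import (
    DegenerateInputError,
    DomainError,
    UnsupportedRegionError,
)
from tests.conftest import random_valid_params

# Closed-form values derived by hand from the piecewise solution and
# cross-checked against the numerical oracle.
N_AT_1 = 0.8 * math.exp(2.375 * 0.2)  # 1.28641...
N_AT_12 = N_AT_1 * math.exp(5.13 * 0.2) / 1.2  # 2.99078...


class TestPredictN:
    @pytest.mark.parametrize(
        "R, expected",
        [
            (0.0, 1.0),
            (0.5, 1.0),  # plateau
            (0.8, 1.0),  # plateau edge included
            (1.0, N_AT_1),
            (1.2, N_AT_12),
            (1.3, N_AT_12 * math.exp(-1.0)),  # one delta past the peak
        ],
    )
    def test_piecewise_values(self, animal_params, R, expected):
        assert predict_N(R, animal_params) == pytest.approx(expected, rel=1e-12)

    def test_vectorised_matches_scalar(self, animal_params):
        grid = np.linspace(0.0, 1.3, 27)
        vec = predict_N(grid, animal_params)
        assert vec == pytest.approx([predict_N(float(R), animal_params) for R in grid])

    def test_negative_radius_rejected(self, animal_params):
        with pytest.raises(DomainError):
            predict_N(-0.1, animal_params)

    def test_beyond_peak_without_delta_rejected(self):
        p = OPTParams(gamma_cz=2.0, gamma_gz=4.0, r_p=0.8, r_peak=1.2)
        assert predict_N(1.2, p) > 1.0
        with pytest.raises(UnsupportedRegionError):
            predict_N(1.25, p)

    def test_no_peak_extends_gz_branch(self):
        p = OPTParams(gamma_cz=2.0, gamma_gz=2.0, r_p=0.5)
        assert predict_N(1.4, p) > predict_N(1.0, p)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), eps=st.floats(1e-9, 1e-7))
    def test_continuity_at_breakpoints(self, seed, eps):
        p = random_valid_params(np.random.default_rng(seed))
        for b in (p.r_p, 1.0, p.r_peak):
            lo, hi = predict_N(b - eps, p), predict_N(b + eps, p)
            assert hi == pytest.approx(lo, rel=1e-5, abs=1e-5)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_rise_and_fall(self, seed):
        """N increases strictly on the flank when gamma_cz*r_p >= 1 (and
        gamma_gz >= 1), and decreases strictly beyond the peak."""
        rng = np.random.default_rng(seed)
        p = random_valid_params(rng)
        if p.gamma_cz * p.r_p < 1.0 or p.gamma_gz < 1.0:
            p = OPTParams(
                gamma_cz=max(p.gamma_cz, 1.0 / p.r_p),
                gamma_gz=max(p.gamma_gz, 1.0 / p.r_p),
                r_p=p.r_p,
                delta=p.delta,
                r_peak=p.r_peak,
            )
        rise = np.linspace(p.r_p + 1e-6, p.r_peak, 200)
        assert np.all(np.diff(predict_N(rise, p)) > 0)
        fall = np.linspace(p.r_peak + 1e-9, p.r_peak + 1.0, 100)
        assert np.all(np.diff(predict_N(fall, p)) < 0)

    def test_stationary_slope_where_gamma_R_equals_one(self):
        """dN/dR = N (gamma R - 1)/R vanishes at R = 1/gamma."""
        p = OPTParams(gamma_cz=1.25, gamma_gz=2.0, r_p=0.5)
        R0, h = 1.0 / p.gamma_cz, 1e-6
        deriv = (predict_N(R0 + h, p) - predict_N(R0 - h, p)) / (2 * h)
        assert deriv == pytest.approx(0.0, abs=1e-6)


class TestOracleEquivalence:
    def test_plateau_grid_is_ones(self, animal_params):
        grid = np.linspace(0.05, 0.75, 20)
        assert ode_profile_oracle(animal_params, grid) == pytest.approx(1.0)

    def test_matches_closed_form_at_12(self, animal_params):
        out = ode_profile_oracle(animal_params, np.array([1.2]))
        assert out[0] == pytest.approx(N_AT_12, abs=1e-6)

    def test_many_random_parameter_sets(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(25):
            p = random_valid_params(rng)
            grid = np.linspace(1e-3, p.r_peak + 1.0, 256)
            diff = np.abs(
                ode_profile_oracle(p, grid) - predict_N(grid, p)
            )
            worst = max(worst, float(diff.max()))
        assert worst <= 1e-6

    def test_tolerance_convergence(self, animal_params):
        grid = np.linspace(0.5, 2.0, 64)
        loose = ode_profile_oracle(animal_params, grid, rtol=1e-9, atol=1e-10)
        tight = ode_profile_oracle(animal_params, grid, rtol=1e-12, atol=1e-13)
        assert np.max(np.abs(loose - tight)) < 1e-7

    def test_grid_validation(self, animal_params):
        with pytest.raises(DomainError):
            ode_profile_oracle(animal_params, np.array([0.5, 0.4]))
        p = OPTParams(gamma_cz=2.0, gamma_gz=4.0, r_p=0.8, r_peak=1.2)
        with pytest.raises(UnsupportedRegionError):
            ode_profile_oracle(p, np.array([0.5, 1.5]))


class TestPredictDensity:
    def test_plateau_value(self, animal_params):
        assert predict_density(0.0, animal_params, r_cz=2.0, n0=5000.0) == 5000.0

    def test_boundary_density(self, animal_params):
        out = predict_density(2.0, animal_params, r_cz=2.0, n0=5000.0)
        assert out == pytest.approx(5000.0 * N_AT_1, rel=1e-12)

    def test_scale_invariance(self, animal_params):
        a = predict_density(1.1, animal_params, r_cz=1.0, n0=4000.0)
        b = predict_density(2.2, animal_params, r_cz=2.0, n0=4000.0)
        assert a == b

    def test_invalid_constants(self, animal_params):
        with pytest.raises(DomainError):
            predict_density(1.0, animal_params, r_cz=0.0, n0=5000.0)
        with pytest.raises(DomainError):
            predict_density(1.0, animal_params, r_cz=1.0, n0=-1.0)


class TestRateConversions:
    def test_paper_worked_example(self):
        """I = 0.5% with a 40 h cycle gives 0.003 per capita per day."""
        assert beta_from_index(0.005, 40.0) == pytest.approx(0.003, abs=1e-15)

    @pytest.mark.parametrize(
        "index, t_hours, expected",
        [(0.0, 40.0, 0.0), (0.01, 24.0, 0.01), (1.0, 24.0, 1.0)],
    )
    def test_simple_values(self, index, t_hours, expected):
        assert beta_from_index(index, t_hours) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            beta_from_index(0.005, 0.0)
        with pytest.raises(DomainError):
            beta_from_index(1.5, 40.0)

    def test_k_star_composition(self):
        # beta = 0.003/day, r_cz = 4 mm, gamma_gz = 5.13
        out = estimate_k_star(5.13, 0.005, 40.0, 4.0)
        assert out == pytest.approx(0.003 * 4.0 / 5.13, rel=1e-12)

    def test_k_star_scales_with_r_cz(self):
        a = estimate_k_star(5.13, 0.005, 40.0, 2.0)
        b = estimate_k_star(5.13, 0.005, 40.0, 4.0)
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_k_star_degenerate_index(self):
        with pytest.raises(DegenerateInputError):
            estimate_k_star(5.13, 0.0, 40.0, 4.0)


class TestParamContainers:
    def test_beta_over_alpha_identity(self, animal_params):
        assert animal_params.beta_over_alpha == animal_params.gamma_gz / animal_params.gamma_cz

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(gamma_cz=-1.0, gamma_gz=5.0, r_p=0.8),
            dict(gamma_cz=2.0, gamma_gz=5.0, r_p=1.2),
            dict(gamma_cz=2.0, gamma_gz=5.0, r_p=0.8, delta=0.1),  # no r_peak
            dict(gamma_cz=2.0, gamma_gz=5.0, r_p=0.8, delta=0.1, r_peak=0.9),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(DomainError):
            OPTParams(**kwargs)

    def test_params_dict_round_trip(self, animal_params):
        assert OPTParams.from_dict(animal_params.to_dict()) == animal_params

    def test_rate_params_consistency(self, animal_params):
        beta = beta_from_index(0.005, 40.0)
        k_star = estimate_k_star(5.13, 0.005, 40.0, 4.0)
        rates = RateParams(beta=beta, k_star=k_star, index=0.005,
                           t_hours=40.0, r_cz=4.0)
        assert rates.gamma_gz == pytest.approx(5.13, rel=1e-9)
        assert rates.consistent_with(animal_params)
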