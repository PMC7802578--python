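"""Closed-form model equations against analytic identities and numerical oracles."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from fermkin import (
    BoltzmannParams,
    DomainError,
    LogisticGrowthParams,
    LuedekingPiretParams,
    PowerLogisticParams,
    WU14_GROWTH_BOLTZMANN,
    WU14_GROWTH_LOGISTIC,
    WU14_LAI_BOLTZMANN,
    WU14_LAI_LUEDEKING_PIRET,
    WU14_SUBSTRATE_POWER_LOGISTIC,
    boltzmann_eval,
    growth_association_fraction,
    logistic_growth_eval,
    logistic_growth_integral,
    logistic_growth_rate,
    luedeking_piret_eval,
    power_logistic_eval,
)

GROWTH = WU14_GROWTH_BOLTZMANN
SUBSTRATE = WU14_SUBSTRATE_POWER_LOGISTIC
LOGISTIC = WU14_GROWTH_LOGISTIC
LP = WU14_LAI_LUEDEKING_PIRET


def sympy_boltzmann(params, t):
    A1, A2, x0, dx = (sympy.Float(v, 30) for v in (params.A1, params.A2, params.x0, params.dx))
    expr = (A1 - A2) / (1 + sympy.exp((sympy.Float(t, 30) - x0) / dx)) + A2
    return float(expr.evalf(30))


def sympy_power_logistic(params, t):
    A1, A2, x0, p = (sympy.Float(v, 30) for v in (params.A1, params.A2, params.x0, params.p))
    expr = (A1 - A2) / (1 + (sympy.Float(t, 30) / x0) ** p) + A2
    return float(expr.evalf(30))


class TestBoltzmann:
    def test_midpoint_is_asymptote_mean(self):
        assert boltzmann_eval(GROWTH, GROWTH.x0) == pytest.approx(
            (GROWTH.A1 + GROWTH.A2) / 2, abs=1e-12
        )
        assert boltzmann_eval(GROWTH, GROWTH.x0) == pytest.approx(1.215105, abs=1e-6)

    def test_one_time_constant_past_inflection(self):
        # independent arbitrary-precision evaluation of the same formula
        t = GROWTH.x0 + GROWTH.dx
        assert boltzmann_eval(GROWTH, t) == pytest.approx(sympy_boltzmann(GROWTH, t), rel=1e-12)
        assert boltzmann_eval(GROWTH, t) == pytest.approx(1.86631, abs=1e-5)

    def test_late_limit_is_maximum_biomass(self):
        assert boltzmann_eval(GROWTH, 1e6) == pytest.approx(2.62428, abs=1e-9)
        assert boltzmann_eval(GROWTH, -1e6) == pytest.approx(GROWTH.A1, abs=1e-9)

    def test_extreme_times_do_not_overflow(self):
        assert np.isfinite(boltzmann_eval(GROWTH, 1e12))
        assert np.isfinite(boltzmann_eval(GROWTH, -1e12))

    def test_nonfinite_time_rejected(self):
        with pytest.raises(DomainError):
            boltzmann_eval(GROWTH, np.nan)

    def test_zero_dx_rejected(self):
        with pytest.raises(DomainError):
            BoltzmannParams(A1=0, A2=1, x0=5, dx=0)

    @settings(max_examples=60, derandomize=True)
    @given(
        A1=st.floats(-10, 10),
        span=st.floats(0.1, 100),
        x0=st.floats(-20, 40),
        dx=st.floats(0.05, 20),
    )
    def test_midpoint_identity_property(self, A1, span, x0, dx):
        params = BoltzmannParams(A1=A1, A2=A1 + span, x0=x0, dx=dx)
        assert boltzmann_eval(params, x0) == pytest.approx((params.A1 + params.A2) / 2, abs=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(
        A1=st.floats(-5, 0),
        span=st.floats(0.5, 50),
        x0=st.floats(0, 24),
        dx=st.floats(0.2, 10),
    )
    def test_rising_sigmoid_strictly_increasing(self, A1, span, x0, dx):
        params = BoltzmannParams(A1=A1, A2=A1 + span, x0=x0, dx=dx)
        # strictly increasing where the transition is numerically resolvable;
        # far in the tails double precision saturates at the asymptotes
        core = boltzmann_eval(params, x0 + dx * np.linspace(-6, 6, 49))
        assert np.all(np.diff(core) > 0)
        full = boltzmann_eval(params, np.linspace(0, 24, 49))
        assert np.all(np.diff(full) >= 0)


class TestPowerLogistic:
    def test_midpoint_at_x0(self):
        assert power_logistic_eval(SUBSTRATE, SUBSTRATE.x0) == pytest.approx(
            (SUBSTRATE.A1 + SUBSTRATE.A2) / 2, abs=1e-12
        )
        assert power_logistic_eval(SUBSTRATE, SUBSTRATE.x0) == pytest.approx(3.83416, abs=1e-5)

    def test_initial_value_is_A1(self):
        assert power_logistic_eval(SUBSTRATE, 0.0) == pytest.approx(7.04942, abs=1e-12)

    def test_end_of_run_matches_arbitrary_precision(self):
        assert power_logistic_eval(SUBSTRATE, 24.0) == pytest.approx(
            sympy_power_logistic(SUBSTRATE, 24.0), rel=1e-9
        )

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            power_logistic_eval(SUBSTRATE, -1.0)

    def test_nonpositive_x0_rejected(self):
        with pytest.raises(DomainError):
            PowerLogisticParams(A1=7, A2=1, x0=0.0, p=1.2)

    @settings(max_examples=60, derandomize=True)
    @given(
        A1=st.floats(-10, 10),
        span=st.floats(-50, 50).filter(lambda s: abs(s) > 1e-3),
        x0=st.floats(0.1, 20),
        p=st.floats(0.2, 6),
    )
    def test_midpoint_identity_property(self, A1, span, x0, p):
        params = PowerLogisticParams(A1=A1, A2=A1 + span, x0=x0, p=p)
        assert power_logistic_eval(params, x0) == pytest.approx((params.A1 + params.A2) / 2, abs=1e-9)


class TestLogisticGrowth:
    def test_initial_condition(self):
        assert logistic_growth_eval(LOGISTIC, 0.0) == pytest.approx(0.2, abs=1e-14)

    def test_matches_ode_integration(self):
        sol = solve_ivp(
            lambda t, x: LOGISTIC.mu_m * x * (1 - x / LOGISTIC.Xmax),
            (0, 24),
            [LOGISTIC.X0],
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        assert logistic_growth_eval(LOGISTIC, 24.0) == pytest.approx(
            float(sol.y[0, -1]), rel=1e-6
        )

    def test_carrying_capacity_limit(self):
        assert logistic_growth_eval(LOGISTIC, 1e6) == pytest.approx(LOGISTIC.Xmax, rel=1e-9)

    def test_closed_form_solves_its_ode(self):
        # central differences vs mu_m X (1 - X/Xmax) over the run
        t = np.linspace(0.5, 24, 48)
        h = 1e-5
        num = (logistic_growth_eval(LOGISTIC, t + h) - logistic_growth_eval(LOGISTIC, t - h)) / (2 * h)
        ana = logistic_growth_rate(LOGISTIC, t)
        assert np.allclose(num, ana, rtol=1e-6)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(DomainError):
            LogisticGrowthParams(X0=5.0, Xmax=2.0, mu_m=0.3)


class TestLogisticGrowthIntegral:
    def test_empty_integral(self):
        assert logistic_growth_integral(LOGISTIC, 0.0) == 0.0

    def test_matches_quadrature(self):
        val, err = quad(lambda tau: logistic_growth_eval(LOGISTIC, tau), 0, 24, epsabs=1e-12)
        assert logistic_growth_integral(LOGISTIC, 24.0) == pytest.approx(val, rel=1e-6)

    def test_monotone_in_time(self):
        assert logistic_growth_integral(LOGISTIC, 10.0) >= logistic_growth_integral(LOGISTIC, 5.0)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            logistic_growth_integral(LOGISTIC, -0.1)

    def test_random_draws_match_quadrature(self, rng):
        for _ in range(25):
            g = LogisticGrowthParams(
                X0=rng.uniform(0.05, 1.0),
                Xmax=rng.uniform(2.0, 50.0),
                mu_m=rng.uniform(0.05, 0.6),
            )
            t_end = rng.uniform(5, 30)
            val, _ = quad(lambda tau: logistic_growth_eval(g, tau), 0, t_end, epsabs=1e-12)
            assert logistic_growth_integral(g, t_end) == pytest.approx(val, rel=1e-6)


class TestLuedekingPiret:
    def test_initial_product(self):
        assert luedeking_piret_eval(LP, 0.0) == pytest.approx(LP.P0, abs=1e-14)

    def test_matches_coupled_ode(self):
        g = LP.growth

        def rhs(t, y):
            x, p = y
            dx = g.mu_m * x * (1 - x / g.Xmax)
            return [dx, LP.alpha * dx + LP.beta * x]

        sol = solve_ivp(rhs, (0, 20), [g.X0, LP.P0], rtol=1e-10, atol=1e-12)
        assert luedeking_piret_eval(LP, 20.0) == pytest.approx(float(sol.y[1, -1]), rel=1e-6)

    def test_pure_growth_associated_limit(self):
        pure = LuedekingPiretParams(alpha=4.0, beta=0.0, growth=LP.growth, P0=0.0)
        t = np.array([0.0, 3.0, 11.0, 24.0])
        expected = 4.0 * (logistic_growth_eval(LP.growth, t) - LP.growth.X0)
        assert np.allclose(luedeking_piret_eval(pure, t), expected, rtol=0, atol=1e-12)


class TestGrowthAssociationFraction:
    def test_beta_zero_fully_growth_associated(self):
        pure = LuedekingPiretParams(alpha=2.0, beta=0.0, growth=LP.growth)
        for t in (0.0, 5.0, 20.0):
            assert growth_association_fraction(pure, t) == 1.0

    def test_alpha_zero_fully_non_growth_associated(self):
        pure = LuedekingPiretParams(alpha=0.0, beta=1.0, growth=LP.growth)
        assert growth_association_fraction(pure, 8.0) == 0.0

    def test_stationary_phase_tends_to_non_growth_coupled(self):
        # dX/dt -> 0 at late times, so production becomes beta-dominated:
        # the non-growth-coupled regime reported for l-AI
        late = growth_association_fraction(LP, 200.0)
        early = growth_association_fraction(LP, 2.0)
        assert late < 1e-6 < early
        assert 0.0 <= late <= early <= 1.0
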