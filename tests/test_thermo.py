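import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermofoot import (
    KineticParams,
    Strategy,
    agricultural_impact,
    arrhenius_rate,
    growth_rate,
    juvenile_survival,
    productivity,
    relative_response,
    stability_factor,
    unfold_constant,
)
from thermofoot.errors import InvalidInputError
from thermofoot.thermo import r_prime_grid


def make_params(**kw):
    base = dict(a_B=1.0, Ea_B=60000.0, kappa_D=2.0, dH_m=4e5, T_m=331.15, dCp=0.0, c=0.1, b=0.75)
    base.update(kw)
    return KineticParams(**base)


class TestArrhenius:
    def test_zero_activation_energy(self):
        assert arrhenius_rate(1.0, 0.0, 300.0) == 1.0

    def test_prefactor_limit(self):
        assert arrhenius_rate(5.0, 60000.0, 1e12) == pytest.approx(5.0, rel=1e-6)

    def test_scalar_value(self):
        # frozen via 30-digit arithmetic: exp(-60000 / (8.314 * 298.15))
        assert arrhenius_rate(1.0, 60000.0, 298.15) == pytest.approx(
            3.0751753416848566e-11, rel=1e-12
        )

    def test_increasing_in_T(self):
        T = np.linspace(270.0, 340.0, 50)
        vals = arrhenius_rate(1.0, 60000.0, T)
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            arrhenius_rate(1.0, 60000.0, 0.0)
        with pytest.raises(InvalidInputError):
            arrhenius_rate(1.0, 60000.0, -5.0)


class TestUnfoldConstant:
    def test_unity_at_midpoint(self):
        p = make_params()
        assert unfold_constant(p.T_m, p) == pytest.approx(1.0, abs=1e-14)
        p2 = make_params(dH_m=1e5, dCp=2000.0)
        assert unfold_constant(p2.T_m, p2) == pytest.approx(1.0, abs=1e-14)

    def test_stable_below_midpoint_for_large_enthalpy(self):
        p = make_params(dH_m=1e7)
        assert unfold_constant(300.0, p) < 1e-30

    def test_scalar_value(self):
        # frozen via 30-digit arithmetic for T=333.15, T_m=331.15, dH_m=4e5
        p = make_params()
        assert unfold_constant(333.15, p) == pytest.approx(2.392164511030066, rel=1e-12)


class TestStabilityFactor:
    def test_midpoint_half(self):
        p = make_params(kappa_D=1.0)
        s = Strategy(M=2.0, p=0.25, q=0.5)  # kappa_D / (q M) = 1
        assert stability_factor(p.T_m, s, p) == pytest.approx(0.5, rel=1e-12)

    def test_zero_maintenance_limit(self):
        p = make_params()
        assert stability_factor(300.0, Strategy(4.0, 0.25, 0.0), p) == 0.0

    def test_scalar_value(self):
        p = make_params(kappa_D=2.0)
        s = Strategy(M=4.0, p=0.25, q=0.25)  # q M = 1
        assert stability_factor(333.15, s, p) == pytest.approx(0.17288089875009265, rel=1e-12)

    def test_monotone_decreasing_in_T(self):
        p = make_params()
        s = Strategy(4.0, 0.25, 0.25)
        T = np.linspace(p.T_m - 30, p.T_m + 30, 61)
        vals = np.array([stability_factor(t, s, p) for t in T])
        assert np.all(np.diff(vals) <= 0)

    def test_monotone_increasing_in_qM(self):
        p = make_params()
        vals = [stability_factor(320.0, Strategy(M, 0.1, 0.4), p) for M in np.linspace(0.5, 10, 20)]
        assert np.all(np.diff(vals) > 0)

    def test_bounded(self):
        p = make_params()
        v = stability_factor(340.0, Strategy(4.0, 0.25, 0.25), p)
        assert 0.0 < v < 1.0


class TestJuvenileSurvival:
    def test_free_acquisition(self):
        assert juvenile_survival(10.0, 0.0) == 1.0

    def test_no_reserves(self):
        assert juvenile_survival(0.0, 0.3) == 1.0

    def test_scalar_value(self):
        assert juvenile_survival(10.0, 0.1) == pytest.approx(0.3486784401, rel=1e-12)

    def test_invalid_cost(self):
        for c in (1.0, 1.5, -0.1):
            with pytest.raises(InvalidInputError):
                juvenile_survival(5.0, c)


class TestProductivity:
    def test_no_residual(self):
        assert productivity(Strategy(3.0, 0.5, 0.5), 0.75) == 0.0

    def test_identity_exponent(self):
        assert productivity(Strategy(4.0, 0.0, 0.0), 1.0) == 4.0

    def test_scalar_value(self):
        assert productivity(Strategy(4.0, 0.25, 0.25), 0.75) == pytest.approx(
            1.681792830507429, rel=1e-12
        )


class TestGrowthRate:
    def test_zero_at_boundaries(self):
        p = make_params()
        assert growth_rate(300.0, Strategy(4.0, 0.0, 0.25), p).r_prime == 0.0
        assert growth_rate(300.0, Strategy(4.0, 0.25, 0.0), p).r_prime == 0.0
        assert growth_rate(300.0, Strategy(4.0, 0.5, 0.5), p).r_prime == 0.0

    def test_product_of_components(self, oracle_r_prime):
        p = make_params(Ea_B=60000.0, kappa_D=2.0, T_m=331.15, c=0.1, b=0.75)
        out = growth_rate(302.15, Strategy(4.0, 0.25, 0.25), p)
        expected = oracle_r_prime(302.15, 4.0, 0.25, 0.25, p)
        assert out.r_prime == pytest.approx(expected, rel=1e-12)
        prod = out.survival * out.productivity * out.reaction_rate * out.stability
        assert out.r_prime == pytest.approx(prod, rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        M=st.floats(0.1, 30.0),
        p=st.floats(0.01, 0.98),
        frac=st.floats(0.01, 0.99),
        T=st.floats(280.0, 340.0),
    )
    def test_components_multiply(self, M, p, frac, T):
        q = (1.0 - p) * frac
        out = growth_rate(T, Strategy(M, p, q), make_params())
        prod = out.survival * out.productivity * out.reaction_rate * out.stability
        assert out.r_prime == pytest.approx(prod, rel=1e-12)

    def test_continuity_in_strategy(self):
        p = make_params()
        rng = np.random.default_rng(5)
        for _ in range(10):
            M = rng.uniform(1, 20)
            pp = rng.uniform(0.05, 0.45)
            qq = rng.uniform(0.05, 0.45)
            base = growth_rate(305.0, Strategy(M, pp, qq), p).r_prime
            eps = 1e-7
            for dM, dp, dq in ((eps, 0, 0), (0, eps, 0), (0, 0, eps)):
                shifted = growth_rate(305.0, Strategy(M + dM, pp + dp, qq + dq), p).r_prime
                assert abs(shifted - base) < 1e-4 * max(base, 1e-30) + 1e-30

    def test_pure_arrhenius_limit(self):
        # kappa_D -> 0 forces the stability factor to 1; r'(T) must then be
        # strictly increasing and match the closed Arrhenius form pointwise
        p = make_params(kappa_D=1e-300)
        s = Strategy(4.0, 0.25, 0.25)
        T = np.linspace(280.0, 340.0, 31)
        r = np.array([growth_rate(t, s, p).r_prime for t in T])
        assert np.all(np.diff(r) > 0)
        prefactor = (
            juvenile_survival(s.M, p.c) * productivity(s, p.b) * p.a_B * s.p * s.M
        )
        closed = prefactor * np.exp(-p.Ea_B / (8.314 * T))
        np.testing.assert_allclose(r, closed, rtol=1e-9)


class TestImpact:
    def test_zero_strategy(self):
        assert agricultural_impact(300.0, Strategy(4.0, 0.0, 0.2), make_params()) == 0.0

    def test_unit_reserves_identity(self):
        p = make_params()
        s = Strategy(1.0, 0.25, 0.25)
        assert agricultural_impact(300.0, s, p) == growth_rate(300.0, s, p).r_prime

    def test_scaling(self):
        p = make_params()
        s = Strategy(4.0, 0.25, 0.25)
        out = growth_rate(302.15, s, p)
        assert out.impact == pytest.approx(4.0 * out.r_prime, rel=1e-15)


class TestRelativeResponse:
    def test_basic(self):
        np.testing.assert_allclose(relative_response([2.0, 4.0], 4.0), [0.5, 1.0])
        np.testing.assert_allclose(relative_response([0.0], 5.0), [0.0])
        np.testing.assert_allclose(relative_response([3.3, 6.6, 9.9], 3.3), [1.0, 2.0, 3.0])

    def test_invalid_reference(self):
        for ref in (0.0, -1.0):
            with pytest.raises(InvalidInputError):
                relative_response([1.0], ref)


class TestValidation:
    def test_strategy_invariants(self):
        with pytest.raises(InvalidInputError):
            Strategy(0.0, 0.2, 0.2)
        with pytest.raises(InvalidInputError):
            Strategy(1.0, -0.1, 0.2)
        with pytest.raises(InvalidInputError):
            Strategy(1.0, 0.7, 0.7)

    def test_params_invariants(self):
        with pytest.raises(InvalidInputError):
            make_params(Ea_B=-1.0)
        with pytest.raises(InvalidInputError):
            make_params(T_m=200.0)
        with pytest.raises(InvalidInputError):
            make_params(c=1.0)
        with pytest.raises(InvalidInputError):
            make_params(b=0.0)
        with pytest.raises(InvalidInputError):
            make_params(dH_m=math.inf)


class TestVectorizedGrid:
    def test_agrees_with_scalar(self, oracle_r_prime):
        p = make_params()
        rng = np.random.default_rng(7)
        M = rng.uniform(0.5, 20, 50)
        pp = rng.uniform(0, 1, 50)
        qq = rng.uniform(0, 1, 50)
        grid = r_prime_grid(305.0, M, pp, qq, p)
        for i in range(50):
            if pp[i] + qq[i] <= 1:
                expected = oracle_r_prime(305.0, M[i], pp[i], qq[i], p)
            else:
                expected = 0.0
            assert grid[i] == pytest.approx(expected, rel=1e-12, abs=1e-300)
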