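"""Model right-hand sides, insulin input interpolation and steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glufa import (
    Mod1Params,
    Mod2Params,
    Mod3Params,
    ModelState,
    TimeSeries,
    insulin_input,
    rhs_mod1,
    rhs_mod2,
    rhs_mod3,
    steady_state,
)
from glufa.errors import (
    InvalidInputError,
    InvalidParameterError,
    NoSteadyStateError,
)

MOD1 = Mod1Params(
    S_G=5.6e-3, G_b=136.4, S_I=3.2e-4, C_x=0.12, I_bx=4.6,
    l_0=0.006, l_2=0.12, X_2=12.7, C_f=0.047, K_Cl=21.7,
)
MOD2 = Mod2Params(
    S_G=6.5e-3, G_b=179.3, S_I=3.9e-4, C_x=0.11, I_bx=7.4,
    l_0=0.033, l_2=0.23, X_2=13.4, A_l=2.1, C_f0=0.23,
)
MOD3 = Mod3Params(
    V_m_Lip=0.54, t_DelayLip=26.9, K_Lip=25.2, h_lip=4.1,
    k_Rem=0.33, V_m_Rem=0.11, t_DelayRem=12.0, K_Rem=47.4, h_Rem=5.3,
)

FLAT_INSULIN = TimeSeries([-10.0, 400.0], [4.6, 4.6])


class TestInsulinInput:
    def test_exact_at_knots_and_linear_midpoint(self):
        ts = TimeSeries([0.0, 10.0], [10.0, 20.0])
        assert insulin_input(0.0, ts) == 10.0
        assert insulin_input(10.0, ts) == 20.0
        assert insulin_input(5.0, ts) == 15.0

    def test_clamps_outside_record(self):
        ts = TimeSeries([0.0, 10.0], [10.0, 20.0])
        assert insulin_input(-5.0, ts) == 10.0
        assert insulin_input(3.0, ts, delay=8.0) == 10.0  # t - delay < 0
        assert insulin_input(50.0, ts) == 20.0

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            TimeSeries([5.0, 1.0], [1.0, 2.0])  # non-monotone grid
        with pytest.raises(InvalidInputError):
            TimeSeries([], [])
        with pytest.raises(InvalidInputError):
            insulin_input(0.0, TimeSeries([1.0], [2.0]))  # single sample
        with pytest.raises(InvalidInputError):
            insulin_input(0.0, TimeSeries([0.0, 1.0], [1.0, 2.0]), delay=-1.0)


class TestMod1:
    def test_basal_glucose_balance(self):
        d = rhs_mod1(0.0, ModelState(MOD1.G_b, 0.0, 1.0), MOD1, FLAT_INSULIN)
        assert d[0] == pytest.approx(0.0, abs=1e-14)

    def test_action_steady_state_under_constant_insulin(self):
        ins = TimeSeries([-10.0, 400.0], [30.0, 30.0])
        x_eq = 30.0 - MOD1.I_bx
        d = rhs_mod1(0.0, ModelState(100.0, x_eq, 1.0), MOD1, ins)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_ffa_steady_state_by_substitution(self):
        f_eq = (MOD1.l_0 + MOD1.l_2) / MOD1.C_f
        d = rhs_mod1(0.0, ModelState(MOD1.G_b, 0.0, f_eq), MOD1, FLAT_INSULIN)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_negative_action_clamped_in_hill_terms(self):
        d = rhs_mod1(0.0, ModelState(100.0, -3.0, 1.0), MOD1, FLAT_INSULIN)
        assert np.all(np.isfinite(d))
        # the FFA equation sees clamped X=0 (Hill terms only)
        d0 = rhs_mod1(0.0, ModelState(100.0, 0.0, 1.0), MOD1, FLAT_INSULIN)
        assert d[2] == pytest.approx(d0[2], abs=1e-14)

    @given(st.floats(0.0, 200.0), st.floats(0.0, 200.0))
    @settings(max_examples=30, deadline=None)
    def test_lipolysis_nonincreasing_and_clearance_bounded(self, x1, x2):
        lo, hi = sorted((x1, x2))

        def lip(x):
            return MOD1.l_0 + MOD1.l_2 / (1.0 + (x / MOD1.X_2) ** MOD1.A_lipo)

        def clr(x):
            h = (x / MOD1.K_Cl) ** MOD1.A_Cl
            return MOD1.C_f * (1.0 + h / (1.0 + h))

        assert lip(hi) <= lip(lo) + 1e-12
        assert clr(lo) <= clr(hi) + 1e-12
        assert MOD1.C_f - 1e-12 <= clr(hi) <= 2.0 * MOD1.C_f + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            Mod1Params(
                S_G=0.01, G_b=100, S_I=1e-4, C_x=0.1, I_bx=5,
                l_0=0.01, l_2=0.1, X_2=0.0, C_f=0.05, K_Cl=20,
            )
        with pytest.raises(InvalidParameterError):
            Mod1Params(
                S_G=-0.01, G_b=100, S_I=1e-4, C_x=0.1, I_bx=5,
                l_0=0.01, l_2=0.1, X_2=10, C_f=0.05, K_Cl=20,
            )


class TestMod2:
    def test_ffa_steady_state(self):
        f_eq = (MOD2.l_0 + MOD2.l_2) / MOD2.C_f0
        ins = TimeSeries([-10.0, 400.0], [MOD2.I_bx, MOD2.I_bx])
        d = rhs_mod2(0.0, ModelState(MOD2.G_b, 0.0, f_eq), MOD2, ins)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_lipolysis_saturates_to_basal_at_high_action(self):
        d = rhs_mod2(0.0, ModelState(100.0, 1e9, 0.0), MOD2, FLAT_INSULIN)
        assert d[2] == pytest.approx(MOD2.l_0, rel=1e-10)

    def test_glucose_equation_shared_with_mod1(self):
        p1 = Mod1Params(
            S_G=MOD2.S_G, G_b=MOD2.G_b, S_I=MOD2.S_I, C_x=MOD2.C_x,
            I_bx=MOD2.I_bx, l_0=0.01, l_2=0.1, X_2=10.0, C_f=0.05, K_Cl=20.0,
        )
        s = ModelState(150.0, 7.0, 1.0)
        ins = TimeSeries([-10.0, 400.0], [25.0, 25.0])
        d1 = rhs_mod1(0.0, s, p1, ins)
        d2 = rhs_mod2(0.0, s, MOD2, ins)
        assert d1[0] == pytest.approx(d2[0], rel=1e-14)
        assert d1[1] == pytest.approx(d2[1], rel=1e-14)


class TestMod3:
    def test_clearance_half_maximum_at_k_rem(self):
        # steady insulin equal to K_Rem everywhere: stimulated clearance
        # sits at half V_m_Rem
        ins = TimeSeries([-100.0, 500.0], [MOD3.K_Rem, MOD3.K_Rem])
        lip = MOD3.V_m_Lip / (1.0 + (MOD3.K_Rem / MOD3.K_Lip) ** MOD3.h_lip)
        d = rhs_mod3(100.0, 1.0, MOD3, ins)
        expected = lip - (MOD3.k_Rem + MOD3.V_m_Rem / 2.0) * 1.0
        assert d == pytest.approx(expected, rel=1e-12)

    def test_saturation_limits(self):
        huge = TimeSeries([-100.0, 500.0], [1e9, 1e9])
        d = rhs_mod3(100.0, 1.0, MOD3, huge)
        assert d == pytest.approx(-(MOD3.k_Rem + MOD3.V_m_Rem), rel=1e-6)

    def test_zero_insulin_steady_state(self):
        zero = TimeSeries([-100.0, 500.0], [0.0, 0.0])
        f_eq = MOD3.V_m_Lip / MOD3.k_Rem
        assert rhs_mod3(100.0, f_eq, MOD3, zero) == pytest.approx(0.0, abs=1e-12)

    def test_zero_half_effect_insulin_rejected(self):
        with pytest.raises(InvalidParameterError):
            Mod3Params(
                V_m_Lip=1, t_DelayLip=10, K_Lip=0.0, h_lip=2,
                k_Rem=0.1, V_m_Rem=0.1, t_DelayRem=10, K_Rem=50, h_Rem=2,
            )


class TestSteadyState:
    @pytest.mark.parametrize(
        "params, expected_f",
        [
            (MOD1, (MOD1.l_0 + MOD1.l_2) / MOD1.C_f),
            (MOD2, (MOD2.l_0 + MOD2.l_2) / MOD2.C_f0),
            (MOD3, MOD3.V_m_Lip / MOD3.k_Rem),
        ],
    )
    def test_fixed_point_values(self, params, expected_f):
        ss = steady_state(params)
        assert ss.F == pytest.approx(expected_f, rel=1e-14)

    def test_rhs_vanishes_at_fixed_point_under_basal_input(self):
        for p, rhs in ((MOD1, rhs_mod1), (MOD2, rhs_mod2)):
            ss = steady_state(p)
            basal = TimeSeries([-10.0, 400.0], [p.I_bx, p.I_bx])
            assert np.max(np.abs(rhs(0.0, ss, p, basal))) < 1e-12
        ss3 = steady_state(MOD3)
        zero = TimeSeries([-10.0, 400.0], [0.0, 0.0])
        assert abs(rhs_mod3(0.0, ss3.F, MOD3, zero)) < 1e-12

    def test_zero_clearance_has_no_steady_state(self):
        p = Mod2Params(
            S_G=0.01, G_b=100, S_I=1e-4, C_x=0.1, I_bx=5,
            l_0=0.01, l_2=0.1, X_2=10, A_l=2.0, C_f0=0.0,
        )
        with pytest.raises(NoSteadyStateError):
            steady_state(p)
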