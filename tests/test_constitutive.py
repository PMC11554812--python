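"""Constitutive pressure–area laws and the coefficients derived from them."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoperf import constitutive as law
from myoperf.params import ParameterSet

PRM = ParameterSet()
DP_RANGE = (-1e4, 2e4)  # Pa, physiological transluminal range

# independently evaluated printed-coefficient values (frozen oracles)
A2_AT_0 = 0.0011 * np.log(3500.0) - 0.0033  # logarithmic branch at Δp = 0
A3_AT_0 = 1e-6 + 2.4e-5 / (1.0 + np.exp(-0.5))


class TestArea:
    def test_small_arteries_rigid(self):
        for dp in (-5e3, 0.0, 1e4):
            assert law.area(1, dp) == 0.07
            assert law.distensibility(1, dp) == 0.0

    def test_arteriolar_negative_asymptote(self):
        assert law.area(2, -1e7) == pytest.approx(0.003, rel=1e-9)

    def test_arteriolar_log_branch_at_zero(self):
        assert law.area(2, 0.0) == pytest.approx(A2_AT_0, rel=1e-12)

    def test_capillary_at_zero(self):
        assert law.area(3, 0.0) == pytest.approx(A3_AT_0, rel=1e-12)

    def test_capillary_asymptotes(self):
        assert law.area(3, -1e7) == pytest.approx(1e-6, rel=1e-9)
        assert law.area(3, 1e7) == pytest.approx(2.5e-5, rel=1e-9)

    def test_saturation_bounds(self):
        dp = np.linspace(*DP_RANGE, 2001)
        a2, a3 = law.area(2, dp), law.area(3, dp)
        assert np.all((a2 >= 0.003) & (a2 <= 0.008))
        assert np.all((a3 >= 1e-6) & (a3 <= 2.5e-5))

    def test_branch_convention_at_zero_is_logarithmic(self):
        sig_at_0 = 0.0030 + 0.0050 / 2.0
        assert law.area(2, 0.0) != pytest.approx(sig_at_0, rel=1e-3)
        assert law.area(2, 0.0) == pytest.approx(A2_AT_0, rel=1e-12)

    def test_junction_jump_small(self):
        # the printed sigmoid/log coefficients leave a ~3.1% value gap at Δp=0
        lo, hi = law.area(2, -1e-9), law.area(2, 0.0)
        jump = abs(hi - lo) / hi
        assert jump == pytest.approx(0.0311, abs=0.002)
        assert jump < 0.035

    def test_invalid_compartment_raises(self):
        with pytest.raises(ValueError):
            law.area(0, 0.0)
        with pytest.raises(ValueError):
            law.distensibility(4, 0.0)


class TestDistensibility:
    def test_analytic_derivative_matches_finite_difference(self):
        dp = np.linspace(DP_RANGE[0], DP_RANGE[1], 401)
        dp = dp[np.abs(dp) > 1.0]  # avoid straddling the Δp=0 branch switch
        h = 1e-2
        for i in (2, 3):
            fd = (np.asarray(law.area(i, dp + h)) -
                  np.asarray(law.area(i, dp - h))) / (2 * h)
            an = np.asarray(law.distensibility(i, dp))
            assert np.allclose(an, fd, rtol=1e-6)

    def test_matches_printed_formulas_within_rounding(self):
        dp = np.linspace(*DP_RANGE, 801)
        for i in (2, 3):
            exact = np.asarray(law.distensibility(i, dp))
            printed = np.asarray(law.distensibility_printed(i, dp))
            assert np.all(np.abs(exact - printed) <= 0.02 * np.abs(exact))

    def test_printed_arteriolar_value_gap(self):
        # at Δp = 2000 Pa: exact derivative vs rounded published numerator
        exact = law.distensibility(2, 2000.0)
        printed = law.distensibility_printed(2, 2000.0)
        assert exact == pytest.approx(0.0011 * 1.2 / 5900.0, rel=1e-12)
        assert printed == pytest.approx(0.0013 / 5900.0, rel=1e-12)
        assert abs(exact - printed) / exact < 0.02

    def test_sigmoid_saturation_kills_compliance(self):
        assert law.distensibility(3, -1e7) == pytest.approx(0.0, abs=1e-20)
        assert law.distensibility(3, 1e7) == pytest.approx(0.0, abs=1e-20)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(min_value=DP_RANGE[0], max_value=DP_RANGE[1]))
    def test_nonnegative_everywhere(self, dp):
        for i in (1, 2, 3):
            assert law.distensibility(i, dp) >= 0.0

    def test_junction_slope_gap_small(self):
        left = law.distensibility(2, -1e-9)
        right = law.distensibility(2, 0.0)
        assert abs(left - right) / right < 0.02


class TestMonotonicity:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(min_value=DP_RANGE[0], max_value=DP_RANGE[1] - 1.0),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_areas_nondecreasing(self, dp, step):
        for i in (2, 3):
            assert law.area(i, dp + step) >= law.area(i, dp) - 1e-15


class TestDerivedCoefficients:
    def test_porosity_values(self):
        assert law.porosity(1, 0.0, PRM) == pytest.approx(0.035, rel=1e-12)
        assert law.porosity(3, 0.0, PRM) == pytest.approx(8000 * A3_AT_0, rel=1e-12)

    def test_porosity_zero_length_density(self):
        prm = PRM.replace(length_density=(1e-300, 15.0, 8000.0))
        assert law.porosity(1, 0.0, prm) == pytest.approx(0.0, abs=1e-200)

    def test_permeability_value_and_proportionality(self):
        assert law.permeability(1, 0.0, PRM) == pytest.approx(1.75e-9, rel=1e-12)
        dp = np.linspace(*DP_RANGE, 101)
        k2 = np.asarray(law.permeability(2, dp, PRM))
        a2 = np.asarray(law.area(2, dp))
        np.testing.assert_allclose(k2 / a2, k2[0] / a2[0], rtol=1e-12)

    def test_conductance_values(self):
        b2 = 0.05 * 15.0 * A2_AT_0**2
        b3 = 10.0 * 8000.0 * A3_AT_0**2
        assert law.compartment_conductance(2, 0.0, PRM) == pytest.approx(b2, rel=1e-12)
        assert law.compartment_conductance(3, 0.0, PRM) == pytest.approx(b3, rel=1e-12)
        assert law.exchange_conductance(2, 3, 0.0, 0.0, PRM) == pytest.approx(
            (b2 + b3) / 2.0, rel=1e-12)

    def test_exchange_symmetry_and_adjacency(self):
        dp = np.linspace(-5e3, 1.5e4, 7)
        for a, b in ((1, 2), (2, 3)):
            ab = np.asarray(law.exchange_conductance(a, b, dp, dp / 2, PRM))
            ba = np.asarray(law.exchange_conductance(b, a, dp / 2, dp, PRM))
            np.testing.assert_allclose(ab, ba, rtol=1e-15)
        assert np.all(np.asarray(
            law.exchange_conductance(1, 3, dp, dp, PRM)) == 0.0)
        assert np.all(np.asarray(
            law.exchange_conductance(1, 3, dp, dp, PRM, all_pairs=True)) > 0.0)

    def test_exchange_same_compartment_raises(self):
        with pytest.raises(ValueError):
            law.exchange_conductance(2, 2, 0.0, 0.0, PRM)


class TestRefit:
    def test_c2_refit_restores_smooth_junction(self):
        coeffs = law.refit_a2_sigmoid()
        a_min, b, k, s = coeffs
        # targets: value/slope/curvature of the logarithmic branch at Δp = 0
        v0 = 0.0011 * np.log(3500.0) - 0.0033
        c1 = 0.0011 * 1.2 / 3500.0
        c2 = -0.0011 * 1.2**2 / 3500.0**2
        sig0 = 1.0 / (1.0 + np.exp(-s))
        assert a_min + b * sig0 == pytest.approx(v0, rel=1e-9)
        assert b * k * sig0 * (1 - sig0) == pytest.approx(c1, rel=1e-9)
        assert b * k**2 * sig0 * (1 - sig0) * (1 - 2 * sig0) == pytest.approx(
            c2, rel=1e-9)
        assert law.area2_refit(-1e-9, coeffs) == pytest.approx(v0, rel=1e-6)

    def test_refit_keeps_asymptotic_minimum(self):
        assert law.area2_refit(-1e8) == pytest.approx(0.003, rel=1e-6)


def test_tabulation_roundtrip(tmp_path):
    import pandas as pd
    dp = np.linspace(-2e3, 2e3, 11)
    path = tmp_path / "curves.csv"
    df = law.tabulate_curves(dp, path)
    back = pd.read_csv(path)
    np.testing.assert_allclose(back["A2_mm2"], df["A2_mm2"], rtol=1e-12)
    assert set(df.columns) == {"dp_Pa", "A1_mm2", "C1_mm2_per_Pa", "A2_mm2",
                               "C2_mm2_per_Pa", "A3_mm2", "C3_mm2_per_Pa"}
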