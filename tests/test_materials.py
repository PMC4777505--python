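"""Material laws: tissue conductivity, thermal conductivity, apparent heat
capacity with the vaporization plateau."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from rfablate import materials as mat


class TestSigmaTissue:
    @pytest.mark.parametrize("T,sigma_o,expected", [
        (37.0, 0.12, 0.12),                      # reference point
        (100.0, 1.0, 2.5728),                    # +1.5%/degC growth at 100
        (102.5, 1.0, 2.5728 - 0.5145 * 2.5),     # mid desiccation ramp
        (110.0, 1.0, 2.5728e-4),                 # desiccated plateau
    ])
    def test_printed_values(self, T, sigma_o, expected):
        assert mat.sigma_tissue(T, sigma_o) == pytest.approx(expected,
                                                             rel=1e-4)

    def test_continuity_at_100(self):
        lo = mat.sigma_tissue(100.0 - 1e-9, 1.0)
        hi = mat.sigma_tissue(100.0 + 1e-9, 1.0)
        assert lo == pytest.approx(hi, rel=1e-4)

    def test_near_continuity_at_105(self):
        """The printed ramp and plateau coefficients agree at 105 degC only
        to their rounding (3.0e-4 vs 2.5728e-4); the clamp keeps the value
        positive and within that rounding band."""
        lo = mat.sigma_tissue(105.0 - 1e-9, 1.0)
        hi = mat.sigma_tissue(105.0 + 1e-9, 1.0)
        assert hi <= lo <= 1.2 * hi

    def test_four_decade_desiccation_drop(self):
        ratio = mat.sigma_tissue(110.0, 1.0) / mat.sigma_tissue(100.0, 1.0)
        assert ratio == pytest.approx(1e-4, rel=1e-3)

    @given(st.floats(min_value=0.0, max_value=200.0),
           st.floats(min_value=0.0, max_value=200.0))
    def test_piecewise_monotonicity(self, t1, t2):
        a, b = sorted((t1, t2))
        sa, sb = mat.sigma_tissue(a, 0.12), mat.sigma_tissue(b, 0.12)
        if b <= 100.0:
            assert sa <= sb * (1 + 1e-12)
        elif a >= 100.0:
            assert sa >= sb * (1 - 1e-12)
        assert 0 < sb <= 0.12 * 2.5728 * (1 + 1e-12)

    def test_vectorized_and_pure(self):
        T = np.array([37.0, 80.0, 101.0, 120.0])
        out1 = mat.sigma_tissue(T, 0.12)
        out2 = mat.sigma_tissue(T, 0.12)
        np.testing.assert_array_equal(out1, out2)
        assert out1.shape == T.shape

    def test_rejects_bad_sigma_o(self):
        with pytest.raises(ValueError):
            mat.sigma_tissue(50.0, 0.0)


class TestKTissue:
    @pytest.mark.parametrize("T,k_o,expected", [
        (37.0, 0.531, 0.531),
        (100.0, 0.531, 0.531 + 0.0756),
        (150.0, 0.531, 0.6066),
    ])
    def test_values(self, T, k_o, expected):
        assert mat.k_tissue(T, k_o) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(min_value=-20.0, max_value=300.0),
           st.floats(min_value=-20.0, max_value=300.0))
    def test_non_decreasing(self, t1, t2):
        a, b = sorted((t1, t2))
        assert mat.k_tissue(a) <= mat.k_tissue(b) + 1e-15

    def test_rejects_bad_k_o(self):
        with pytest.raises(ValueError):
            mat.k_tissue(50.0, -1.0)


class TestApparentHeatCapacity:
    @pytest.mark.parametrize("T,expected", [
        (50.0, 1060.0 * 3111.0),            # liquid phase
        (99.5, 2.162e9 * 0.75),             # latent plateau
        (110.0, 370.44 * 2155.92),          # gas phase
    ])
    def test_branch_values(self, T, expected):
        assert mat.apparent_volumetric_heat_capacity(T) == pytest.approx(
            expected, rel=1e-9)

    def test_enthalpy_integral_consistency(self):
        """Integrating d(rho h)/dT over [98, 101] recovers one degree of
        each branch."""
        pc = mat.PhaseChangeParams()
        val, _ = quad(mat.apparent_volumetric_heat_capacity, 98.0, 101.0,
                      args=(pc,), points=[99.0, 100.0], limit=200)
        expected = pc.rho_l * pc.c_l + pc.H_fg * pc.C + pc.rho_g * pc.c_g
        assert val == pytest.approx(expected, rel=1e-6)

    def test_latent_heat_is_volumetric_product(self):
        """2257 kJ/kg x 958 kg/m^3 = 2.162e9 J/m^3 (with water content
        0.75 applied separately inside the plateau branch)."""
        assert 2257e3 * 958.0 == pytest.approx(2.162e9, rel=1e-3)
        pc = mat.PhaseChangeParams()
        assert pc.H_fg == pytest.approx(2.162e9)
        assert pc.C == 0.75

    def test_slowdown_factor(self):
        pc = mat.PhaseChangeParams()
        assert pc.slowdown_factor == pytest.approx(
            2.162e9 * 0.75 / (1060.0 * 3111.0), rel=1e-9)
        assert pc.slowdown_factor == pytest.approx(491.0, rel=0.01)


class TestPropertyTables:
    def test_table_defaults(self):
        p = mat.REGION_PROPS
        assert p["electrode"].sigma == 4.6e6
        assert p["electrode"].k == 71.0
        assert p["thermistor"].rho == 32.0
        assert p["catheter"].c == 1045.0
        assert p["blood"].sigma == 0.667
        assert p["tissue"].rho == 1060.0
        assert p["tissue_gas"].c == 2155.92

    def test_round_trip(self):
        table = mat.props_to_table()
        back = mat.props_from_table(table)
        assert back == mat.REGION_PROPS

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            mat.MaterialProps("x", sigma=-1.0, k=1.0, rho=1.0, c=1.0)
        with pytest.raises(ValueError):
            mat.PhaseChangeParams(T_lower=100.0, T_upper=99.0)
        with pytest.raises(ValueError):
            mat.PhaseChangeParams(C=1.5)
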