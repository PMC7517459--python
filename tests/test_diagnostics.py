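import numpy as np
import pytest

from kkpeusner import (
    CPCoefficientSet,
    Environment,
    classify_signs,
    evaluate_profile,
    rform_coefficients,
    xi_coefficients,
    xi_simplified,
    zeta_difference_factors,
    zeta_from_delta,
)

C2BAR = 37.71
ENV = Environment()
HOM = CPCoefficientSet.homogeneous()


def matrices_at(membrane, c1bar, zeta_a, zeta_b):
    ma = rform_coefficients(membrane, CPCoefficientSet.reduced(zeta_a, zeta_a, "A"), c1bar, C2BAR)
    mb = rform_coefficients(membrane, CPCoefficientSet.reduced(zeta_b, zeta_b, "B"), c1bar, C2BAR)
    mh = rform_coefficients(membrane, HOM, c1bar, C2BAR)
    return ma, mb, mh


class TestXiCoefficients:
    def test_identical_matrices_give_zero(self, membrane):
        ma, mb, mh = matrices_at(membrane, 5.0, 0.4, 0.4)
        summary = xi_coefficients(ma, mb, mh)
        assert np.allclose(summary.xi, 0.0)
        assert summary.xi_det == pytest.approx(0.0, abs=1e-12)
        assert np.all(summary.interpretation == "critical")

    def test_antisymmetric_under_configuration_swap(self, membrane):
        ma, mb, mh = matrices_at(membrane, 2.0, 0.5, 0.03)
        fwd = xi_coefficients(ma, mb, mh)
        rev = xi_coefficients(mb, ma, mh)
        assert np.allclose(fwd.xi, -rev.xi, rtol=1e-12)
        assert fwd.xi_det == pytest.approx(-rev.xi_det, rel=1e-12)

    def test_zero_at_critical_concentration_with_profiles(self, membrane, profiles):
        za = evaluate_profile(profiles[0], 9.24)
        zb = evaluate_profile(profiles[1], 9.24)
        summary = xi_coefficients(*matrices_at(membrane, 9.24, za, zb))
        assert np.allclose(summary.xi, 0.0, atol=1e-9)

    def test_sign_flips_across_crossing(self, membrane, profiles):
        # every entry changes sign between the two sides of the critical
        # concentration
        lo = xi_coefficients(
            *matrices_at(membrane, 2.0, evaluate_profile(profiles[0], 2.0), evaluate_profile(profiles[1], 2.0))
        )
        hi = xi_coefficients(
            *matrices_at(
                membrane, 15.0, evaluate_profile(profiles[0], 15.0), evaluate_profile(profiles[1], 15.0)
            )
        )
        assert np.all(np.sign(lo.xi) == -np.sign(hi.xi))
        assert np.sign(lo.xi_det) == -np.sign(hi.xi_det)
        # below the crossing configuration B carries the larger resistances
        assert np.all(lo.xi < 0)
        assert lo.xi_det < 0

    def test_variant_mismatch_rejected(self, membrane):
        ma, _, mh = matrices_at(membrane, 5.0, 0.5, 0.3)
        printed = rform_coefficients(
            membrane, CPCoefficientSet.reduced(0.3, 0.3, "B"), 5.0, C2BAR, variant="as_printed"
        )
        with pytest.raises(ValueError):
            xi_coefficients(ma, printed, mh)


class TestXiSimplified:
    def test_equal_zetas_give_zero(self, membrane):
        summary = xi_simplified(0.4, 0.4, membrane, 5.0, C2BAR)
        assert np.allclose(summary.xi, 0.0)
        assert summary.xi_det == 0.0

    def test_plateau_zetas(self, membrane):
        summary = xi_simplified(0.5, 0.03, membrane, 2.0, C2BAR)
        f = (0.5 - 0.03) / (0.5 * 0.03)
        assert summary.xi[1, 0] == pytest.approx(-f)  # -31.333
        assert summary.xi[1, 0] == pytest.approx(-31.333, abs=1e-3)
        assert summary.xi[2, 0] == summary.xi[1, 0]
        assert summary.xi[1, 1] == -summary.xi[1, 0]

    def test_determinant_closed_form(self, membrane):
        summary = xi_simplified(0.5, 0.03, membrane, 2.0, C2BAR)
        expected = (0.5**2 - 0.03**2) / (0.5**2 * 0.03**2)
        assert summary.xi_det == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_zeta_rejected(self, membrane):
        with pytest.raises(ValueError):
            xi_simplified(0.0, 0.5, membrane, 2.0, C2BAR)

    @pytest.mark.parametrize("zeta_a, zeta_b", [(0.5, 0.05), (0.05, 0.5), (0.3, 0.6), (0.9, 0.95)])
    def test_magnitudes_match_matrix_definition(self, membrane, zeta_a, zeta_b):
        """The closed forms reproduce |xi| from actual matrices within 5%
        for the reduced CP model.  The published forms carry the opposite
        sign for the entries scaling as 1/zeta (all but the (2,1) and
        (3,1) positions); magnitudes are what the approximation controls.
        """
        for c1bar in (2.0, 9.0, 20.0):
            full = xi_coefficients(*matrices_at(membrane, c1bar, zeta_a, zeta_b))
            simp = xi_simplified(zeta_a, zeta_b, membrane, c1bar, C2BAR)
            assert np.allclose(np.abs(full.xi), np.abs(simp.xi), rtol=0.05)
            assert abs(full.xi_det) == pytest.approx(abs(simp.xi_det), rel=0.05)
            # sign structure: same sign at (2,1)/(3,1), opposite elsewhere
            same = np.sign(full.xi) == np.sign(simp.xi)
            expected_same = np.zeros((3, 3), dtype=bool)
            expected_same[1, 0] = expected_same[2, 0] = True
            assert np.array_equal(same, expected_same)


class TestZetaDifferenceFactors:
    OMEGA, D = 0.8e-9, 0.69e-9

    def test_equal_layers_give_zero(self, membrane):
        assert zeta_difference_factors(0.4, 0.4, self.OMEGA, self.D, ENV) == (0.0, 0.0)

    def test_factors_match_direct_zeta_arithmetic(self):
        za, zb = 0.5, 0.03
        first, second = zeta_difference_factors(za, zb, self.OMEGA, self.D, ENV)
        assert first == pytest.approx((za - zb) / (za * zb), rel=1e-10)
        assert second == pytest.approx((za**2 - zb**2) / (za**2 * zb**2), rel=1e-10)

    def test_plateau_layer_thickness_difference(self):
        # zetas implied by the plateau layer thicknesses 0.52 mm and
        # 3.95 mm; their difference of 3.43 mm sets the first factor
        za = zeta_from_delta(self.OMEGA, self.D, self.D, 0.52e-3, 0.52e-3, ENV)
        zb = zeta_from_delta(self.OMEGA, self.D, self.D, 3.95e-3, 3.95e-3, ENV)
        first, _ = zeta_difference_factors(za, zb, self.OMEGA, self.D, ENV)
        expected = 2 * ENV.RT * self.OMEGA * (3.95e-3 - 0.52e-3) / self.D
        assert first == pytest.approx(expected, rel=1e-9)
        assert first == pytest.approx(19.716, abs=5e-3)


class TestClassifySigns:
    def test_identical_matrices_all_critical(self, membrane):
        ma, mb, mh = matrices_at(membrane, 5.0, 0.4, 0.4)
        table = classify_signs(xi_coefficients(ma, mb, mh), ma, mb, mh)
        assert set(table["interpretation"]) == {"critical"}
        assert set(table["ordering"]) == {"A=B"}

    def test_below_crossing_all_convection_up(self, membrane, profiles):
        za = evaluate_profile(profiles[0], 2.0)
        zb = evaluate_profile(profiles[1], 2.0)
        ma, mb, mh = matrices_at(membrane, 2.0, za, zb)
        table = classify_signs(xi_coefficients(ma, mb, mh), ma, mb, mh)
        assert set(table["xi_sign"]) == {"negative"}
        row11 = table[table["entry"] == "xi_11"].iloc[0]
        assert row11["base_sign"] == "positive"
        assert row11["ordering"] == "A<B"  # smaller resistance where convection stirs

    def test_above_crossing_all_convection_down(self, membrane, profiles):
        za = evaluate_profile(profiles[0], 15.0)
        zb = evaluate_profile(profiles[1], 15.0)
        ma, mb, mh = matrices_at(membrane, 15.0, za, zb)
        table = classify_signs(xi_coefficients(ma, mb, mh), ma, mb, mh)
        assert set(table["xi_sign"]) == {"positive"}

    def test_table_covers_all_entries_and_determinant(self, membrane):
        ma, mb, mh = matrices_at(membrane, 5.0, 0.5, 0.3)
        table = classify_signs(xi_coefficients(ma, mb, mh), ma, mb, mh)
        assert len(table) == 10
        assert "xi_det" in set(table["entry"])
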