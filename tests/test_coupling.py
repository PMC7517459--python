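import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kkpeusner import (
    CPCoefficientSet,
    MembranePracticalCoefficients,
    coupling_sweep_summary,
    degree_of_coupling,
    e_max,
    energy_conversion,
    evaluate_profile,
    qr_parameter,
    rform_coefficients,
)
from kkpeusner.coupling import coupling_statistics
from kkpeusner.resistance import ResistanceMatrix

C2BAR = 37.71
HOM = CPCoefficientSet.homogeneous()

unit_r = st.floats(min_value=-0.99, max_value=0.99, allow_nan=False)


class TestDegreeOfCoupling:
    def test_zero_off_diagonal_gives_zero(self):
        entries = np.diag([2.0, 3.0, 4.0])
        m = ResistanceMatrix(entries, "strict_inverse", "homogeneous", 1.0, 1.0, det=24.0)
        assert degree_of_coupling(m, 1, 2) == 0.0

    def test_reference_r12_at_high_concentration(self, membrane):
        m = rform_coefficients(membrane, HOM, 21.67, C2BAR)
        assert degree_of_coupling(m, 1, 2, "reduced") == pytest.approx(0.305, abs=0.001)

    def test_near_reciprocity_homogeneous(self, membrane):
        # r12 and r21 differ only through the tiny omega12*c2bar term
        for c1bar in np.linspace(1.0, 22.0, 8):
            m = rform_coefficients(membrane, HOM, c1bar, C2BAR)
            r12 = degree_of_coupling(m, 1, 2)
            r21 = degree_of_coupling(m, 2, 1)
            assert abs(r12 - r21) < 0.01

    def test_literal_on_printed_matrix_is_dimensional(self, membrane):
        # auditing mode: the unscaled printed first column yields r21 > 1,
        # which is why "reduced" is the default
        printed = rform_coefficients(membrane, HOM, 21.67, C2BAR, variant="as_printed")
        assert degree_of_coupling(printed, 2, 1, "literal") > 1.0
        assert degree_of_coupling(printed, 2, 1, "reduced") == pytest.approx(0.305, abs=0.001)

    def test_non_positive_diagonal_rejected(self):
        entries = np.diag([-1.0, 3.0, 4.0])
        m = ResistanceMatrix(entries, "strict_inverse", "homogeneous", 1.0, 1.0, det=-12.0)
        with pytest.raises(ValueError):
            degree_of_coupling(m, 1, 2)


class TestEnergyConversion:
    def test_uncoupled_converts_nothing(self):
        assert energy_conversion(0.0, 0.0) == 0.0

    @given(r=unit_r)
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_case_equals_e_max(self, r):
        assert energy_conversion(r, r) == pytest.approx(e_max(r), rel=1e-12)

    def test_reference_pair(self):
        # frozen from direct evaluation at the high-concentration coupling
        # degrees of the reference system
        assert energy_conversion(0.304, 0.305) == pytest.approx(0.0244, abs=1e-4)

    def test_product_above_one_rejected(self):
        with pytest.raises(ValueError):
            energy_conversion(1.2, 0.9)

    def test_monotone_in_product(self):
        values = [energy_conversion(r, r) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert values == sorted(values)


class TestQRParameter:
    def test_uncoupled(self):
        assert qr_parameter(0.0, 0.0) == 0.0

    def test_complete_coupling(self):
        assert qr_parameter(1.0, 1.0) == 1.0

    def test_reference_value(self, membrane):
        m = rform_coefficients(membrane, HOM, 21.67, C2BAR)
        q = qr_parameter(degree_of_coupling(m, 1, 2), degree_of_coupling(m, 2, 1))
        assert q == pytest.approx(0.0488, abs=5e-4)

    @given(r=st.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_closed_form(self, r):
        assert qr_parameter(r, r) == pytest.approx(r**2 / (2 - r**2), rel=1e-12)

    def test_monotone_in_product(self):
        values = [qr_parameter(r, r) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert values == sorted(values)

    def test_product_at_two_rejected(self):
        with pytest.raises(ValueError):
            qr_parameter(1.5, 1.5)


class TestPhysicalBounds:
    @given(
        zeta1=st.floats(min_value=0.03, max_value=1.0),
        zeta2=st.floats(min_value=0.03, max_value=1.0),
        c1bar=st.floats(min_value=0.5, max_value=25.0),
        sigma1=st.floats(min_value=0.0, max_value=0.15),
        sigma2=st.floats(min_value=0.0, max_value=0.15),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_reduced_statistics_bounded(self, zeta1, zeta2, c1bar, sigma1, sigma2):
        """|r| <= 1, 0 <= e <= 1 and 0 <= Q_R <= 1 over randomized draws
        in the leaky-membrane regime (sigma <= 0.15) the model describes.

        The bound is a second-law theorem only for reciprocal (Onsager)
        matrices; concentration polarization breaks reciprocity, and for
        strongly reflective membranes with asymmetric polarization the
        entrywise bound can fail (see
        test_bound_can_fail_for_reflective_membranes)."""
        membrane = MembranePracticalCoefficients(
            Lp=4.9e-12,
            sigma1=sigma1,
            sigma2=sigma2,
            omega11=0.8e-9,
            omega12=0.81e-13,
            omega21=1.63e-12,
            omega22=1.43e-9,
        )
        cp = CPCoefficientSet.reduced(zeta1, zeta2, "A")
        m = rform_coefficients(membrane, cp, c1bar, C2BAR)
        stats = coupling_statistics(m, "reduced")
        for r in stats.r.values():
            assert abs(r) <= 1.0 + 1e-12
        for e in stats.e.values():
            assert -1e-12 <= e <= 1.0
        for q in stats.q.values():
            assert -1e-12 <= q <= 1.0

    def test_bound_can_fail_for_reflective_membranes(self):
        # documented limitation: with sigma1 = 0.5 and strongly
        # asymmetric polarization the non-reciprocal CP matrix violates
        # the entrywise |r| <= 1 bound
        membrane = MembranePracticalCoefficients(
            Lp=4.9e-12,
            sigma1=0.5,
            sigma2=0.0,
            omega11=0.8e-9,
            omega12=0.81e-13,
            omega21=1.63e-12,
            omega22=1.43e-9,
        )
        cp = CPCoefficientSet.reduced(0.03125, 1.0, "A")
        m = rform_coefficients(membrane, cp, 13.0, C2BAR)
        stats = coupling_statistics(m, "reduced")
        assert max(abs(r) for r in stats.r.values()) > 1.0


class TestCouplingSweepSummary:
    def test_profile_curves_cross_near_critical_concentration(self, membrane, profiles):
        grid = np.linspace(2.0, 20.0, 90)
        mats_a, mats_b = [], []
        for c1 in grid:
            za = evaluate_profile(profiles[0], c1)
            zb = evaluate_profile(profiles[1], c1)
            mats_a.append(rform_coefficients(membrane, CPCoefficientSet.reduced(za, za, "A"), c1, C2BAR))
            mats_b.append(rform_coefficients(membrane, CPCoefficientSet.reduced(zb, zb, "B"), c1, C2BAR))
        summary = coupling_sweep_summary(grid, mats_a, mats_b)
        assert summary[(1, 2)]["crossing"] == pytest.approx(9.24, abs=0.5)
        assert summary[(2, 1)]["crossing"] == pytest.approx(9.24, abs=0.5)

    def test_homogeneous_series_configuration_independent(self, membrane):
        grid = np.linspace(1.0, 22.0, 30)
        mats = [rform_coefficients(membrane, HOM, c1, C2BAR) for c1 in grid]
        summary = coupling_sweep_summary(grid, mats, mats)
        for pair_stats in summary.values():
            assert pair_stats["r_A_min"] == pair_stats["r_B_min"]
            assert pair_stats["r_A_max"] == pair_stats["r_B_max"]

    def test_reduced_couplings_within_unit_interval_over_sweep(self, membrane, profiles):
        grid = np.linspace(2.0, 20.0, 40)
        for c1 in grid:
            za = evaluate_profile(profiles[0], c1)
            m = rform_coefficients(membrane, CPCoefficientSet.reduced(za, za, "A"), c1, C2BAR)
            for i, j in ((1, 2), (2, 1), (1, 3), (3, 1)):
                assert 0.0 <= degree_of_coupling(m, i, j) <= 1.0

    def test_unsorted_grid_rejected(self, membrane):
        m = rform_coefficients(membrane, HOM, 5.0, C2BAR)
        with pytest.raises(ValueError):
            coupling_sweep_summary([2.0, 1.0], [m, m], [m, m])
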