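"""Vessel/aneurysm geometry, wall law, and compliance integrals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pulsewave.geometry import (
    AneurysmProfile,
    FluidProperties,
    GeometryError,
    VesselSegment,
    adan_wall_thickness,
    arc_aneurysm_radius,
    compute_K,
    cosine_aneurysm_radius,
    excess_compliance,
    plate_modulus,
    segment_compliance_summary,
    tau_from_geometry,
    wave_speed,
)

A_V = 8.5e-3
L_A = 0.09
R_S = 0.01


class TestWaveSpeed:
    def test_rig_tube_speed_matches_measured(self):
        # rig tube (ID 17 mm, wall 2 mm, E 2.8 MPa, rubber-like) -> ~21 m/s
        c = wave_speed(8.5e-3, 2e-3, 2.8e6, 0.5, 1000.0)
        assert c == pytest.approx(20.96, abs=0.01)

    @pytest.mark.parametrize("factor,expect", [(4.0, 2.0), (0.25, 0.5)])
    def test_sqrt_scaling_in_modulus(self, factor, expect):
        base = wave_speed(8.5e-3, 2e-3, 2.8e6, 0.5)
        assert wave_speed(8.5e-3, 2e-3, factor * 2.8e6, 0.5) \
            == pytest.approx(expect * base)

    def test_inverse_sqrt_scaling_in_radius(self):
        base = wave_speed(8.5e-3, 2e-3, 2.8e6, 0.5)
        assert wave_speed(4 * 8.5e-3, 2e-3, 2.8e6, 0.5) == pytest.approx(base / 2)

    @given(a0=st.floats(1e-3, 0.05), h=st.floats(1e-4, 5e-3),
           E=st.floats(1e4, 1e9), sig=st.floats(0.0, 0.49),
           rho=st.floats(500.0, 2000.0))
    def test_definition_identity(self, a0, h, E, sig, rho):
        c = wave_speed(a0, h, E, sig, rho)
        assert c * c * 2 * rho * a0 == pytest.approx(h * plate_modulus(E, sig),
                                                     rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(GeometryError):
            wave_speed(-1e-3, 2e-3, 1e6)
        with pytest.raises(GeometryError):
            wave_speed(1e-3, 0.0, 1e6)


class TestAdanThickness:
    def test_printed_value_at_1cm(self):
        assert adan_wall_thickness(1.0) == pytest.approx(0.1202, abs=2e-4)

    def test_vanishes_at_small_radius(self):
        assert adan_wall_thickness(1e-9) < 1e-9

    def test_increasing_on_aortic_range(self):
        a = np.linspace(0.01, 2.0, 400)
        h = adan_wall_thickness(a)
        assert np.all(np.diff(h) > 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(GeometryError):
            adan_wall_thickness(0.0)


class TestArcProfile:
    def test_boundary_and_peak(self):
        prof = arc_aneurysm_radius(A_V, 0.05, L_A, R_S)
        assert prof(0.0) == pytest.approx(A_V, rel=1e-12)
        assert prof(L_A) == pytest.approx(A_V, rel=1e-12)
        assert prof(L_A / 2) == pytest.approx(0.025, rel=1e-12)

    def test_degenerate_flat(self):
        prof = arc_aneurysm_radius(A_V, 2 * A_V, L_A, R_S)
        x = np.linspace(0, L_A, 33)
        assert np.allclose(prof(x), A_V)

    def test_bump_never_below_vessel(self):
        for D in (24e-3, 34e-3, 44e-3, 50e-3):
            x = np.linspace(0, L_A, 2001)
            assert np.all(arc_aneurysm_radius(A_V, D, L_A, R_S)(x) >= A_V - 1e-15)

    @pytest.mark.parametrize("D_mm", [24, 34, 44, 50])
    def test_tangent_continuity_at_junctions(self, D_mm):
        # C1: slopes from both sides of every circle junction agree
        prof = arc_aneurysm_radius(A_V, D_mm * 1e-3, L_A, R_S)
        d = 0.5 * D_mm * 1e-3 - A_V
        R_A = ((L_A / 2) ** 2 + d * d - 2 * d * R_S) / (2 * d)
        x_t = (L_A / 2) * R_S / (R_S + R_A)
        h = 5e-9
        for xj in (x_t, L_A - x_t):
            left = (prof(xj) - prof(xj - h)) / h
            right = (prof(xj + h) - prof(xj)) / h
            assert abs(left - right) < 1e-6

    def test_infeasible_geometry_raises(self):
        # tall narrow bump with huge conjugation radius cannot be tangent
        with pytest.raises(GeometryError):
            arc_aneurysm_radius(1e-3, 2.4e-3, 1.2e-3, 1.0)
        with pytest.raises(GeometryError):
            arc_aneurysm_radius(A_V, 0.01, L_A, R_S)  # D < vessel diameter


class TestComputeK:
    #: Table of reference compliance ratios for the laboratory arc aneurysms.
    REFERENCE = {24: 1.11, 34: 3.92, 44: 8.66, 50: 12.7}

    @pytest.mark.parametrize("D_mm", sorted(REFERENCE))
    def test_laboratory_reference_values(self, D_mm):
        prof = arc_aneurysm_radius(A_V, D_mm * 1e-3, L_A, R_S)
        K = compute_K(prof, A_V, L_A)
        assert K == pytest.approx(self.REFERENCE[D_mm], rel=0.02)

    def test_monotone_in_peak_diameter(self):
        Ks = [compute_K(arc_aneurysm_radius(A_V, D * 1e-3, L_A, R_S), A_V, L_A)
              for D in sorted(self.REFERENCE)]
        assert all(a < b for a, b in zip(Ks, Ks[1:]))

    @given(k=st.floats(0.0, 3.0))
    def test_cosine_closed_form(self, k):
        # mean over the bump of (1 + k s)^3 - 1, s = (1-cos)/2:
        # (3/2) k + (9/8) k^2 + (5/16) k^3
        a0 = lambda x: np.full_like(np.asarray(x, float), 6.775e-3)
        prof = cosine_aneurysm_radius(a0, k, 0.0, 0.104)
        expected = 1.5 * k + 1.125 * k**2 + 0.3125 * k**3
        assert compute_K(prof, a0, 0.104) == pytest.approx(expected, abs=1e-8)

    def test_taper_cancels_for_proportional_bump(self):
        taper = lambda x: 7.1e-3 - 0.7e-3 * x / 0.104
        prof = cosine_aneurysm_radius(taper, 1.0, 0.0, 0.104)
        K = compute_K(lambda x: prof(x), lambda x: taper(x), 0.104)
        assert K == pytest.approx(47 / 16, abs=1e-8)

    def test_zero_bump(self):
        assert compute_K(A_V, A_V, L_A) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(GeometryError):
            compute_K(A_V, 0.0, L_A)


class TestExcessCompliance:
    EP = 2.8e6 / (1 - 0.25)
    H = 2e-3

    def test_zero_for_identical_profiles(self):
        assert excess_compliance(A_V, A_V, self.EP, self.H, L_A=L_A) == \
            pytest.approx(0.0, abs=1e-18)

    def test_uniform_stiffness_identity_with_K(self):
        # integral form == (2 pi a_v^3 L_A / E' h) K for constant a_v
        prof = arc_aneurysm_radius(A_V, 0.05, L_A, R_S)
        dca = excess_compliance(prof, A_V, self.EP, self.H, L_A=L_A)
        K = compute_K(prof, A_V, L_A)
        closed = 2 * np.pi * A_V**3 * L_A * K / (self.EP * self.H)
        assert dca == pytest.approx(closed, rel=1e-6)

    def test_against_trapezoid_oracle(self):
        # independent brute-force quadrature of the D=50 experimental profile
        prof = arc_aneurysm_radius(A_V, 0.05, L_A, R_S)
        x = np.linspace(0, L_A, 200001)
        oracle = np.trapezoid(2 * np.pi * (prof(x) ** 3 - A_V**3)
                              / (self.EP * self.H), x)
        dca = excess_compliance(prof, A_V, self.EP, self.H, L_A=L_A)
        assert dca == pytest.approx(oracle, rel=1e-6)

    def test_softer_aneurysm_wall_raises_compliance(self):
        prof = arc_aneurysm_radius(A_V, 0.034, L_A, R_S)
        stiff = excess_compliance(prof, A_V, self.EP, self.H, self.EP, self.H, L_A)
        soft = excess_compliance(prof, A_V, 0.5 * self.EP, self.H,
                                 self.EP, self.H, L_A)
        assert soft > stiff


class TestTau:
    def test_aaa2_printed_value(self):
        assert tau_from_geometry(0.104, 4.36, 47 / 16) * 1e3 == \
            pytest.approx(35.0, rel=5e-3)

    def test_aaa3_printed_value(self):
        assert tau_from_geometry(0.104, 4.36, 10.0) * 1e3 == \
            pytest.approx(119.2, rel=5e-3)

    def test_zero_K(self):
        assert tau_from_geometry(0.104, 4.36, 0.0) == 0.0


class TestVesselSegment:
    def make(self, **kw):
        base = dict(name="seg", length=0.14, radius_in=A_V, radius_out=A_V,
                    wall_thickness=2e-3, youngs_modulus=2.8e6, poisson=0.5)
        base.update(kw)
        return VesselSegment(**base)

    def test_healthy_taper_linear(self):
        s = self.make(radius_in=7.1e-3, radius_out=6.45e-3)
        assert s.radius_healthy(0.07) == pytest.approx(0.5 * (7.1e-3 + 6.45e-3))

    def test_embedded_arc_summary_matches_free_standing(self):
        s = self.make(aneurysm=AneurysmProfile("arc", 0.025, L_A,
                                               peak_diameter=0.05,
                                               conjugation_radius=R_S))
        K_free = compute_K(arc_aneurysm_radius(A_V, 0.05, L_A, R_S), A_V, L_A)
        assert segment_compliance_summary(s).K == pytest.approx(K_free, rel=1e-9)

    def test_summary_consistency_tau_eq_tau0_K(self):
        s = self.make(aneurysm=AneurysmProfile("arc", 0.025, L_A,
                                               peak_diameter=0.044,
                                               conjugation_radius=R_S))
        summ = segment_compliance_summary(s)
        assert summ.tau == pytest.approx(summ.tau0 * summ.K, rel=1e-12)

    def test_adan_thickness_law_in_si(self):
        s = self.make(radius_in=0.01, radius_out=0.01, wall_thickness="adan")
        assert s.thickness(0.0) == pytest.approx(0.1202e-2, abs=2e-6)

    @pytest.mark.parametrize("bad", [
        dict(length=-1.0), dict(radius_in=0.0), dict(poisson=0.7),
        dict(youngs_modulus=0.0), dict(wall_thickness=-1e-3),
        dict(wall_thickness="mystery"),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(GeometryError):
            self.make(**bad)

    def test_aneurysm_outside_segment_rejected(self):
        with pytest.raises(GeometryError):
            self.make(aneurysm=AneurysmProfile("cosine", 0.10, 0.09, k_delta=1.0))


def test_fluid_properties_validation():
    with pytest.raises(GeometryError):
        FluidProperties(density=-1.0)
    assert FluidProperties(1000.0, 0.0).viscosity == 0.0
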