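"""Beam-model unit and property tests: eigenvalues, frequency formulas,
mode splitting and mass-sensing figures of merit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnamech.beam import (
    BEAM_RATIO_21,
    BEAM_RATIO_32,
    BundleGeometry,
    MaterialState,
    beam_frequencies,
    clamped_clamped_modal_factors,
    general_beam_frequencies,
    high_tension_limit_check,
    limit_of_detection,
    mass_of_bundle,
    sensitivity,
    sensitivity_report,
    split_frequencies,
    string_frequencies,
)

# Textbook clamped-clamped eigenvalues, used only as independent cross-checks.
LAMBDA_REF = [4.73004074, 7.85320462, 10.99560784]


class TestModalFactors:
    def test_first_three_roots_match_textbook_values(self):
        lam = clamped_clamped_modal_factors(3)
        assert lam == pytest.approx(LAMBDA_REF, rel=1e-8)

    def test_roots_satisfy_characteristic_equation(self):
        for lam in clamped_clamped_modal_factors(6):
            assert math.cos(lam) * math.cosh(lam) == pytest.approx(1.0, abs=1e-6)

    def test_roots_strictly_increasing(self):
        lam = clamped_clamped_modal_factors(10)
        assert np.all(np.diff(lam) > 0)

    def test_large_n_asymptote(self):
        # lam_n -> (n + 1/2) pi as n grows
        lam = clamped_clamped_modal_factors(6)
        for n in (5, 6):
            assert lam[n - 1] / ((n + 0.5) * math.pi) == pytest.approx(1.0, abs=1e-4)

    def test_unstressed_mode_ratios(self):
        assert round(BEAM_RATIO_21, 2) == 2.76
        assert round(BEAM_RATIO_32, 2) == 1.96

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_mode_count_rejected(self, bad):
        with pytest.raises(ValueError):
            clamped_clamped_modal_factors(bad)


class TestGeometryAndMaterial:
    def test_section_properties(self):
        g = BundleGeometry(length=10e-6, diameter=80e-9)
        r = 40e-9
        assert g.radius == r
        assert g.area == pytest.approx(math.pi * r**2, rel=1e-15)
        assert g.second_moment == pytest.approx(math.pi * r**4 / 4, rel=1e-15)

    def test_elliptical_defaults_to_circular(self):
        g = BundleGeometry(length=10e-6, diameter=80e-9)
        assert g.d_max == g.d_min == 80e-9 and g.is_circular

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length": -1e-6, "diameter": 80e-9},
            {"length": 10e-6, "diameter": 0.0},
            {"length": 10e-6, "diameter": 80e-9, "d_max": 70e-9, "d_min": 80e-9},
            {"length": float("nan"), "diameter": 80e-9},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BundleGeometry(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"young_modulus": -5e9, "density": 1700.0},
            {"young_modulus": 5e9, "density": 0.0},
            {"young_modulus": 5e9, "density": 1700.0, "axial_stress": -1.0},
            {"young_modulus": float("inf"), "density": 1700.0},
        ],
    )
    def test_invalid_material_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MaterialState(**kwargs)


valid_geometry = st.builds(
    BundleGeometry,
    length=st.floats(5e-6, 30e-6),
    diameter=st.floats(20e-9, 200e-9),
)
valid_material = st.builds(
    MaterialState,
    young_modulus=st.floats(1e9, 20e9),
    density=st.floats(1000.0, 2000.0),
    axial_stress=st.floats(0.0, 1e8),
)


class TestBeamFrequencies:
    def test_worked_example_fundamental(self):
        # E = 5.3 GPa, rho = 1700, R = 50 nm, L = 12 um, unstressed -> ~1.09 MHz
        g = BundleGeometry(length=12e-6, diameter=100e-9)
        m = MaterialState(young_modulus=5.3e9, density=1700.0)
        f1 = beam_frequencies(g, m, 1)[0].frequency
        lam1 = clamped_clamped_modal_factors(1)[0]
        oracle = lam1**2 / (4 * math.pi) * (50e-9 / 12e-6**2) * math.sqrt(5.3e9 / 1700.0)
        assert f1 == pytest.approx(oracle, rel=1e-12)
        assert f1 == pytest.approx(1.09e6, rel=0.01)

    @settings(max_examples=50, deadline=None)
    @given(geometry=valid_geometry, material=valid_material)
    def test_general_and_circular_forms_agree(self, geometry, material):
        fa = [m.frequency for m in beam_frequencies(geometry, material, 3)]
        fb = [m.frequency for m in general_beam_frequencies(geometry, material, 3)]
        np.testing.assert_allclose(fa, fb, rtol=1e-12)

    def test_tension_factor_is_one_at_zero_stress(self, geometry, pristine):
        lam = clamped_clamped_modal_factors(3)
        unstressed = [
            lam[n] ** 2 / (4 * math.pi) * (geometry.radius / geometry.length**2)
            * math.sqrt(pristine.young_modulus / pristine.density)
            for n in range(3)
        ]
        got = [m.frequency for m in beam_frequencies(geometry, pristine, 3)]
        np.testing.assert_allclose(got, unstressed, rtol=1e-14)

    def test_geometric_scaling(self, geometry, pristine):
        base = [m.frequency for m in beam_frequencies(geometry, pristine, 3)]
        doubled_r = BundleGeometry(length=geometry.length, diameter=2 * geometry.diameter)
        doubled_l = BundleGeometry(length=2 * geometry.length, diameter=geometry.diameter)
        np.testing.assert_allclose(
            [m.frequency for m in beam_frequencies(doubled_r, pristine, 3)],
            [2 * f for f in base], rtol=1e-14,
        )
        np.testing.assert_allclose(
            [m.frequency for m in beam_frequencies(doubled_l, pristine, 3)],
            [f / 4 for f in base], rtol=1e-14,
        )

    def test_elliptical_geometry_rejected(self, pristine):
        g = BundleGeometry(length=10e-6, diameter=80e-9, d_max=90e-9, d_min=80e-9)
        with pytest.raises(ValueError, match="circular"):
            beam_frequencies(g, pristine)


class TestStringLimit:
    def test_string_mode_ratios_exact(self, geometry):
        m = MaterialState(young_modulus=5.3e9, density=1700.0, axial_stress=1e7)
        f = [x.frequency for x in string_frequencies(geometry, m, 3)]
        assert f[1] / f[0] == pytest.approx(2.0, rel=1e-15)
        assert f[2] / f[1] == pytest.approx(1.5, rel=1e-15)

    def test_quadrupling_stress_doubles_frequency(self, geometry):
        m1 = MaterialState(young_modulus=5.3e9, density=1700.0, axial_stress=1e7)
        m4 = MaterialState(young_modulus=5.3e9, density=1700.0, axial_stress=4e7)
        f1 = string_frequencies(geometry, m1, 1)[0].frequency
        f4 = string_frequencies(geometry, m4, 1)[0].frequency
        assert f4 == pytest.approx(2 * f1, rel=1e-14)

    def test_zero_tension_rejected(self, geometry, pristine):
        with pytest.raises(ValueError, match="tension"):
            string_frequencies(geometry, pristine)

    def test_high_tension_limit(self, geometry):
        # choose sigma so the mode-1 tension term is ~1e6
        lam1 = clamped_clamped_modal_factors(1)[0]
        E = 5.3e9
        I, A = BundleGeometry(12e-6, 100e-9).second_moment, BundleGeometry(12e-6, 100e-9).area
        sigma = 1e6 * E * I * lam1**2 / (A * geometry.length**2)
        m = MaterialState(young_modulus=E, density=1700.0, axial_stress=sigma)
        chk = high_tension_limit_check(geometry, m)
        assert chk.applicable and chk.tension_term == pytest.approx(1e6, rel=1e-6)
        for r in chk.ratios:
            assert r == pytest.approx(1.0, abs=1e-3)

    def test_zero_stress_not_applicable(self, geometry, pristine):
        assert not high_tension_limit_check(geometry, pristine).applicable


class TestSplitFrequencies:
    @settings(max_examples=50, deadline=None)
    @given(
        length=st.floats(5e-6, 30e-6),
        d_min=st.floats(20e-9, 150e-9),
        ecc=st.floats(1.0, 1.10),
    )
    def test_splitting_identity(self, length, d_min, ecc):
        g = BundleGeometry(length=length, diameter=d_min, d_max=d_min * ecc, d_min=d_min)
        m = MaterialState(young_modulus=5.3e9, density=1700.0)
        (fast, slow), = split_frequencies(g, m, 1)
        assert fast.frequency / slow.frequency == pytest.approx(ecc, rel=1e-12)
        assert fast.frequency >= slow.frequency

    def test_degenerate_ellipse_equals_circular_beam(self, geometry, pristine):
        (fast, slow), = split_frequencies(geometry, pristine, 1)
        f_circ = beam_frequencies(geometry, pristine, 1)[0].frequency
        assert fast.frequency == pytest.approx(f_circ, rel=1e-12)
        assert slow.frequency == pytest.approx(f_circ, rel=1e-12)

    def test_relative_splitting_first_order(self, pristine):
        # (f_f - f_s)/f_f = 1 - d_min/d_max ~ Omega to first order
        omega = 0.0115
        g = BundleGeometry(12e-6, 100e-9, d_max=100e-9 * (1 + omega), d_min=100e-9)
        (fast, slow), = split_frequencies(g, pristine, 1)
        rel = (fast.frequency - slow.frequency) / fast.frequency
        assert rel == pytest.approx(1 - 1 / (1 + omega), rel=1e-12)
        assert rel == pytest.approx(omega, rel=2 * omega)

    def test_stressed_ellipse_rejected(self):
        g = BundleGeometry(12e-6, 100e-9, d_max=102e-9, d_min=100e-9)
        m = MaterialState(young_modulus=5.3e9, density=1700.0, axial_stress=1e6)
        with pytest.raises(ValueError, match="unstressed"):
            split_frequencies(g, m)


class TestMassSensing:
    def test_mass_worked_example(self):
        g = BundleGeometry(length=10e-6, diameter=100e-9)
        m = MaterialState(young_modulus=5.3e9, density=1700.0)
        mass_ag = mass_of_bundle(g, m) * 1e21
        assert mass_ag == pytest.approx(1.335e5, rel=5e-3)

    def test_mass_linear_in_density(self, geometry):
        m17 = MaterialState(young_modulus=5.3e9, density=1700.0)
        m15 = MaterialState(young_modulus=5.3e9, density=1500.0)
        assert mass_of_bundle(geometry, m15) == pytest.approx(
            mass_of_bundle(geometry, m17) * 1500 / 1700, rel=1e-14
        )

    def test_sensitivity_sign_and_worked_example(self):
        # f = 1.57 MHz on the 1.335e5 ag bundle -> |S| ~ 5.9 Hz/ag
        s = sensitivity(1.57e6, 1.335e-16)
        assert s < 0
        assert abs(s) * 1e-21 == pytest.approx(5.9, rel=0.01)

    def test_sensitivity_scaling(self):
        assert sensitivity(1e6, 2e-16) == pytest.approx(sensitivity(1e6, 1e-16) / 2)
        assert sensitivity(0.0, 1e-16) == 0.0

    def test_limit_of_detection(self):
        # m = 1.335e5 ag, df/f = 1e-4 -> ~26.7 ag
        lod_ag = limit_of_detection(1.335e-16, 1e-4) * 1e21
        assert lod_ag == pytest.approx(26.7, rel=0.01)

    def test_lod_sensitivity_roundtrip(self):
        # dm_min = df/|S| with df = f*(df/f)
        f, m, stab = 1.2e6, 2e-16, 3e-4
        dm = limit_of_detection(m, stab)
        assert dm == pytest.approx(f * stab / abs(sensitivity(f, m)), rel=1e-12)

    def test_report_in_presentation_units(self):
        g = BundleGeometry(length=10e-6, diameter=100e-9)
        m = MaterialState(young_modulus=5.3e9, density=1700.0)
        rep = sensitivity_report(g, m, relative_frequency_stability=1e-4)
        assert rep.sensitivity_hz_per_ag == pytest.approx(
            abs(rep.sensitivity) * 1e-21, rel=1e-14
        )
        assert rep.limit_of_detection_ag == pytest.approx(2 * rep.mass_ag * 1e-4, rel=1e-12)
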