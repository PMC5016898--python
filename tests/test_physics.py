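import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import odepsim as o
from odepsim.errors import ValidationError
from odepsim.physics import EPS0, grad_E2_map


class TestComplexPermittivity:
    def test_zero_conductivity_is_real(self):
        eps = o.complex_permittivity(0.0, 78.0, 1e5)
        assert eps.imag == 0.0
        assert eps.real == pytest.approx(78.0 * EPS0)

    def test_high_frequency_limit(self):
        eps = o.complex_permittivity(1.0, 78.0, 1e15)
        assert abs(eps.imag) < 1e-3 * eps.real

    def test_medium_defaults_at_100khz(self):
        eps = o.complex_permittivity(3.4e-4, 78.0, 1e5)
        assert -eps.imag == pytest.approx(3.4e-4 / (2 * np.pi * 1e5))

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValidationError):
            o.complex_permittivity(3.4e-4, 78.0, 0.0)


class TestSingleShell:
    def test_transparent_membrane_recovers_cytoplasm(self):
        cell = o.CellDielectric(radius=10.0, membrane_capacitance=1e6,
                                membrane_conductance=1e9,
                                enforce_sign_constraint=False)
        eff = o.single_shell_effective_permittivity(cell, 1e5)
        cyto = o.complex_permittivity(cell.cytoplasm_conductivity,
                                      cell.cytoplasm_rel_permittivity, 1e5)
        assert eff == pytest.approx(cyto, rel=1e-3)

    def test_dead_cell_low_frequency_conductivity_equilibrated(self):
        """Leaky membrane: the effective low-frequency conductivity of a
        dead cell approaches its (medium-equilibrated) cytoplasm value."""
        cell = o.dead_cancer_cell()
        f = 1e3
        eff = o.single_shell_effective_permittivity(cell, f)
        sigma_eff = -eff.imag * 2 * np.pi * f
        assert sigma_eff == pytest.approx(cell.cytoplasm_conductivity,
                                          rel=0.15)


class TestClausiusMossotti:
    def test_identical_permittivities_give_zero(self):
        m = o.MediumProps()
        # a membrane-free cell whose cytoplasm equals the medium
        cell = o.CellDielectric(radius=10.0, membrane_capacitance=1e6,
                                membrane_conductance=1e9,
                                cytoplasm_conductivity=m.conductivity,
                                cytoplasm_rel_permittivity=m.rel_permittivity,
                                enforce_sign_constraint=False)
        k = o.clausius_mossotti(cell, m, 1e5)
        assert abs(k) < 1e-3

    def test_live_dead_sign_structure_at_operating_point(self):
        m = o.MediumProps()
        for make in (o.live_cancer_cell, o.live_leukocyte):
            assert o.clausius_mossotti(make(), m, 1e5).real > 0
        for make in (o.dead_cancer_cell, o.dead_leukocyte):
            assert o.clausius_mossotti(make(), m, 1e5).real < 0

    def test_conducting_particle_limit(self):
        cell = o.CellDielectric(radius=10.0, membrane_capacitance=1e6,
                                membrane_conductance=1e9,
                                cytoplasm_conductivity=1e4,
                                enforce_sign_constraint=False)
        k = o.clausius_mossotti(cell, o.MediumProps(), 1e5)
        assert k.real == pytest.approx(1.0, abs=1e-3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(radius=st.floats(1.0, 30.0),
           cm=st.floats(1e-3, 5e-2),
           gm=st.floats(0.0, 1e6),
           sig_i=st.floats(1e-5, 2.0),
           eps_i=st.floats(20.0, 120.0),
           sig_m=st.floats(1e-5, 2.0),
           eps_m=st.floats(20.0, 120.0),
           log_f=st.floats(2.0, 9.0))
    def test_cm_factor_bounded(self, radius, cm, gm, sig_i, eps_i,
                               sig_m, eps_m, log_f):
        """-0.5 <= Re[K] <= 1 for every physical parameter set."""
        cell = o.CellDielectric(radius=radius, membrane_capacitance=cm,
                                membrane_conductance=gm,
                                cytoplasm_conductivity=sig_i,
                                cytoplasm_rel_permittivity=eps_i,
                                enforce_sign_constraint=False)
        medium = o.MediumProps(conductivity=sig_m, rel_permittivity=eps_m)
        k = o.clausius_mossotti(cell, medium, 10.0 ** log_f)
        assert -0.5 - 1e-9 <= k.real <= 1.0 + 1e-9

    def test_sign_constraint_enforced_at_construction(self):
        with pytest.raises(ValidationError):
            # a live cell with dead-cell dielectrics must be rejected
            o.CellDielectric(radius=10.0, viability="live",
                             membrane_conductance=1e5,
                             cytoplasm_conductivity=3.4e-4,
                             cytoplasm_rel_permittivity=50.0)


class TestForces:
    def test_dep_force_zero_without_gradient(self):
        assert o.dep_force(10.0, o.MediumProps(), 0.5, 0.0) == 0.0

    def test_dep_force_cubic_in_radius_linear_in_K(self):
        m = o.MediumProps()
        f1 = o.dep_force(5.0, m, 0.5, 1e12)
        assert o.dep_force(10.0, m, 0.5, 1e12) == pytest.approx(8 * f1)
        assert o.dep_force(5.0, m, -0.5, 1e12) == pytest.approx(-f1)

    def test_stokes_drag_printed_operating_points(self):
        # cancer cell (r = 11.5 um) at its 8-V maximum velocity
        assert o.stokes_drag(11.5, 1e-3, 290.01) \
            == pytest.approx(6.29e-11, rel=5e-3)
        # live leukocyte (r = 5 um) at its maximum velocity
        assert o.stokes_drag(5.0, 1e-3, 250.49) \
            == pytest.approx(2.36e-11, rel=5e-3)
        assert o.stokes_drag(5.0, 1e-3, 0.0) == 0.0

    def test_manipulation_force_linear_in_viscosity(self):
        cell = o.live_cancer_cell()
        f_full = o.manipulation_force_from_velocity(
            cell, o.MediumProps(), 290.01)
        f_half = o.manipulation_force_from_velocity(
            cell, o.MediumProps(viscosity=0.5e-3), 290.01)
        assert f_half == pytest.approx(0.5 * f_full)
        assert o.manipulation_force_from_velocity(
            cell, o.MediumProps(), 0.0) == 0.0


class TestForceModel:
    def test_anchors_reproduced_exactly(self, force_model):
        assert force_model.calibration_report["rel_residual"].max() < 1e-6

    def test_printed_anchor_velocities(self, force_model):
        cfg = o.ODEPConfig(voltage=8.0)
        bar = o.LightPattern(kind="bar", bandwidth=150.0)
        circ = o.LightPattern(kind="hollow_circle", bandwidth=40.0)
        cases = [(o.live_leukocyte(), bar, 250.49),
                 (o.dead_leukocyte(), bar, 115.57),
                 (o.live_cancer_cell(), circ, 290.01),
                 (o.dead_cancer_cell(), circ, 82.84)]
        for cell, pat, v in cases:
            assert o.max_manipulation_velocity(cell, pat, cfg, force_model) \
                == pytest.approx(v, rel=0.05)

    def test_exact_voltage_squared_scaling(self, force_model):
        cell = o.live_cancer_cell()
        circ = o.LightPattern(kind="hollow_circle", bandwidth=40.0)
        v8 = o.max_manipulation_velocity(cell, circ, o.ODEPConfig(voltage=8),
                                         force_model)
        v4 = o.max_manipulation_velocity(cell, circ, o.ODEPConfig(voltage=4),
                                         force_model)
        assert v4 == pytest.approx(0.25 * v8, rel=1e-12)
        # parabola through the origin over the full working range
        volts = np.arange(2.0, 10.5, 1.0)
        vs = [o.max_manipulation_velocity(cell, circ,
                                          o.ODEPConfig(voltage=v),
                                          force_model) for v in volts]
        coeffs = np.polyfit(volts ** 2, vs, 1)
        assert abs(coeffs[1]) < 1e-9 * max(vs)

    def test_bandwidth_orderings(self, force_model):
        a = force_model.amplitude
        assert a[("bar", 150.0)] > a[("bar", 200.0)] > a[("bar", 250.0)]
        assert a[("hollow_circle", 40.0)] > a[("hollow_circle", 60.0)] \
            > a[("hollow_circle", 20.0)]
        assert force_model.unstable(
            o.LightPattern(kind="hollow_circle", bandwidth=20.0))

    def test_grad_E2_voltage_and_edge_structure(self, force_model):
        pat = o.LightPattern(kind="bar", bandwidth=150.0)
        d = np.linspace(0, 300, 31)
        g8 = grad_E2_map(pat, o.ODEPConfig(voltage=8), force_model, d)
        g4 = grad_E2_map(pat, o.ODEPConfig(voltage=4), force_model, d)
        assert np.allclose(g8, 4.0 * g4, rtol=1e-12)
        assert g8[0] == g8.max()          # peaked at the edge
        assert (np.diff(g8) < 0).all()    # monotone decay away from it
        # vanishing drive: the gradient vanishes quadratically with V
        g0 = grad_E2_map(pat, o.ODEPConfig(voltage=1e-12), force_model, d)
        assert g0.max() < 1e-24 * g8.max()

    def test_round_trip_force_consistency(self, force_model):
        """Net force from v_max equals Stokes drag at v_max by
        construction; the two routes agree to 0.1%."""
        cell = o.live_leukocyte()
        bar = o.LightPattern(kind="bar", bandwidth=150.0)
        cfg = o.ODEPConfig(voltage=8.0)
        v = o.max_manipulation_velocity(cell, bar, cfg, force_model)
        f_back = o.manipulation_force_from_velocity(cell, o.MediumProps(), v)
        f_direct = o.stokes_drag(cell.radius, 1e-3, v)
        assert f_back == pytest.approx(f_direct, rel=1e-3)

    def test_uncalibrated_bandwidth_rejected_without_interpolation(
            self, force_model):
        with pytest.raises(ValidationError):
            o.max_manipulation_velocity(
                o.live_leukocyte(),
                o.LightPattern(kind="bar", bandwidth=175.0),
                o.ODEPConfig(), force_model)

    def test_aggregation_risk_flagged_above_8V(self):
        with pytest.warns(UserWarning, match="aggregation"):
            cfg = o.ODEPConfig(voltage=10.0)
        assert cfg.aggregation_risk
        assert not o.ODEPConfig(voltage=8.0).aggregation_risk
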