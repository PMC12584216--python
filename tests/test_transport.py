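"""Transport surrogate: conservation, boundedness, closure, refinement."""

import numpy as np
import pytest

from csftwin import anatomy, flow, transport
from csftwin.compliance import SolverSettings, StepSizeError
from csftwin.transport import (
    DispersionClosure,
    InjectionProtocol,
    effective_dispersion,
    injection_flow,
    simulate_transport,
    tracer_front_z,
)
from csftwin.units import ML_MIN_TO_MM3_S


def region_pid(conc, geometry, t_s):
    pid = conc.slice_pid_pct(t_s, 1.0)
    return {
        r: float(pid[geometry.region_mask(r)].sum())
        for r in ("lumbar", "thoracic", "cervical", "cranial")
    }


def _zero_field(geometry, params):
    """A compliant-mode field with no oscillation at all."""
    zero = flow.composite_station_waveform(params, 0.0)
    q = np.zeros((geometry.n_slices, len(zero.times_s)))
    return flow.SpatialFlowField(
        z_mm=geometry.z_mm,
        times_s=zero.times_s,
        q_mL_min=q,
        mode="compliant",
        period_s=zero.period_s,
        carrier_freq_hz=1.0 / params.cardiac_period_s,
    )


class TestEffectiveDispersion:
    def test_zero_velocity_gives_zero_dispersion(self, geometry, params):
        fld = _zero_field(geometry, params)
        d = effective_dispersion(fld, geometry, DispersionClosure(k_disp=3.0))
        assert np.all(d == 0.0)

    def test_linearity_in_k(self, compliant_field, geometry):
        d1 = effective_dispersion(compliant_field, geometry, DispersionClosure(k_disp=1.0))
        d2 = effective_dispersion(compliant_field, geometry, DispersionClosure(k_disp=2.0))
        assert np.allclose(d2, 2.0 * d1)

    def test_mechanical_form_value(self, compliant_field, geometry):
        cl = DispersionClosure(k_disp=1.7)
        d = effective_dispersion(compliant_field, geometry, cl)
        i, j = 100, 37
        u = abs(compliant_field.q_mL_min[i, j]) * ML_MIN_TO_MM3_S / geometry.csa_mm2[i]
        assert d[i, j] == pytest.approx(1.7 * u * geometry.hd_mm[i], rel=1e-12)

    def test_oscillatory_shear_form(self, compliant_field, geometry):
        cl = DispersionClosure(form="oscillatory-shear", k_disp=0.8)
        d = effective_dispersion(compliant_field, geometry, cl)
        omega = 2 * np.pi * compliant_field.carrier_freq_hz
        i = 120
        u_amp = compliant_field.amplitude_mL_min[i] * ML_MIN_TO_MM3_S / geometry.csa_mm2[i]
        assert d[i, 0] == pytest.approx(0.8 * u_amp**2 / omega, rel=1e-12)

    def test_floor_applies(self, geometry, params):
        fld = _zero_field(geometry, params)
        d = effective_dispersion(
            fld, geometry, DispersionClosure(k_disp=0.0, floor_mm2_s=0.3)
        )
        assert np.all(d == 0.3)


class TestInjectionFlow:
    def test_zero_outside_window(self, geometry, protocol):
        assert np.all(injection_flow(protocol, geometry, -1.0) == 0.0)
        assert np.all(injection_flow(protocol, geometry, 61.0) == 0.0)

    def test_cranial_of_site_during_window(self, geometry, protocol):
        q = injection_flow(protocol, geometry, 30.0)
        cranial = geometry.z_mm < protocol.site_z_mm
        assert np.all(q[cranial] == -1.0)
        assert np.all(q[~cranial] == 0.0)

    def test_cumulative_injected_volume(self, conc_compliant):
        j60 = int(np.argmin(np.abs(conc_compliant.times_s - 60.0)))
        assert conc_compliant.injected_mL[j60] == pytest.approx(1.0, rel=1e-9)
        assert conc_compliant.injected_mL[-1] == pytest.approx(1.0, rel=1e-9)


class TestConservationAndBounds:
    def test_mass_balance_within_tolerance(self, conc_compliant, conc_rigid):
        for conc in (conc_compliant, conc_rigid):
            assert np.max(np.abs(conc.mass_error_rel)) < 1e-3

    def test_concentration_bounded(self, conc_compliant, conc_rigid):
        for conc in (conc_compliant, conc_rigid):
            assert conc.c.min() >= -1e-12
            assert conc.c.max() <= 1.0 + 1e-12

    def test_domain_plus_efflux_accounts_for_dose(
        self, conc_compliant, geometry, t_query
    ):
        pid = region_pid(conc_compliant, geometry, t_query)
        j = int(np.argmin(np.abs(conc_compliant.times_s - t_query)))
        efflux = (
            conc_compliant.efflux_tracer_mL[j] + conc_compliant.plenum_tracer_mL[j]
        ) * 100.0
        assert sum(pid.values()) + efflux == pytest.approx(100.0, abs=0.1)

    def test_zero_flow_zero_dispersion_keeps_bolus_lumbar(
        self, geometry, params, protocol
    ):
        """Without oscillation or dispersion the bolus stays at the site."""
        fld = _zero_field(geometry, params)
        conc = simulate_transport(
            protocol,
            fld,
            geometry,
            closure=DispersionClosure(k_disp=0.0),
            settings=SolverSettings(dt_injection_s=0.01, dt_post_s=0.1),
            duration_s=300.0,
        )
        for t in (60.0, 150.0, 300.0):
            pid = region_pid(conc, geometry, t)
            assert pid["lumbar"] == pytest.approx(100.0, abs=0.1)
        # tracer occupies only slices near the injection site
        occupied = conc.z_mm[conc.at_time(300.0) > 1e-6]
        assert occupied.min() > protocol.site_z_mm - 40.0

    def test_courant_violation_refused(self, compliant_field, geometry, protocol):
        with pytest.raises(StepSizeError, match="require dt"):
            simulate_transport(
                protocol,
                compliant_field,
                geometry,
                settings=SolverSettings(
                    dt_injection_s=0.005, dt_post_s=0.05, max_courant=1e-6
                ),
                duration_s=10.0,
            )


class TestComplianceContrast:
    def test_compliant_front_stays_caudal_of_T11(
        self, conc_compliant, t_query
    ):
        front = tracer_front_z(conc_compliant, 1.0, t_query)
        assert front > 147.3  # T11 attachment

    def test_monotone_compliance_effect(
        self, conc_compliant, conc_rigid, t_query
    ):
        """The compliant 95%-mass envelope lies inside the rigid envelope."""
        from csftwin.quantify import mass_envelope

        lo_c, hi_c = mass_envelope(conc_compliant, t_query)
        lo_r, hi_r = mass_envelope(conc_rigid, t_query)
        assert lo_c >= lo_r - 1.0  # one slice of slack
        assert hi_c <= hi_r + 1.0

    def test_rigid_disperses_further_than_compliant(
        self, conc_compliant, conc_rigid, geometry, t_query
    ):
        pid_c = region_pid(conc_compliant, geometry, t_query)
        pid_r = region_pid(conc_rigid, geometry, t_query)
        assert pid_c["lumbar"] > pid_r["lumbar"]
        assert pid_c["cervical"] < pid_r["cervical"] + 1e-9


class TestRefinement:
    def test_grid_and_time_refinement_changes_regional_pid_below_2pct(
        self, params, protocol
    ):
        """Halving dz and dt moves 60-min regional %ID by < 2 points."""
        results = []
        for h, dti, dtp in ((1.0, 0.01, 0.1), (0.5, 0.005, 0.05)):
            geom, _ = anatomy.build_reference_geometry(
                anatomy.GeometryConfig(slice_height_mm=h)
            )
            stations = flow.build_flow_stations(params)
            fld = flow.interpolate_axial(stations, geom, params)
            conc = simulate_transport(
                protocol,
                fld,
                geom,
                settings=SolverSettings(dt_injection_s=dti, dt_post_s=dtp),
            )
            results.append(region_pid(conc, geom, protocol.duration_s + 3600.0))
        for region in ("lumbar", "thoracic", "cervical", "cranial"):
            assert abs(results[0][region] - results[1][region]) < 2.0


class TestCalibration:
    def test_bisection_recovers_order_unity_coefficient(
        self, geometry, rigid_flow_field, protocol
    ):
        """The front-anchor bisection lands near the shipped default."""
        k = transport.calibrate_dispersion(
            geometry,
            rigid_flow_field,
            protocol,
            settings=SolverSettings(dt_injection_s=0.01, dt_post_s=0.1),
            k_lo=1.0,
            k_hi=6.0,
            tol_mm=5.0,
            max_iter=6,
        )
        assert 2.0 <= k <= 4.5

    def test_rejects_rigid_anchor_on_compliant_field(
        self, geometry, compliant_field, protocol
    ):
        with pytest.raises(ValueError, match="rigid"):
            transport.calibrate_dispersion(geometry, compliant_field, protocol)


class TestProtocolValidation:
    def test_negative_bolus_rejected(self):
        with pytest.raises(ValueError):
            InjectionProtocol(bolus_volume_mL=-1.0)

    def test_needle_geometry_checked(self):
        with pytest.raises(ValueError):
            InjectionProtocol(needle_inner_mm=0.6, needle_outer_mm=0.5)
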