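"""Dose metrics, AUC, hydrodynamics and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from csftwin.anatomy import FluidProperties
from csftwin.flow import SpatialFlowField
from csftwin.quantify import (
    auc_profile,
    compare_maps,
    dose_metrics,
    hydrodynamic_summary,
    percent_injected_dose,
    pid_map,
    regional_dose_table,
)
from csftwin.transport import ConcentrationField


def synthetic_conc(geometry, c_fn, times=None):
    """Concentration field with prescribed c(z) profiles (constant in t)."""
    t = np.arange(0.0, 3721.0, 1.0) if times is None else times
    prof = c_fn(geometry.z_mm)
    c = np.tile(prof[:, None], (1, len(t)))
    return ConcentrationField(
        z_mm=geometry.z_mm,
        times_s=t,
        c=c,
        injected_mL=np.ones(len(t)),
        efflux_tracer_mL=np.zeros(len(t)),
        plenum_tracer_mL=np.zeros(len(t)),
        slice_volume_mL=geometry.slice_volume_mL,
        mass_error_rel=np.zeros(len(t)),
        metadata={"bolus_volume_mL": 1.0},
    )


class TestPercentInjectedDose:
    def test_uniform_concentration_recovers_formula(self, geometry):
        """c = 10% over a region -> %ID = c * V_region / bolus * 100."""
        conc = synthetic_conc(
            geometry,
            lambda z: np.where((z >= 50.7) & (z < 181.3), 0.10, 0.0),
        )
        got = percent_injected_dose(conc, geometry, "thoracic", 100.0)
        v_thor = geometry.region_volume_mL("thoracic")
        assert got == pytest.approx(0.10 * v_thor * 100.0, rel=1e-9)

    def test_whole_domain_holds_full_dose(self, geometry):
        """Uniform c = bolus/V_total gives 100% ID before any efflux."""
        v_tot = float(geometry.slice_volume_mL.sum())
        conc = synthetic_conc(geometry, lambda z: np.full(len(z), 1.0 / v_tot))
        table = regional_dose_table(conc, geometry, 0.0)
        assert sum(table.values()) == pytest.approx(100.0, rel=1e-6)

    def test_compliant_run_keeps_lumbar_dose(
        self, conc_compliant, geometry, t_query
    ):
        lumbar = percent_injected_dose(conc_compliant, geometry, "lumbar", t_query)
        assert lumbar >= 90.0

    def test_unknown_region_raises(self, conc_compliant, geometry):
        with pytest.raises(KeyError):
            percent_injected_dose(conc_compliant, geometry, "sacral", 60.0)

    def test_time_outside_window_raises(self, conc_compliant, geometry):
        with pytest.raises(ValueError):
            percent_injected_dose(conc_compliant, geometry, "lumbar", 1e9)


class TestAUC:
    def test_constant_half_dose_slice_gives_50_pct_hr(self, geometry):
        """A slice holding 50% ID for the whole hour scores 50 %.hr."""
        i = 120
        v = geometry.slice_volume_mL[i]

        def profile(z):
            out = np.zeros(len(z))
            out[i] = 0.5 / v  # 50% of a 1 mL bolus in this slice
            return out

        conc = synthetic_conc(geometry, profile)
        _, auc = auc_profile(conc, geometry)
        assert auc[i] == pytest.approx(50.0, rel=1e-3)
        assert np.all(auc[np.arange(len(auc)) != i] == 0.0)

    def test_zero_concentration_gives_zero_auc(self, geometry):
        conc = synthetic_conc(geometry, lambda z: np.zeros(len(z)))
        _, auc = auc_profile(conc, geometry)
        assert np.all(auc == 0.0)

    def test_linearity_in_concentration(self, conc_compliant, geometry):
        _, auc1 = auc_profile(conc_compliant, geometry)
        scaled = ConcentrationField(
            z_mm=conc_compliant.z_mm,
            times_s=conc_compliant.times_s,
            c=conc_compliant.c * 0.5,
            injected_mL=conc_compliant.injected_mL,
            efflux_tracer_mL=conc_compliant.efflux_tracer_mL,
            plenum_tracer_mL=conc_compliant.plenum_tracer_mL,
            slice_volume_mL=conc_compliant.slice_volume_mL,
            mass_error_rel=conc_compliant.mass_error_rel,
            metadata=conc_compliant.metadata,
        )
        _, auc2 = auc_profile(scaled, geometry)
        assert np.allclose(auc2, 0.5 * auc1)

    def test_insufficient_coverage_raises(self, geometry):
        conc = synthetic_conc(
            geometry, lambda z: np.zeros(len(z)), times=np.arange(0.0, 100.0)
        )
        with pytest.raises(ValueError, match="window"):
            auc_profile(conc, geometry)

    def test_compliant_exposure_concentrates_near_site(
        self, conc_compliant, conc_rigid, geometry, protocol
    ):
        """Compliance concentrates AUC near the injection site."""
        _, auc_c = auc_profile(conc_compliant, geometry)
        _, auc_r = auc_profile(conc_rigid, geometry)
        assert auc_c.max() > auc_r.max()
        assert abs(geometry.z_mm[np.argmax(auc_c)] - protocol.site_z_mm) < 15.0


class TestHydrodynamics:
    def test_worked_reynolds_number(self, geometry):
        """U = 34.5 mm/s, HD = 2 mm -> Re = rho U HD / mu ~ 100."""
        fluid = FluidProperties()
        re = (
            fluid.density_kg_m3 * (34.5e-3) * (2.0e-3) / (fluid.viscosity_mPa_s * 1e-3)
        )
        assert re == pytest.approx(100.06, abs=0.05)

    def test_zero_flow_gives_zero_reynolds(self, geometry, params):
        zero = SpatialFlowField(
            z_mm=geometry.z_mm,
            times_s=np.linspace(0.0, 1.0, 11),
            q_mL_min=np.zeros((geometry.n_slices, 11)),
            mode="rigid",
            period_s=1.0,
            carrier_freq_hz=1.0,
        )
        h = hydrodynamic_summary(zero, geometry)
        assert np.all(h.reynolds_max == 0.0)
        assert np.all(h.u_peak_mm_s == 0.0)

    def test_velocity_consistent_with_flow_and_area(
        self, compliant_field, geometry
    ):
        h = hydrodynamic_summary(compliant_field, geometry)
        i = 60
        expect = (
            np.max(np.abs(compliant_field.q_mL_min[i]))
            * 1000.0
            / 60.0
            / geometry.csa_mm2[i]
        )
        assert h.u_peak_mm_s[i] == pytest.approx(expect, rel=1e-12)

    def test_unit_system_invariance(self, compliant_field, geometry):
        """Re computed in SI equals Re from mm-mL-s quantities to 1e-9."""
        h = hydrodynamic_summary(compliant_field, geometry)
        fluid = geometry.fluid
        # independent path: nu in mm^2/s, Re = U[mm/s] HD[mm] / nu[mm^2/s]
        nu_mm2_s = fluid.viscosity_mPa_s * 1e-3 / fluid.density_kg_m3 * 1e6
        re_alt = h.u_peak_mm_s * geometry.hd_mm / nu_mm2_s
        assert np.allclose(h.reynolds_max, re_alt, rtol=1e-9)

    def test_signed_peaks_bracket_zero(self, compliant_field, geometry):
        h = hydrodynamic_summary(compliant_field, geometry)
        assert np.all(h.q_peak_systolic_mL_min >= 0.0)
        assert np.all(h.q_peak_diastolic_mL_min <= 0.0)


class TestAgreement:
    def test_identity_maps(self, conc_compliant):
        m = pid_map(conc_compliant)
        s = compare_maps(m, m)
        assert s.r2 == pytest.approx(1.0, abs=1e-12)
        assert s.slope == pytest.approx(1.0, abs=1e-12)
        assert s.intercept == pytest.approx(0.0, abs=1e-12)
        assert s.bias == pytest.approx(0.0, abs=1e-12)
        assert s.loa_lower == pytest.approx(-s.loa_upper, abs=1e-12)

    def test_exact_affine_relation(self, rng):
        a = rng.random((40, 50))
        b = 1.07 * a
        s = compare_maps(a, b)
        assert s.slope == pytest.approx(1.07, rel=1e-12)
        assert s.r2 == pytest.approx(1.0, abs=1e-12)

    @given(
        slope=st.floats(0.2, 5.0),
        intercept=st.floats(-3.0, 3.0),
    )
    @hsettings(max_examples=25, deadline=None)
    def test_recovers_arbitrary_affine_maps(self, slope, intercept):
        x = np.linspace(0.0, 10.0, 200)
        s = compare_maps(x, slope * x + intercept)
        assert s.slope == pytest.approx(slope, rel=1e-9)
        assert s.intercept == pytest.approx(intercept, abs=1e-7)
        assert s.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_map_raises(self):
        with pytest.raises(ValueError, match="singular"):
            compare_maps(np.ones((5, 5)), np.random.default_rng(0).random((5, 5)))

    def test_limits_symmetric_about_bias(self, rng):
        a = rng.random((30, 30))
        b = a + rng.normal(0, 0.05, a.shape)
        s = compare_maps(a, b)
        assert s.loa_upper - s.bias == pytest.approx(s.bias - s.loa_lower, rel=1e-9)


class TestDoseMetricsBundle:
    def test_bundle_consistency(self, conc_compliant, geometry, t_query):
        m = dose_metrics(conc_compliant, geometry, t_s=t_query)
        assert set(m.regional_pid) == {"lumbar", "thoracic", "cervical", "cranial"}
        assert sum(m.regional_pid.values()) + m.efflux_pid == pytest.approx(
            100.0, abs=0.1
        )
        assert m.peak_auc_pct_hr == pytest.approx(np.max(m.auc_pct_hr))
        table = m.rounded_table()
        assert all(round(v, 1) == v for v in table.values())
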