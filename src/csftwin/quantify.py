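"""Pharmacokinetic and hydrodynamic summary metrics.

Percent of injected dose (%ID) for a region is the tracer volume held by the
region's slices as a percentage of the bolus, i.e. the slice-wise form of
concentration x region volume / bolus volume. AUC(z) integrates each slice's
%ID over the post-injection hour at 1 s cadence, in units of %.hr, a local
exposure measure. Hydrodynamic summaries report per-slice peak systolic /
diastolic flowrate, section-mean peak velocity U = Q/CSA, and the Reynolds
number Re = rho U HD / mu (evaluated in SI units).

Agreement between two spatial-temporal %ID maps is quantified the way method
comparisons are usually done: ordinary least squares of one map on the other
plus Bland-Altman bias and 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .anatomy import FluidProperties, NeuraxisGeometry
from .flow import SpatialFlowField
from .transport import ConcentrationField
from .units import ML_MIN_TO_MM3_S

__all__ = [
    "DoseMetrics",
    "HydrodynamicSummary",
    "AgreementStats",
    "percent_injected_dose",
    "regional_dose_table",
    "auc_profile",
    "pid_map",
    "hydrodynamic_summary",
    "compare_maps",
    "mass_envelope",
    "dose_metrics",
]

REGIONS = ("lumbar", "thoracic", "cervical", "cranial")


@dataclass(frozen=True)
class DoseMetrics:
    """Regional %ID at a query time plus the AUC exposure profile."""

    query_time_s: float
    regional_pid: dict[str, float]
    efflux_pid: float
    auc_z_mm: np.ndarray
    auc_pct_hr: np.ndarray

    @property
    def peak_auc_pct_hr(self) -> float:
        return float(np.max(self.auc_pct_hr))

    @property
    def peak_auc_z_mm(self) -> float:
        return float(self.auc_z_mm[int(np.argmax(self.auc_pct_hr))])

    def rounded_table(self) -> dict[str, float]:
        """Regional %ID rounded to one decimal (report convention)."""
        return {k: round(v, 1) for k, v in self.regional_pid.items()}


@dataclass(frozen=True)
class HydrodynamicSummary:
    """Per-slice peak flow, velocity and Reynolds number."""

    z_mm: np.ndarray
    q_peak_systolic_mL_min: np.ndarray
    q_peak_diastolic_mL_min: np.ndarray
    u_peak_mm_s: np.ndarray
    reynolds_max: np.ndarray

    def region_max_re(self, geometry: NeuraxisGeometry, region: str) -> float:
        return float(self.reynolds_max[geometry.region_mask(region)].max())

    def spinal_max_re(self, geometry: NeuraxisGeometry) -> float:
        m = ~geometry.region_mask("cranial")
        return float(self.reynolds_max[m].max())


@dataclass(frozen=True)
class AgreementStats:
    """OLS regression plus Bland-Altman limits for two paired maps."""

    r2: float
    slope: float
    intercept: float
    bias: float
    loa_lower: float
    loa_upper: float

    @property
    def loa_halfwidth(self) -> float:
        return 0.5 * (self.loa_upper - self.loa_lower)


def percent_injected_dose(
    conc: ConcentrationField,
    geometry: NeuraxisGeometry,
    region: str,
    t_s: float,
    bolus_mL: float | None = None,
) -> float:
    """Regional %ID at a query time (slice-wise volume-weighted sum)."""
    if region not in REGIONS:
        raise KeyError(f"unknown region: {region!r}; expected one of {REGIONS}")
    bolus = conc.metadata.get("bolus_volume_mL", 1.0) if bolus_mL is None else bolus_mL
    if not conc.times_s[0] <= t_s <= conc.times_s[-1]:
        raise ValueError(f"t = {t_s} s outside the output window")
    pid = conc.slice_pid_pct(t_s, bolus)
    return float(pid[geometry.region_mask(region)].sum())


def regional_dose_table(
    conc: ConcentrationField,
    geometry: NeuraxisGeometry,
    t_s: float,
    bolus_mL: float | None = None,
) -> dict[str, float]:
    return {
        r: percent_injected_dose(conc, geometry, r, t_s, bolus_mL)
        for r in REGIONS
    }


def pid_map(conc: ConcentrationField, bolus_mL: float | None = None) -> np.ndarray:
    """Slice-wise %ID map over all output times, shape (n_slices, n_times)."""
    bolus = conc.metadata.get("bolus_volume_mL", 1.0) if bolus_mL is None else bolus_mL
    return conc.c * conc.slice_volume_mL[:, None] / bolus * 100.0


def auc_profile(
    conc: ConcentrationField,
    geometry: NeuraxisGeometry,
    bolus_mL: float | None = None,
    window_s: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """AUC(z) in %.hr: summed slice %ID at 1 s cadence over the hour.

    The default window is the post-injection hour. Raises when the output
    cadence is coarser than 1 s or the window is not covered.
    """
    t = conc.times_s
    dt = float(t[1] - t[0])
    if dt > 1.0 + 1e-9:
        raise ValueError("AUC needs output at 1 s cadence or finer")
    t0 = 60.0 if window_s is None else window_s[0]
    t1 = (t0 + 3600.0) if window_s is None else window_s[1]
    if t[0] > t0 + 1e-9 or t[-1] < t1 - 1e-9:
        raise ValueError(
            f"output window [{t[0]}, {t[-1]}] s does not cover [{t0}, {t1}] s"
        )
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    pid = pid_map(conc, bolus_mL)[:, sel]
    auc = pid.sum(axis=1) * dt / 3600.0
    return conc.z_mm.copy(), auc


def hydrodynamic_summary(
    field: SpatialFlowField,
    geometry: NeuraxisGeometry,
    fluid: FluidProperties | None = None,
) -> HydrodynamicSummary:
    """Peak flows, velocities and Reynolds numbers per slice.

    Peak systolic flow is the signed max over the cycle (caudally-directed),
    diastolic the signed min. Re = rho U_peak HD / mu is computed in SI:
    U in m/s, HD in m, mu in Pa.s.
    """
    fluid = fluid or geometry.fluid
    q = field.q_mL_min
    q_sys = q.max(axis=1)
    q_dia = q.min(axis=1)
    u_peak = (
        np.max(np.abs(q), axis=1) * ML_MIN_TO_MM3_S / geometry.csa_mm2
    )  # mm/s
    hd = geometry.hd_mm
    re = (
        fluid.density_kg_m3
        * (u_peak * 1e-3)
        * (hd * 1e-3)
        / (fluid.viscosity_mPa_s * 1e-3)
    )
    return HydrodynamicSummary(
        z_mm=geometry.z_mm,
        q_peak_systolic_mL_min=q_sys,
        q_peak_diastolic_mL_min=q_dia,
        u_peak_mm_s=u_peak,
        reynolds_max=re,
    )


def compare_maps(map_a: np.ndarray, map_b: np.ndarray) -> AgreementStats:
    """Regression + Bland-Altman agreement of two paired (z, t) maps."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share their grid")
    if np.ptp(a) == 0.0:
        raise ValueError("reference map is constant; regression is singular")
    res = stats.linregress(a, b)
    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


def mass_envelope(
    conc: ConcentrationField,
    t_s: float,
    frac: float = 0.95,
) -> tuple[float, float]:
    """Central axial interval (z_lo, z_hi) holding ``frac`` of in-domain tracer.

    Computed from the cumulative tracer-volume distribution along z; the
    interval excludes the (1-frac)/2 mass tails on each side.
    """
    m = conc.at_time(t_s) * conc.slice_volume_mL
    total = m.sum()
    if total <= 0:
        raise ValueError("no tracer in the domain at the query time")
    cum = np.cumsum(m) / total
    tail = (1.0 - frac) / 2.0
    lo = int(np.searchsorted(cum, tail))
    hi = int(np.searchsorted(cum, 1.0 - tail))
    hi = min(hi, len(cum) - 1)
    return float(conc.z_mm[lo]), float(conc.z_mm[hi])


def dose_metrics(
    conc: ConcentrationField,
    geometry: NeuraxisGeometry,
    t_s: float = 3660.0,
    bolus_mL: float | None = None,
) -> DoseMetrics:
    """Bundle the regional %ID table, efflux remainder and AUC profile."""
    bolus = conc.metadata.get("bolus_volume_mL", 1.0) if bolus_mL is None else bolus_mL
    regional = regional_dose_table(conc, geometry, t_s, bolus)
    j = int(np.argmin(np.abs(conc.times_s - t_s)))
    efflux = float(
        (conc.efflux_tracer_mL[j] + conc.plenum_tracer_mL[j]) / bolus * 100.0
    )
    z, auc = auc_profile(conc, geometry, bolus)
    return DoseMetrics(
        query_time_s=t_s,
        regional_pid=regional,
        efflux_pid=efflux,
        auc_z_mm=z,
        auc_pct_hr=auc,
    )
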