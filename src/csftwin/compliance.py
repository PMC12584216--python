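"""Deforming-wall emulation of craniospinal compliance.

Instead of a pressure-volume law, compliance is emulated kinematically: each
1 mm section's dura radius moves so that the swept volume absorbs the net
volumetric efflux of the section demanded by the target flow field. For a
section of instantaneous radius r, height h and net efflux dQ over a step dt,

    r_new = sqrt(r^2 - dQ * dt / (pi * h)),      delta_r = r_new - r,

so positive net efflux (flow leaving the section, caudally-positive sign
convention: dQ = Q at the caudal face - Q at the cranial face) moves the wall
inward. The update is applied to the instantaneous radius each step, which
makes the per-step volume bookkeeping geometrically exact; a linearized
reference-radius variant is provided for comparison.

The inverse map (``flow_from_displacement``) reconstructs slice flowrates
from the swept volumes by cumulative summation from the closed sacral end,
and serves as the verification oracle for the forward algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import NeuraxisGeometry
from .flow import SpatialFlowField
from .units import ML_MIN_TO_MM3_S

__all__ = [
    "SolverSettings",
    "WallDisplacementField",
    "section_radius_update",
    "LumenCollapseError",
    "StepSizeError",
    "ModeError",
    "displacement_from_flow",
    "flow_from_displacement",
    "roundtrip_error",
    "reconstructed_station_peak",
]


class LumenCollapseError(ValueError):
    """The requested efflux would collapse the lumen of a section."""


class StepSizeError(ValueError):
    """The time step violates the Courant bound for the given field."""


class ModeError(ValueError):
    """Operation undefined for the flow-field mode (rigid has no wall motion)."""


@dataclass(frozen=True)
class SolverSettings:
    """Time-step and convergence controls shared by the numerical stages."""

    dt_injection_s: float = 0.001
    dt_post_s: float = 0.01
    max_courant: float = 0.5
    convergence_tol: float = 1e-7

    def __post_init__(self):
        if not 0.0 < self.dt_injection_s <= self.dt_post_s:
            raise ValueError("require 0 < dt_injection <= dt_post")
        if not 0.0 < self.max_courant < 1.0:
            raise ValueError("max_courant must lie in (0, 1)")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class WallDisplacementField:
    """Radial dura displacement delta_r(z, t) relative to reference radii."""

    z_mm: np.ndarray
    times_s: np.ndarray
    delta_r_mm: np.ndarray  # (n_slices, n_times)
    r_ref_mm: np.ndarray
    h_mm: float
    dt_s: float

    def __post_init__(self):
        if self.delta_r_mm.shape != (len(self.z_mm), len(self.times_s)):
            raise ValueError("delta_r must have shape (n_slices, n_times)")
        if np.any(self.r_ref_mm[:, None] + self.delta_r_mm <= 0):
            raise LumenCollapseError("lumen radius must stay positive")
        if np.max(np.abs(self.delta_r_mm[:, 0])) > 1e-12:
            raise ValueError("displacement must start from zero")

    @property
    def radius_mm(self) -> np.ndarray:
        return self.r_ref_mm[:, None] + self.delta_r_mm

    def max_abs_by_slice(self) -> np.ndarray:
        return np.max(np.abs(self.delta_r_mm), axis=1)

    def region_summary(self, geometry: NeuraxisGeometry) -> dict:
        per_slice = self.max_abs_by_slice()
        out = {}
        for region in ("cranial", "cervical", "thoracic", "lumbar"):
            m = geometry.region_mask(region)
            out[region] = {
                "max_abs_um": float(per_slice[m].max() * 1000.0),
                "min_signed_um": float(self.delta_r_mm[m].min() * 1000.0),
                "max_signed_um": float(self.delta_r_mm[m].max() * 1000.0),
            }
        return out


def section_radius_update(r_mm, efflux_volume_mm3, h_mm):
    """One application of the radial volume-balance update.

    For a cylindrical section of radius r and height h losing a net fluid
    volume ``efflux_volume_mm3`` (= dQ * dt), the new radius is
    sqrt(r^2 - efflux_volume / (pi h)); positive efflux moves the wall
    inward. Raises :class:`LumenCollapseError` when the efflux exceeds the
    section volume.
    """
    r = np.asarray(r_mm, dtype=float)
    arg = r * r - np.asarray(efflux_volume_mm3, dtype=float) / (np.pi * h_mm)
    if np.any(arg <= 0):
        raise LumenCollapseError("requested efflux exceeds the section volume")
    out = np.sqrt(arg)
    return float(out) if out.ndim == 0 else out


def _face_flows_mm3_s(field: SpatialFlowField, geometry: NeuraxisGeometry,
                      t_s: np.ndarray) -> np.ndarray:
    """Face flowrates (n_faces, n_times), closed at both model ends.

    Interior faces linearly interpolate the slice-centered field; the cranial
    vertex and sacral termination faces are closed (Q = 0), which is the
    boundary condition the compliant field is built to satisfy.
    """
    z = geometry.z_mm
    h = geometry.height_mm
    faces = np.concatenate(([z[0] - h[0] / 2.0], z + h / 2.0))
    q = np.empty((len(faces), len(t_s)))
    for k, t in enumerate(t_s):
        qc = field.at_time(t) * ML_MIN_TO_MM3_S
        q[:, k] = np.interp(faces, z, qc)
    q[0, :] = 0.0
    q[-1, :] = 0.0
    return q


def displacement_from_flow(
    field: SpatialFlowField,
    geometry: NeuraxisGeometry,
    settings: SolverSettings | None = None,
    dt_s: float | None = None,
    n_cycles: int = 1,
    linearized: bool = False,
) -> WallDisplacementField:
    """Radial wall displacements that reproduce a target flow field.

    Per step the net efflux of each section (trapezoidal average of the face
    flow difference over the step) is absorbed by the wall; the radius update
    is the square-root volume balance above, applied to the instantaneous
    radius (or, with ``linearized=True``, the small-displacement form
    delta_r_step = -dV / (2 pi r_ref h) for comparison).
    """
    if field.mode != "compliant":
        raise ModeError("wall motion is only defined for the compliant field")
    settings = settings or SolverSettings()
    dt = settings.dt_post_s if dt_s is None else dt_s
    if dt <= 0:
        raise StepSizeError("dt must be positive")

    n_steps = int(round(n_cycles * field.period_s / dt))
    t = np.arange(n_steps + 1) * dt
    h = float(geometry.height_mm[0])
    qf = _face_flows_mm3_s(field, geometry, t)

    # Courant-style bound on the advective speed implied by the field
    u_max = float(np.max(np.abs(qf)) / np.min(geometry.csa_mm2))
    if u_max * dt / h > settings.max_courant:
        raise StepSizeError(
            f"dt = {dt} s violates the Courant bound; require dt <= "
            f"{settings.max_courant * h / u_max:.3g} s"
        )

    dq = qf[1:, :] - qf[:-1, :]  # caudal minus cranial face, per slice
    r_ref = geometry.dura_radius_mm.astype(float)
    r = r_ref.copy()
    delta = np.zeros((len(r_ref), n_steps + 1))
    for k in range(n_steps):
        dv = -0.5 * (dq[:, k] + dq[:, k + 1]) * dt  # swept volume, mm^3
        if linearized:
            r = r + dv / (2.0 * np.pi * r_ref * h)
        else:
            try:
                r = section_radius_update(r, -dv, h)
            except LumenCollapseError:
                arg = r * r + dv / (np.pi * h)
                i = int(np.argmax(arg <= 0))
                raise LumenCollapseError(
                    f"lumen collapse at z = {geometry.z_mm[i]:.1f} mm, "
                    f"t = {t[k]:.4f} s"
                ) from None
        delta[:, k + 1] = r - r_ref
    return WallDisplacementField(
        z_mm=geometry.z_mm,
        times_s=t,
        delta_r_mm=delta,
        r_ref_mm=r_ref,
        h_mm=h,
        dt_s=dt,
    )


def flow_from_displacement(
    disp: WallDisplacementField,
    geometry: NeuraxisGeometry | None = None,
) -> SpatialFlowField:
    """Reconstruct slice flowrates from wall motion (the inverse bookkeeping).

    Per step, each section's swept volume pi (r_new^2 - r_old^2) h equals
    -dQ dt; cumulative summation from the closed sacral end recovers the face
    flowrates, which are averaged to slice centers. Reconstructed flows are
    step averages assigned to the left endpoint of each step.
    """
    if geometry is not None and not np.array_equal(disp.z_mm, geometry.z_mm):
        raise ValueError("displacement and geometry grids do not match")
    r = disp.radius_mm
    h = disp.h_mm
    dv = np.pi * (r[:, 1:] ** 2 - r[:, :-1] ** 2) * h  # (n_slices, n_steps)
    dq = -dv / disp.dt_s  # net efflux per slice, mm^3/s
    # face flows: Q_face[j] = Q_face[j+1] - dq[j], with the termination closed
    n_sl, n_st = dq.shape
    qf = np.zeros((n_sl + 1, n_st))
    qf[:-1, :] = -np.cumsum(dq[::-1, :], axis=0)[::-1, :]
    q_center = 0.5 * (qf[:-1, :] + qf[1:, :]) / ML_MIN_TO_MM3_S
    return SpatialFlowField(
        z_mm=disp.z_mm,
        times_s=disp.times_s[:-1],
        q_mL_min=q_center,
        mode="compliant",
        period_s=disp.times_s[-1] - disp.times_s[0],
        carrier_freq_hz=0.0,
    )


def _station_items(geometry: NeuraxisGeometry):
    return list(geometry.station_positions_mm.items())


def roundtrip_error(
    field: SpatialFlowField,
    geometry: NeuraxisGeometry,
    settings: SolverSettings | None = None,
    dt_s: float | None = None,
) -> float:
    """Max relative error (%) at peak systole over the six stations.

    Runs the forward wall-motion algorithm, reconstructs the flow from the
    displacements and, at each station, compares the reconstruction with the
    target at the target's peak-systolic sample, normalized by the station's
    peak flow. Raises :class:`ModeError` for a rigid field, which has no wall
    motion.
    """
    if field.mode != "compliant":
        raise ModeError("round-trip error is undefined for the rigid model")
    settings = settings or SolverSettings()
    disp = displacement_from_flow(field, geometry, settings, dt_s=dt_s)
    rec = flow_from_displacement(disp, geometry)
    worst = 0.0
    for _, z_st in _station_items(geometry):
        tgt = np.array(
            [np.interp(z_st, field.z_mm, field.at_time(t)) for t in rec.times_s]
        )
        got = rec.station_series(z_st)
        peak = float(np.max(np.abs(tgt)))
        if peak == 0.0:
            continue
        k = int(np.argmax(tgt))  # peak systole: max caudally-directed flow
        worst = max(worst, abs(got[k] - tgt[k]) / peak * 100.0)
    return worst


def reconstructed_station_peak(
    field: SpatialFlowField,
    geometry: NeuraxisGeometry,
    station: str = "L3/4",
    settings: SolverSettings | None = None,
    dt_s: float | None = None,
) -> float:
    """Peak |Q| (mL/min) at a station after the displacement round trip."""
    if field.mode != "compliant":
        raise ModeError("round trip is undefined for the rigid model")
    settings = settings or SolverSettings()
    disp = displacement_from_flow(field, geometry, settings, dt_s=dt_s)
    rec = flow_from_displacement(disp, geometry)
    z_st = geometry.station_positions_mm[station]
    return float(np.max(np.abs(rec.station_series(z_st))))
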