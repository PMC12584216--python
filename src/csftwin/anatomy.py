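"""Slice-wise geometry of the non-human-primate CSF system.

The spatial backbone of the model is a stack of 1 mm axial slices running from
the cranial vertex (negative z, near the superior sagittal sinus) through the
foramen magnum (z = 0) to the sacral termination of the spinal canal
(z ~ 231 mm). Each slice carries the CSF cross-sectional area, wetted
perimeter, dura- and CNS-contact surface areas and an effective lumen radius
(the radius of the circle whose area equals the dura-enclosed area, i.e. CSF
annulus plus enclosed CNS tissue), which is the radius the compliant-wall
algorithm acts on.

Axial profiles between the printed regional aggregates are under-determined:
smooth monotone-cubic (PCHIP) profiles are drawn through per-region anchor
values and then scaled region-by-region so that slice sums reproduce the
regional calibration targets exactly. The default targets are the measured
NHP regional CSF volumes and contact areas.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from . import units
from .units import (
    CRANIAL_VERTEX_MM,
    FORAMEN_MAGNUM_MM,
    CERVICOTHORACIC_MM,
    THORACOLUMBAR_MM,
    SPINAL_TERMINATION_MM,
    region_of,
)

__all__ = [
    "FluidProperties",
    "RootletRecord",
    "RegionRecord",
    "RegionTable",
    "NeuraxisGeometry",
    "GeometryConfig",
    "CalibrationError",
    "build_reference_geometry",
    "hydraulic_diameter",
    "scale_rootlet_lattice",
    "regional_summary",
    "load_rootlet_table",
    "default_region_targets",
    "station_positions",
]


class CalibrationError(ValueError):
    """Raised when a regional target cannot be met by the slice profile."""


@dataclass(frozen=True)
class FluidProperties:
    """CSF at body temperature."""

    density_kg_m3: float = 1000.59
    viscosity_mPa_s: float = 0.69

    def __post_init__(self):
        if self.density_kg_m3 <= 0 or self.viscosity_mPa_s <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class RootletRecord:
    """One spinal-level, one side (dorsal or ventral) rootlet bundle."""

    level: str
    side: str
    z_mm: float
    descending_angle_deg: float
    radicular_line_mm: float
    diameter_mm: float
    count: int
    provenance: str = "table"

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("rootlet count must be >= 1")
        if self.diameter_mm <= 0:
            raise ValueError("rootlet diameter must be positive")
        if not 0.0 <= self.descending_angle_deg <= 90.0:
            raise ValueError("descending angle must lie in [0, 90] degrees")


@dataclass(frozen=True)
class RegionRecord:
    csf_volume_mL: float
    dura_sa_cm2: float
    cns_sa_cm2: float
    rootlet_volume_cm3: float = 0.0


@dataclass(frozen=True)
class RegionTable:
    """Regional CSF volumes and tissue-contact areas.

    Spinal rows are keyed lumbar/thoracic/cervical; cranial compartments keep
    the finer sub-division (hemispheres, cerebellum, basal cisterns,
    ventricles). All totals are computed, never stored, so they agree with
    their constituents identically.
    """

    spinal: dict[str, RegionRecord]
    cranial: dict[str, RegionRecord]
    rootlet_sa_cm2: dict[str, float] = field(default_factory=dict)

    def _sum(self, rows: Iterable[RegionRecord], attr: str) -> float:
        return float(sum(getattr(r, attr) for r in rows))

    @property
    def spinal_csf_mL(self) -> float:
        return self._sum(self.spinal.values(), "csf_volume_mL")

    @property
    def cranial_csf_mL(self) -> float:
        return self._sum(self.cranial.values(), "csf_volume_mL")

    @property
    def total_csf_mL(self) -> float:
        return self.spinal_csf_mL + self.cranial_csf_mL

    @property
    def spinal_dura_sa_cm2(self) -> float:
        return self._sum(self.spinal.values(), "dura_sa_cm2")

    @property
    def cranial_dura_sa_cm2(self) -> float:
        return self._sum(self.cranial.values(), "dura_sa_cm2")

    @property
    def total_dura_sa_cm2(self) -> float:
        return self.spinal_dura_sa_cm2 + self.cranial_dura_sa_cm2

    @property
    def spinal_cns_sa_cm2(self) -> float:
        return self._sum(self.spinal.values(), "cns_sa_cm2")

    @property
    def cranial_cns_sa_cm2(self) -> float:
        return self._sum(self.cranial.values(), "cns_sa_cm2")

    @property
    def total_cns_sa_cm2(self) -> float:
        return self.spinal_cns_sa_cm2 + self.cranial_cns_sa_cm2

    @property
    def spinal_tissue_cm3(self) -> float:
        return self._sum(self.spinal.values(), "rootlet_volume_cm3")

    def region_csf_mL(self, region: str) -> float:
        if region == "cranial":
            return self.cranial_csf_mL
        return self.spinal[region].csf_volume_mL

    def to_json_dict(self) -> dict:
        out = {
            "spinal": {k: vars(v) for k, v in self.spinal.items()},
            "cranial": {k: vars(v) for k, v in self.cranial.items()},
            "rootlet_sa_cm2": dict(self.rootlet_sa_cm2),
            "totals": {
                "spinal_csf_mL": self.spinal_csf_mL,
                "cranial_csf_mL": self.cranial_csf_mL,
                "total_csf_mL": self.total_csf_mL,
                "total_dura_sa_cm2": self.total_dura_sa_cm2,
                "total_cns_sa_cm2": self.total_cns_sa_cm2,
            },
        }
        return out


# ---------------------------------------------------------------------------
# fixture data loaders
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("csftwin.data").joinpath(name)


def load_rootlet_table(path=None) -> list[RootletRecord]:
    """Load the NHP rootlet records (already at NHP scale)."""
    if path is None:
        with resources.as_file(_data_path("table1_rootlets.csv")) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return [
        RootletRecord(
            level=r.level,
            side=r.side,
            z_mm=float(r.z_mm),
            descending_angle_deg=float(r.descending_angle_deg),
            radicular_line_mm=float(r.radicular_line_mm),
            diameter_mm=float(r.diameter_mm),
            count=int(r.count),
            provenance=str(r.provenance),
        )
        for r in df.itertuples()
    ]


def default_region_targets() -> dict:
    """Regional calibration targets (measured NHP values) as a nested dict."""
    with resources.as_file(_data_path("region_targets.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def _region_table_from_targets(targets: dict) -> RegionTable:
    spinal = {
        k: RegionRecord(**v) for k, v in targets["spinal"].items()
    }
    cranial = {
        k: RegionRecord(**v) for k, v in targets["cranial"].items()
    }
    return RegionTable(
        spinal=spinal,
        cranial=cranial,
        rootlet_sa_cm2=dict(targets.get("rootlet_sa_cm2", {})),
    )


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Fixture parameters for the slice-wise geometry.

    ``csa_anchors`` / ``cns_csa_anchors`` are (z_mm, area_mm2) control points
    of the smooth axial profiles before per-region volume calibration;
    ``hd_target_mm`` sets the wetted perimeter via P_w = 4 CSA / HD. The
    cranial CNS(brain):CSF cross-section ratio fixes the effective lumen
    radius around the brain.
    """

    slice_height_mm: float = 1.0
    z_min_mm: float = CRANIAL_VERTEX_MM
    z_max_mm: float = SPINAL_TERMINATION_MM
    region_targets: dict | None = None
    include_rootlets: bool = True
    hd_target_mm: float = 2.0
    cranial_cns_csf_ratio: float = 7.6
    csa_anchors: tuple = (
        (-28.0, 40.0),
        (-22.0, 330.0),
        (-12.0, 390.0),
        (-4.0, 300.0),
        (0.0, 85.0),
        (15.0, 34.0),
        (35.0, 27.0),
        (50.7, 24.0),
        (90.0, 20.0),
        (140.0, 20.0),
        (175.0, 25.0),
        (190.0, 55.0),
        (211.0, 85.0),
        (222.0, 88.0),
        (231.0, 35.0),
    )
    cns_csa_anchors: tuple = (
        (0.0, 55.0),
        (8.0, 38.0),
        (25.0, 32.0),
        (40.0, 24.0),
        (50.7, 20.0),
        (90.0, 14.0),
        (140.0, 13.0),
        (170.0, 16.0),
        (185.0, 24.0),
        (205.0, 28.0),
        (220.0, 18.0),
        (231.0, 5.0),
    )

    def __post_init__(self):
        if self.slice_height_mm <= 0:
            raise ValueError("slice height must be positive")
        if self.z_min_mm >= self.z_max_mm:
            raise ValueError("z_min must be below z_max")


@dataclass
class NeuraxisGeometry:
    """Ordered 1 mm axial slices plus rootlet records and fluid properties.

    ``slices`` is a DataFrame with one row per slice (cranial vertex first,
    z strictly increasing) and unit-suffixed columns: z_mm, height_mm, region,
    dura_radius_mm, csa_mm2, wetted_perimeter_mm, dura_sa_mm2, cns_sa_mm2,
    cns_csa_mm2.
    """

    slices: pd.DataFrame
    rootlets: list[RootletRecord]
    fluid: FluidProperties
    region_table: RegionTable
    station_positions_mm: dict[str, float]

    # -- convenience array views -------------------------------------------
    @property
    def z_mm(self) -> np.ndarray:
        return self.slices["z_mm"].to_numpy()

    @property
    def csa_mm2(self) -> np.ndarray:
        return self.slices["csa_mm2"].to_numpy()

    @property
    def height_mm(self) -> np.ndarray:
        return self.slices["height_mm"].to_numpy()

    @property
    def dura_radius_mm(self) -> np.ndarray:
        return self.slices["dura_radius_mm"].to_numpy()

    @property
    def hd_mm(self) -> np.ndarray:
        return hydraulic_diameter(
            self.slices["csa_mm2"].to_numpy(),
            self.slices["wetted_perimeter_mm"].to_numpy(),
        )

    @property
    def slice_volume_mL(self) -> np.ndarray:
        return self.csa_mm2 * self.height_mm / units.MM3_PER_ML

    def region_mask(self, region: str) -> np.ndarray:
        return (self.slices["region"] == region).to_numpy()

    def region_volume_mL(self, region: str) -> float:
        return float(self.slice_volume_mL[self.region_mask(region)].sum())

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def validate(self, vol_rtol: float = 5e-3) -> None:
        """Check the structural invariants of the slice table."""
        df = self.slices
        z = df["z_mm"].to_numpy()
        if not np.all(np.diff(z) > 0):
            raise ValueError("slice z positions must be strictly increasing")
        for col in ("height_mm", "csa_mm2", "wetted_perimeter_mm", "dura_radius_mm"):
            if not np.all(df[col].to_numpy() > 0):
                raise ValueError(f"{col} must be positive everywhere")
        encl = np.pi * df["dura_radius_mm"].to_numpy() ** 2
        if not np.all(encl >= df["csa_mm2"].to_numpy() - 1e-9):
            raise ValueError("lumen must enclose the CSF annulus")
        for region in ("cervical", "thoracic", "lumbar", "cranial"):
            target = self.region_table.region_csf_mL(region)
            got = self.region_volume_mL(region)
            if abs(got - target) > vol_rtol * target:
                raise CalibrationError(
                    f"slice volumes for {region} ({got:.4f} mL) miss target "
                    f"({target:.4f} mL) beyond {100 * vol_rtol:.2f}%"
                )

    def to_csv(self, path) -> None:
        self.slices.to_csv(path, index=False)


def station_positions() -> dict[str, float]:
    """Axial positions of the six flow-measurement stations (mm from FM).

    Disk-level stations sit midway between the bracketing root attachments
    from the rootlet table; the foramen magnum defines z = 0.
    """
    return {
        "FM": 0.0,
        "C2/3": (7.6 + 12.5) / 2.0,
        "C5/6": (26.0 + 31.1) / 2.0,
        "T4/5": (77.6 + 81.8) / 2.0,
        "T10/11": (130.4 + 147.3) / 2.0,
        "L3/4": (208.8 + 214.1) / 2.0,
    }


def hydraulic_diameter(csa_mm2, wetted_perimeter_mm):
    """HD = 4 CSA / P_w (mm). Accepts scalars or arrays."""
    csa = np.asarray(csa_mm2, dtype=float)
    pw = np.asarray(wetted_perimeter_mm, dtype=float)
    if np.any(csa <= 0) or np.any(pw <= 0):
        raise ValueError("CSA and wetted perimeter must be positive")
    out = 4.0 * csa / pw
    return float(out) if out.ndim == 0 else out


def scale_rootlet_lattice(
    rootlets: list[RootletRecord],
    nhp_canal_mm: float,
    human_canal_mm: float,
) -> list[RootletRecord]:
    """Linearly scale a rootlet lattice by the canal-length ratio.

    Positions, radicular lines and diameters scale by nhp/human canal length;
    counts and descending angles are preserved.
    """
    if nhp_canal_mm <= 0 or human_canal_mm <= 0:
        raise ValueError("canal lengths must be positive")
    s = nhp_canal_mm / human_canal_mm
    return [
        replace(
            r,
            z_mm=r.z_mm * s,
            radicular_line_mm=r.radicular_line_mm * s,
            diameter_mm=r.diameter_mm * s,
        )
        for r in rootlets
    ]


def _pchip_profile(anchors, z):
    za = np.array([a[0] for a in anchors], dtype=float)
    va = np.array([a[1] for a in anchors], dtype=float)
    return PchipInterpolator(za, va)(np.clip(z, za[0], za[-1]))


def build_reference_geometry(
    config: GeometryConfig | None = None,
) -> tuple[NeuraxisGeometry, RegionTable]:
    """Build the calibrated slice-wise NHP geometry fixture.

    Smooth PCHIP profiles through the configured anchors are scaled with one
    multiplicative factor per region so that slice sums reproduce the regional
    CSF volumes exactly; dura- and CNS-contact areas are distributed along
    each region proportionally to the local equivalent perimeter and scaled to
    the regional targets. Raises :class:`CalibrationError` when a target is
    infeasible (non-positive scale, or empty region).
    """
    cfg = config or GeometryConfig()
    targets = cfg.region_targets or default_region_targets()
    table = _region_table_from_targets(targets)
    if not cfg.include_rootlets:
        table = RegionTable(
            spinal={
                k: replace(v, rootlet_volume_cm3=0.0)
                for k, v in table.spinal.items()
            },
            cranial=dict(table.cranial),
            rootlet_sa_cm2={k: 0.0 for k in table.rootlet_sa_cm2},
        )

    h = cfg.slice_height_mm
    n = int(round((cfg.z_max_mm - cfg.z_min_mm) / h))
    z = cfg.z_min_mm + (np.arange(n) + 0.5) * h
    regions = np.array([region_of(zz) for zz in z])

    csa = _pchip_profile(cfg.csa_anchors, z)
    cns = np.zeros_like(csa)
    spinal_mask = z >= FORAMEN_MAGNUM_MM
    cns[spinal_mask] = _pchip_profile(cfg.cns_csa_anchors, z[spinal_mask])
    cns[~spinal_mask] = cfg.cranial_cns_csf_ratio * csa[~spinal_mask]

    # per-region scaling of the CSF profile so slice sums hit targets exactly
    for region in ("cranial", "cervical", "thoracic", "lumbar"):
        m = regions == region
        if not m.any():
            raise CalibrationError(f"region {region} has no slices")
        target_mm3 = table.region_csf_mL(region) * units.MM3_PER_ML
        raw = float((csa[m] * h).sum())
        scale = target_mm3 / raw
        if scale <= 0 or not np.isfinite(scale):
            raise CalibrationError(f"infeasible CSF volume target for {region}")
        csa[m] *= scale

    # scale spinal cord tissue cross-sections to the regional tissue volumes
    for region in ("cervical", "thoracic", "lumbar"):
        m = regions == region
        target_mm3 = table.spinal[region].rootlet_volume_cm3 * units.MM3_PER_ML
        raw = float((cns[m] * h).sum())
        if raw <= 0 and target_mm3 > 0:
            raise CalibrationError(f"infeasible CNS volume target for {region}")
        cns[m] *= 0.0 if raw <= 0 else target_mm3 / raw

    pw = 4.0 * csa / cfg.hd_target_mm
    r_lumen = np.sqrt((csa + cns) / np.pi)

    # distribute contact areas within each region ~ local perimeter, scaled to
    # the regional targets (cm^2 -> mm^2)
    dura_sa = 2.0 * np.pi * r_lumen * h
    cns_sa = 2.0 * np.pi * np.sqrt(np.maximum(cns, 1e-12) / np.pi) * h
    for region in ("cranial", "cervical", "thoracic", "lumbar"):
        m = regions == region
        if region == "cranial":
            dura_t = table.cranial_dura_sa_cm2 * 100.0
            cns_t = table.cranial_cns_sa_cm2 * 100.0
        else:
            dura_t = table.spinal[region].dura_sa_cm2 * 100.0
            cns_t = table.spinal[region].cns_sa_cm2 * 100.0
        dura_sa[m] *= dura_t / dura_sa[m].sum()
        cns_sa[m] *= cns_t / cns_sa[m].sum()

    df = pd.DataFrame(
        {
            "z_mm": z,
            "height_mm": np.full(n, h),
            "region": regions,
            "dura_radius_mm": r_lumen,
            "csa_mm2": csa,
            "wetted_perimeter_mm": pw,
            "dura_sa_mm2": dura_sa,
            "cns_sa_mm2": cns_sa,
            "cns_csa_mm2": cns,
        }
    )

    rootlets = load_rootlet_table() if cfg.include_rootlets else []
    geom = NeuraxisGeometry(
        slices=df,
        rootlets=rootlets,
        fluid=FluidProperties(),
        region_table=table,
        station_positions_mm=station_positions(),
    )
    geom.validate()
    return geom, table


def regional_summary(geometry: NeuraxisGeometry) -> dict:
    """Regional volumes/areas plus the derived occupancy fractions."""
    t = geometry.region_table
    cranial = t.cranial
    cortical = (
        cranial["left_hemisphere"].csf_volume_mL
        + cranial["right_hemisphere"].csf_volume_mL
    )
    out = {
        "region_table": t.to_json_dict(),
        "fractions": {
            "cortical_of_cranial": cortical / t.cranial_csf_mL,
            "ventricular_of_cranial": (
                cranial["ventricular"].csf_volume_mL / t.cranial_csf_mL
            ),
            "spinal_of_total": t.spinal_csf_mL / t.total_csf_mL,
            "spinal_cns_to_csf": t.spinal_tissue_cm3 / t.spinal_csf_mL,
        },
        "slice_volumes_mL": {
            region: geometry.region_volume_mL(region)
            for region in ("cranial", "cervical", "thoracic", "lumbar")
        },
        "mean_hd_mm": float(np.mean(geometry.hd_mm)),
    }
    return out
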