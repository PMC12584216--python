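"""CSF flow-waveform synthesis and axial distribution.

The oscillatory CSF flow is a superposition of a cardiac component (a short
harmonic template with a sharp systolic peak) and a slower respiratory
sinusoid whose amplitude is a fixed fraction of the cardiac amplitude. One
composite cycle spans one respiratory period and contains an integer number
of cardiac cycles (the measured cardiac:respiratory rate ratio 115/28 = 4.10
is rounded down to 4 to avoid aliasing of the composite cycle).

"Amplitude" of a waveform throughout this module means max over the cycle of
|q|; ratio checks depend on that convention.

Two spatial modes are supported. The rigid field applies one composite
waveform (calibrated at C2/3) uniformly along the spine. The compliant field
interpolates station peak amplitudes along the neuroaxis (shape-preserving
monotone interpolation, zero phase lag) and attenuates the flow to zero at the
spinal termination and at the cranial vertex, which is what craniospinal
compliance does to the pulse in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .anatomy import NeuraxisGeometry, station_positions
from .units import MIN_PER_DAY

__all__ = [
    "WaveformParams",
    "CardiacShape",
    "CyclicWaveform",
    "FlowStations",
    "SpatialFlowField",
    "synthesize_cardiac_waveform",
    "superpose_cardiac_respiratory",
    "composite_station_waveform",
    "build_flow_stations",
    "interpolate_axial",
    "rigid_field",
    "aqueduct_waveform",
    "DEFAULT_STATION_PEAKS_ML_MIN",
]


#: Default station peak amplitudes (mL/min) for the compliant model. C2/3 and
#: L3/4 are the measured values (0.65 and 0.065); the intermediate stations
#: follow a monotone caudal attenuation with mild attenuation toward the
#: foramen magnum, the axial pattern craniospinal compliance produces.
DEFAULT_STATION_PEAKS_ML_MIN = {
    "FM": 0.62,
    "C2/3": 0.65,
    "C5/6": 0.58,
    "T4/5": 0.35,
    "T10/11": 0.15,
    "L3/4": 0.065,
}


@dataclass(frozen=True)
class WaveformParams:
    """Physiological waveform parameters (measured NHP defaults)."""

    cardiac_rate_bpm: float = 115.0
    respiratory_rate_bpm: float = 28.0
    resp_to_cardiac_amp_ratio: float = 0.52
    cardiac_to_resp_rate_ratio_used: float = 4.0
    c23_peak_mL_min: float = 0.65
    aqueduct_amp_ratio: float = 1.0 / 24.0
    csf_production_mL_day: float = 25.0
    sample_dt_s: float = 0.001
    strict_aliasing: bool = True

    def __post_init__(self):
        for name in (
            "cardiac_rate_bpm",
            "respiratory_rate_bpm",
            "resp_to_cardiac_amp_ratio",
            "cardiac_to_resp_rate_ratio_used",
            "c23_peak_mL_min",
            "aqueduct_amp_ratio",
            "csf_production_mL_day",
            "sample_dt_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.cardiac_to_resp_rate_ratio_used
        if self.strict_aliasing and abs(ratio - round(ratio)) > 1e-12:
            raise ValueError(
                f"cardiac:respiratory rate ratio {ratio} is not an integer; "
                "round it (e.g. 115/28 = 4.10 -> 4.0) to avoid aliasing of "
                "the composite cycle"
            )

    @property
    def rate_ratio_exact(self) -> float:
        """The unrounded cardiac:respiratory rate ratio (115/28 = 4.107)."""
        return self.cardiac_rate_bpm / self.respiratory_rate_bpm

    @property
    def composite_period_s(self) -> float:
        """One respiratory cycle; the fundamental period of the composite."""
        return 60.0 / self.respiratory_rate_bpm

    @property
    def cardiac_period_s(self) -> float:
        """Cardiac period inside the composite cycle (period / ratio_used)."""
        return self.composite_period_s / self.cardiac_to_resp_rate_ratio_used


@dataclass(frozen=True)
class CardiacShape:
    """Harmonic template of the cardiac CSF flow waveform.

    ``harmonics`` holds (order, amplitude, phase_rad) terms of a zero-mean
    sine series; the default two-harmonic template gives the sharp systolic
    peak and shallow diastolic trough characteristic of measured CSF flow.
    ``systolic_fraction`` documents the fraction of the cycle occupied by the
    systolic (caudally-directed) lobe of the default template.
    """

    harmonics: tuple = ((1, 1.0, 0.0), (2, 0.45, 0.9))
    systolic_fraction: float = 0.42

    def evaluate(self, phase: np.ndarray) -> np.ndarray:
        """Evaluate the raw (un-normalized) template at phase in [0, 1)."""
        out = np.zeros_like(phase, dtype=float)
        for order, amp, ph in self.harmonics:
            out += amp * np.sin(2.0 * np.pi * order * phase + ph)
        return out


@dataclass
class CyclicWaveform:
    """One composite cycle of a flow waveform, uniformly sampled.

    Samples include both endpoints of the cycle (q[0] == q[-1] up to sampling
    tolerance) so trapezoidal means over the cycle are exact for harmonics.
    """

    times_s: np.ndarray
    q_mL_min: np.ndarray
    period_s: float
    cardiac_component: np.ndarray | None = None
    respiratory_component: np.ndarray | None = None

    def __post_init__(self):
        dt = np.diff(self.times_s)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("waveform sampling must be uniform")
        if abs(self.q_mL_min[0] - self.q_mL_min[-1]) > 1e-6 * max(
            1.0, float(np.max(np.abs(self.q_mL_min)))
        ):
            raise ValueError("waveform must be cyclically continuous")

    @property
    def amplitude_mL_min(self) -> float:
        """max over the cycle of |q| (the amplitude convention used here)."""
        return float(np.max(np.abs(self.q_mL_min)))

    @property
    def mean_mL_min(self) -> float:
        """Trapezoidal mean over one cycle."""
        return float(
            np.trapezoid(self.q_mL_min, self.times_s) / self.period_s
        )

    def scaled(self, factor: float) -> "CyclicWaveform":
        return CyclicWaveform(
            times_s=self.times_s,
            q_mL_min=self.q_mL_min * factor,
            period_s=self.period_s,
            cardiac_component=(
                None
                if self.cardiac_component is None
                else self.cardiac_component * factor
            ),
            respiratory_component=(
                None
                if self.respiratory_component is None
                else self.respiratory_component * factor
            ),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.times_s, "q_mL_min": self.q_mL_min}
        ).to_csv(path, index=False)


@dataclass
class FlowStations:
    """The six measurement stations, each with one composite waveform."""

    positions_mm: dict[str, float]
    waveforms: dict[str, CyclicWaveform]

    def __post_init__(self):
        periods = {round(w.period_s, 12) for w in self.waveforms.values()}
        lengths = {len(w.times_s) for w in self.waveforms.values()}
        if len(periods) > 1 or len(lengths) > 1:
            raise ValueError("stations must share period and sampling grid")

    @property
    def period_s(self) -> float:
        return next(iter(self.waveforms.values())).period_s

    @property
    def times_s(self) -> np.ndarray:
        return next(iter(self.waveforms.values())).times_s


@dataclass
class SpatialFlowField:
    """Flowrate Q(z, t) on the slice grid over one composite cycle.

    ``q_mL_min`` has shape (n_slices, n_times). The field is cyclically
    extended in time by evaluating t modulo the period. ``carrier_freq_hz``
    is the dominant (cardiac) frequency, used by the oscillatory-shear
    dispersion closure.
    """

    z_mm: np.ndarray
    times_s: np.ndarray
    q_mL_min: np.ndarray
    mode: Literal["rigid", "compliant"]
    period_s: float
    carrier_freq_hz: float
    amplitude_mL_min: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.q_mL_min.shape != (len(self.z_mm), len(self.times_s)):
            raise ValueError("q must have shape (n_slices, n_times)")
        if self.amplitude_mL_min is None:
            self.amplitude_mL_min = np.max(np.abs(self.q_mL_min), axis=1)

    def at_time(self, t_s: float) -> np.ndarray:
        """Sample the cyclically-extended field at an arbitrary time."""
        tm = np.mod(t_s, self.period_s)
        j = np.searchsorted(self.times_s, tm, side="right") - 1
        j = min(max(j, 0), len(self.times_s) - 2)
        w = (tm - self.times_s[j]) / (self.times_s[j + 1] - self.times_s[j])
        return (1.0 - w) * self.q_mL_min[:, j] + w * self.q_mL_min[:, j + 1]

    def station_series(self, z_station_mm: float) -> np.ndarray:
        """Time series at a station position (linear interpolation in z)."""
        out = np.empty(len(self.times_s))
        for j in range(len(self.times_s)):
            out[j] = np.interp(z_station_mm, self.z_mm, self.q_mL_min[:, j])
        return out

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.q_mL_min,
            index=pd.Index(self.z_mm, name="z_mm"),
            columns=[f"{t:.6f}" for t in self.times_s],
        )
        df.to_csv(path)


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _cycle_times(period_s: float, dt_s: float) -> np.ndarray:
    n = max(int(round(period_s / dt_s)), 8)
    return np.linspace(0.0, period_s, n + 1)


def synthesize_cardiac_waveform(
    params: WaveformParams,
    shape: CardiacShape | None = None,
    peak_mL_min: float | None = None,
) -> CyclicWaveform:
    """Zero-mean periodic cardiac waveform with the configured peak.

    The harmonic template is normalized to unit peak and scaled so that
    max over the cycle of |q| equals ``peak_mL_min`` (default: the C2/3
    calibration peak). A zero peak is allowed and returns the zero waveform;
    negative peaks are rejected.
    """
    shape = shape or CardiacShape()
    peak = params.c23_peak_mL_min if peak_mL_min is None else peak_mL_min
    if peak < 0:
        raise ValueError("peak amplitude must be non-negative")
    period = params.cardiac_period_s
    t = _cycle_times(period, params.sample_dt_s)
    raw = shape.evaluate(t / period)
    m = np.max(np.abs(raw))
    q = np.zeros_like(raw) if (peak == 0.0 or m == 0.0) else raw * (peak / m)
    return CyclicWaveform(times_s=t, q_mL_min=q, period_s=period)


def superpose_cardiac_respiratory(
    cardiac: CyclicWaveform,
    params: WaveformParams,
) -> CyclicWaveform:
    """Tile the cardiac cycle and add the respiratory sinusoid.

    The composite period is one respiratory cycle (= ratio_used cardiac
    cycles); the respiratory amplitude is ``resp_to_cardiac_amp_ratio`` times
    the cardiac amplitude. No rescaling is applied here, so the composite
    amplitude generally exceeds the cardiac amplitude.
    """
    ratio = params.cardiac_to_resp_rate_ratio_used
    if abs(ratio - round(ratio)) > 1e-12:
        raise ValueError("rate ratio must be an integer for aliasing-free tiling")
    ratio = int(round(ratio))
    nseg = len(cardiac.times_s) - 1
    card = np.concatenate(
        [np.tile(cardiac.q_mL_min[:-1], ratio), cardiac.q_mL_min[-1:]]
    )
    period = cardiac.period_s * ratio
    t = np.linspace(0.0, period, ratio * nseg + 1)
    resp_amp = params.resp_to_cardiac_amp_ratio * cardiac.amplitude_mL_min
    resp = resp_amp * np.sin(2.0 * np.pi * t / period)
    return CyclicWaveform(
        times_s=t,
        q_mL_min=card + resp,
        period_s=period,
        cardiac_component=card,
        respiratory_component=resp,
    )


def composite_station_waveform(
    params: WaveformParams,
    peak_mL_min: float,
    shape: CardiacShape | None = None,
) -> CyclicWaveform:
    """Composite waveform normalized so its own peak equals ``peak_mL_min``.

    Station peaks are reported on the composite (cardiac+respiratory) signal,
    so station builders rescale the composite to the target peak; the
    cardiac:respiratory component ratio is preserved by the rescale.
    """
    cardiac = synthesize_cardiac_waveform(params, shape=shape, peak_mL_min=1.0)
    comp = superpose_cardiac_respiratory(cardiac, params)
    amp = comp.amplitude_mL_min
    if amp == 0.0:
        return comp
    return comp.scaled(peak_mL_min / amp)


def build_flow_stations(
    params: WaveformParams,
    peaks_mL_min: dict[str, float] | None = None,
    shape: CardiacShape | None = None,
) -> FlowStations:
    """Station waveforms from the default (or configured) peak profile."""
    peaks = dict(DEFAULT_STATION_PEAKS_ML_MIN if peaks_mL_min is None else peaks_mL_min)
    pos = station_positions()
    unknown = set(peaks) - set(pos)
    if unknown:
        raise KeyError(f"unknown stations: {sorted(unknown)}")
    waveforms = {
        name: composite_station_waveform(params, peak, shape=shape)
        for name, peak in peaks.items()
    }
    return FlowStations(
        positions_mm={k: pos[k] for k in waveforms}, waveforms=waveforms
    )


# ---------------------------------------------------------------------------
# spatial fields
# ---------------------------------------------------------------------------

def _carrier_freq(params: WaveformParams) -> float:
    return 1.0 / params.cardiac_period_s


def interpolate_axial(
    stations: FlowStations,
    geometry: NeuraxisGeometry,
    params: WaveformParams,
    kind: Literal["pchip", "linear"] = "pchip",
) -> SpatialFlowField:
    """Compliant-mode field: axially interpolated amplitude, shared shape.

    Peak amplitudes are interpolated through the station values with zero
    anchors at the cranial vertex and spinal termination; every slice carries
    the same unit-peak composite waveform (zero phase lag between levels).
    """
    z = geometry.z_mm
    z_lo, z_hi = geometry.slices["z_mm"].iloc[0], geometry.slices["z_mm"].iloc[-1]
    h = float(geometry.height_mm[0])
    zs = np.array([stations.positions_mm[k] for k in stations.positions_mm])
    if np.any(zs < z_lo - h) or np.any(zs > z_hi + h):
        raise ValueError("station positions fall outside the geometry extent")

    names = list(stations.positions_mm)
    order = np.argsort(zs)
    knot_z = np.concatenate(([z_lo - h / 2.0], zs[order], [z_hi + h / 2.0]))
    knot_a = np.concatenate(
        (
            [0.0],
            [stations.waveforms[names[i]].amplitude_mL_min for i in order],
            [0.0],
        )
    )
    if kind == "pchip":
        amp = PchipInterpolator(knot_z, knot_a)(z)
    elif kind == "linear":
        amp = np.interp(z, knot_z, knot_a)
    else:
        raise ValueError(f"unknown interpolation kind: {kind}")

    ref = stations.waveforms[names[int(order[0])]]  # most cranial station
    unit = ref.q_mL_min / (ref.amplitude_mL_min or 1.0)
    q = np.outer(amp, unit)
    return SpatialFlowField(
        z_mm=z,
        times_s=ref.times_s,
        q_mL_min=q,
        mode="compliant",
        period_s=ref.period_s,
        carrier_freq_hz=_carrier_freq(params),
        amplitude_mL_min=amp,
    )


def rigid_field(
    c23_waveform: CyclicWaveform,
    geometry: NeuraxisGeometry,
    params: WaveformParams,
) -> SpatialFlowField:
    """Rigid-mode field: the C2/3 composite waveform at every spinal slice.

    Cranial slices carry the same waveform (the oscillation passes through to
    the superior-sagittal-sinus outlet in the rigid model), so the field is
    z-invariant over the whole domain.
    """
    z = geometry.z_mm
    q = np.tile(c23_waveform.q_mL_min, (len(z), 1))
    return SpatialFlowField(
        z_mm=z,
        times_s=c23_waveform.times_s,
        q_mL_min=q,
        mode="rigid",
        period_s=c23_waveform.period_s,
        carrier_freq_hz=_carrier_freq(params),
    )


def aqueduct_waveform(
    c23_waveform: CyclicWaveform,
    params: WaveformParams,
) -> CyclicWaveform:
    """Aqueduct-of-Sylvius waveform: scaled C2/3 oscillation plus production.

    The oscillatory part is the C2/3 waveform scaled to 1/24 of its
    amplitude; a constant offset sets the cycle mean to the net CSF
    production rate (caudally-positive sign convention: production flows out
    through the aqueduct toward the subarachnoid spaces).
    """
    osc = c23_waveform.q_mL_min * params.aqueduct_amp_ratio
    mean_osc = float(
        np.trapezoid(osc, c23_waveform.times_s) / c23_waveform.period_s
    )
    offset = params.csf_production_mL_day / MIN_PER_DAY - mean_osc
    return CyclicWaveform(
        times_s=c23_waveform.times_s,
        q_mL_min=osc + offset,
        period_s=c23_waveform.period_s,
    )
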