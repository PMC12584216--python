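"""Run configuration: YAML loading, validation and normalization.

A run is fully described by a nested mapping with blocks ``fixture``,
``waveform``, ``protocol``, ``closure``, ``solver``, ``output`` plus the
top-level ``mode`` (rigid | compliant) and ``seed``. Every numeric field is
validated against its domain type's invariants at load time; unknown keys
are rejected so typos fail loudly before a simulation starts. An empty file
yields the full default (reference-study) configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .anatomy import GeometryConfig
from .compliance import SolverSettings
from .flow import DEFAULT_STATION_PEAKS_ML_MIN, WaveformParams
from .transport import DispersionClosure, InjectionProtocol
from .units import ML_MIN_TO_MM3_S

__all__ = ["RunConfig", "OutputConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """A configuration failed validation; the message names the field."""


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "csftwin_run"
    concentration_dt_s: float = 1.0
    field_dt_s: float = 0.01
    duration_s: float | None = None  # None = injection + 1 h

    def __post_init__(self):
        if self.concentration_dt_s <= 0 or self.field_dt_s <= 0:
            raise ValueError("output cadences must be positive")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Validated, normalized run description."""

    mode: str = "compliant"
    fixture: GeometryConfig = field(default_factory=GeometryConfig)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    station_peaks_mL_min: dict = field(
        default_factory=lambda: dict(DEFAULT_STATION_PEAKS_ML_MIN)
    )
    protocol: InjectionProtocol = field(default_factory=InjectionProtocol)
    closure: DispersionClosure = field(default_factory=DispersionClosure)
    solver: SolverSettings = field(default_factory=SolverSettings)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "fixture": _asdict_shallow(self.fixture),
            "waveform": _asdict_shallow(self.waveform),
            "station_peaks_mL_min": dict(self.station_peaks_mL_min),
            "protocol": _asdict_shallow(self.protocol),
            "closure": _asdict_shallow(self.closure),
            "solver": _asdict_shallow(self.solver),
            "output": _asdict_shallow(self.output),
            "seed": self.seed,
        }
        # tuples -> lists so the YAML round-trips cleanly
        for key in ("csa_anchors", "cns_csa_anchors"):
            d["fixture"][key] = [list(a) for a in d["fixture"][key]]
        return d


def _asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def _build(cls, block: dict, name: str, **extra):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    try:
        return cls(**{**block, **extra})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}") from exc


def validate_config(raw: dict | None) -> RunConfig:
    """Normalize a parsed mapping into a :class:`RunConfig`.

    Fills defaults (the reference-study values), applies every domain type's
    invariants, and runs cross-field checks (integer rate ratio, a Courant
    feasibility estimate for the configured solver steps).
    """
    raw = dict(raw or {})
    known_top = {
        "mode",
        "fixture",
        "waveform",
        "station_peaks_mL_min",
        "protocol",
        "closure",
        "solver",
        "output",
        "seed",
    }
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    mode = raw.get("mode", "compliant")
    if mode not in ("rigid", "compliant"):
        raise ConfigError(f"mode must be 'rigid' or 'compliant', got {mode!r}")

    fixture_block = dict(raw.get("fixture", {}))
    for key in ("csa_anchors", "cns_csa_anchors"):
        if key in fixture_block:
            fixture_block[key] = tuple(tuple(a) for a in fixture_block[key])
    fixture = _build(GeometryConfig, fixture_block, "fixture")
    wave_block = dict(raw.get("waveform", {}))
    ratio = wave_block.get("cardiac_to_resp_rate_ratio_used")
    waveform = _build(WaveformParams, wave_block, "waveform")
    if waveform.strict_aliasing and ratio is not None:
        if abs(ratio - round(ratio)) > 1e-12:
            # WaveformParams already rejects this; keep a guiding message here
            raise ConfigError(
                f"rate ratio {ratio} would alias the composite cycle; use "
                f"{int(ratio)}.0 (the measured 115/28 = 4.10 is rounded to 4.0)"
            )
    peaks = dict(raw.get("station_peaks_mL_min", DEFAULT_STATION_PEAKS_ML_MIN))
    for name, v in peaks.items():
        if v < 0:
            raise ConfigError(f"station peak for {name} must be >= 0")
    protocol = _build(InjectionProtocol, dict(raw.get("protocol", {})), "protocol")
    closure = _build(DispersionClosure, dict(raw.get("closure", {})), "closure")
    solver = _build(SolverSettings, dict(raw.get("solver", {})), "solver")
    output = _build(OutputConfig, dict(raw.get("output", {})), "output")
    seed = int(raw.get("seed", 0))

    # Courant feasibility estimate: fastest plausible advective velocity
    u_est = (
        (max(peaks.values()) + protocol.rate_mL_min) * ML_MIN_TO_MM3_S / 15.0
    )  # mm/s over the narrowest plausible section (~15 mm^2)
    nu = u_est * solver.dt_post_s / fixture.slice_height_mm
    if nu > solver.max_courant:
        raise ConfigError(
            f"solver.dt_post_s = {solver.dt_post_s} s gives an estimated "
            f"Courant number {nu:.2f} > {solver.max_courant}"
        )

    return RunConfig(
        mode=mode,
        fixture=fixture,
        waveform=waveform,
        station_peaks_mL_min=peaks,
        protocol=protocol,
        closure=closure,
        solver=solver,
        output=output,
        seed=seed,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return validate_config(raw)
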