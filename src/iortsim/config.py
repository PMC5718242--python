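"""Run configuration: strict schema, TOML reading/writing, defaults.

One documented dialect (TOML); unknown keys are rejected with the offending
key path in the error message.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .geometry import DiscPose, GeometryModel
from .source import BeamSourceModel, PRESETS
from .transport import TransportSettings

__all__ = ["RunConfig", "ConfigError", "read_config", "write_config"]


class ConfigError(ValueError):
    """Schema violation with key-path context."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SourceConfig(_Strict):
    preset: Optional[str] = None
    mean_energy: Optional[float] = None  # MeV
    sigma_energy: float = 0.5  # MeV
    sigma_y: float = 1.0  # mm
    sigma_z: float = 1.0  # mm
    sigma_theta: float = 6.0  # degrees

    @model_validator(mode="after")
    def _check(self):
        if (self.preset is None) == (self.mean_energy is None):
            raise ValueError("give exactly one of source.preset / source.mean_energy")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )
        return self


class GeometryConfig(_Strict):
    ssd: float = 1000.0  # mm
    collimator_inner_diameter: float = 100.0  # mm
    collimator_outer_diameter: float = 140.0  # mm
    window_thickness: float = 0.06  # mm
    phantom_size: float = 200.0  # mm


class DiscPoseConfig(_Strict):
    depth: float  # mm, proximal face
    lateral_shift: float = 0.0  # mm along y
    tilt: float = 0.0  # degrees about the z-parallel diameter
    flipped: bool = False
    al_thickness: float = 4.0  # mm
    pb_thickness: float = 2.0  # mm
    diameter: float = 120.0  # mm

    def pose(self) -> DiscPose:
        return DiscPose(**self.model_dump())


class DiscConfig(_Strict):
    pose: Optional[DiscPoseConfig] = None
    reference: Optional[DiscPoseConfig] = None


class TransportConfig(_Strict):
    n_histories: int = 100_000
    n_batches: int = 10
    max_step: Optional[float] = None  # mm; default: half a voxel
    max_fractional_energy_loss: float = 0.05
    brems_enabled: bool = True
    straggling_enabled: bool = True
    scattering_enabled: bool = True
    local_deposit_below: float = 0.10  # MeV
    electron_cutoffs_kev: dict[str, float] = {}

    @model_validator(mode="after")
    def _check(self):
        if self.n_histories < self.n_batches:
            raise ValueError("transport.n_histories must be >= transport.n_batches")
        return self


class ScoringConfig(_Strict):
    voxel_size: float = 0.5  # mm, isotropic
    detector_depth: float = 70.0  # mm
    detector_width: float = 150.0  # mm


class AnalysisConfig(_Strict):
    aperture: float = 2.0  # mm, transverse averaging square
    prescription_gy: float = 23.0  # Gy at R100

    @model_validator(mode="after")
    def _check(self):
        if self.prescription_gy not in (23.0, 21.0):
            raise ValueError("analysis.prescription_gy must be 23 or 21")
        return self


class RunConfig(_Strict):
    source: SourceConfig = SourceConfig(preset="10MeV")
    geometry: GeometryConfig = GeometryConfig()
    disc: DiscConfig = DiscConfig()
    transport: TransportConfig = TransportConfig()
    scoring: ScoringConfig = ScoringConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = 0

    @model_validator(mode="after")
    def _check_consistency(self):
        # cross-block invariants (e.g. disc vs collimator diameter) surface
        # as schema errors at parse time, not at run time
        self.geometry_model()
        return self

    # -- adapters ----------------------------------------------------------

    def source_model(self) -> BeamSourceModel:
        if self.source.preset is not None:
            base = PRESETS[self.source.preset]
            return BeamSourceModel(
                mean_energy=base.mean_energy,
                sigma_energy=base.sigma_energy,
                sigma_y=base.sigma_y,
                sigma_z=base.sigma_z,
                sigma_theta=base.sigma_theta,
                n_histories=self.transport.n_histories,
                seed=self.seed,
            )
        return BeamSourceModel(
            mean_energy=self.source.mean_energy,
            sigma_energy=self.source.sigma_energy,
            sigma_y=self.source.sigma_y,
            sigma_z=self.source.sigma_z,
            sigma_theta=self.source.sigma_theta,
            n_histories=self.transport.n_histories,
            seed=self.seed,
        )

    def geometry_model(self) -> GeometryModel:
        return GeometryModel(
            ssd=self.geometry.ssd,
            collimator_inner_diameter=self.geometry.collimator_inner_diameter,
            collimator_outer_diameter=self.geometry.collimator_outer_diameter,
            window_thickness=self.geometry.window_thickness,
            phantom_size=self.geometry.phantom_size,
            detector_depth=self.scoring.detector_depth,
            detector_width=self.scoring.detector_width,
            disc=self.disc.pose.pose() if self.disc.pose else None,
            reference_disc=self.disc.reference.pose() if self.disc.reference else None,
        )

    def transport_settings(self) -> TransportSettings:
        max_step = self.transport.max_step
        if max_step is None:
            max_step = self.scoring.voxel_size / 2.0
        return TransportSettings(
            max_step=max_step,
            max_fractional_energy_loss=self.transport.max_fractional_energy_loss,
            brems_enabled=self.transport.brems_enabled,
            straggling_enabled=self.transport.straggling_enabled,
            scattering_enabled=self.transport.scattering_enabled,
            local_deposit_below=self.transport.local_deposit_below,
            electron_cutoff_overrides=tuple(
                sorted(self.transport.electron_cutoffs_kev.items())
            ),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    try:
        data = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: not valid TOML: {exc}") from exc
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(f"{path}: invalid config:\n  " + "\n  ".join(lines)) from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _emit_table(name: str, data: dict, out: list[str]) -> None:
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    if scalars or not tables:
        if name:
            out.append(f"[{name}]")
        for k, v in scalars.items():
            out.append(f"{k} = {_toml_value(v)}")
        out.append("")
    for k, v in tables.items():
        _emit_table(f"{name}.{k}" if name else k, v, out)


def write_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write a config back to TOML (round-trip stable)."""
    path = Path(path)
    data = cfg.model_dump(exclude_none=True)
    out: list[str] = []
    root_scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    for k, v in root_scalars.items():
        out.append(f"{k} = {_toml_value(v)}")
    if root_scalars:
        out.append("")
    for k, v in data.items():
        if isinstance(v, dict):
            _emit_table(k, v, out)
    path.write_text("\n".join(out).rstrip() + "\n")
    return path
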