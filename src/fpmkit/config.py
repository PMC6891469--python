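"""Run configuration: one validated YAML/JSON document for a whole run.

Sections mirror the package modules (optics, geometry, plan, camera,
sample, sim, recon, sa, evaluation) plus a global seed.  Unknown keys are
rejected so typos fail loudly; every section validates its module's
invariants before any computation starts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .sa import SAConfig
from .simulate import CameraModel
from .system import (
    DEFAULT_EXPOSURE_MAP,
    LEDArrayGeometry,
    OpticalSystem,
)

__all__ = ["RunConfig", "load_config", "save_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsSection(_Section):
    wavelength_um: float = 0.633
    objective_na: float = 0.1
    magnification: float = 2.0
    camera_pixel_um: float = 3.45
    bit_depth: int = 10
    dynamic_range_db: float = 50.0
    sensor_shape: tuple[int, int] = (64, 64)

    def build(self) -> OpticalSystem:
        return OpticalSystem(**self.model_dump())


class GeometrySection(_Section):
    half_extent: int = 15
    pitch_mm: float = 2.5
    standoff_mm: float = 93.0
    offset_mm: tuple[float, float] = (0.0, 0.0)
    roll_deg: float = 0.0

    @field_validator("standoff_mm", "pitch_mm")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    def build(self) -> LEDArrayGeometry:
        return LEDArrayGeometry(**self.model_dump())


class PlanSection(_Section):
    max_ring: Optional[int] = None
    exposure_map: list[tuple[int, float]] = list(DEFAULT_EXPOSURE_MAP)
    duty_cycle: Union[float, dict[int, float]] = 1.0
    order: Literal["center_out", "raster"] = "center_out"


class CameraSection(_Section):
    photon_budget: float = 500.0
    full_well_e: float = 1.0e5
    read_noise_e: float = 316.0
    bit_depth: int = 10
    shot_noise: bool = True
    quantize: bool = True

    def build(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class SampleSection(_Section):
    kind: Literal["bar_chart", "phase"] = "bar_chart"
    periods_um: list[float] = [6.6, 4.4, 2.19, 1.6]
    n_bars: int = 3
    bar_level: float = 0.0
    feature_scale_um: float = 8.0
    max_phase_rad: float = 1.5


class SimSection(_Section):
    factors_sigma: float = 0.2

    @field_validator("factors_sigma")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"factors_sigma must be >= 0, got {v}")
        return v


class ReconSection(_Section):
    upsampling_factor: Optional[int] = None
    max_sweeps: int = 10
    rel_tol: float = 1.0e-3
    update_order: Literal["center_out_spiral", "raster"] = "center_out_spiral"
    sa_enabled: bool = True


class SASection(_Section):
    t_initial: Optional[float] = None
    cooling: float = 0.9
    proposals_per_visit: int = 3
    proposal_width: float = 0.1
    t_floor: float = 1.0e-12

    def build(self, seed: int | None = None) -> SAConfig:
        return SAConfig(seed=seed, **self.model_dump())


class EvaluationSection(_Section):
    min_contrast: float = 0.2

    @field_validator("min_contrast")
    @classmethod
    def _in_unit(cls, v: float) -> float:
        if not (0 < v < 1):
            raise ValueError(f"min_contrast must be in (0, 1), got {v}")
        return v


class RunConfig(_Section):
    """The full, validated run document."""

    optics: OpticsSection = OpticsSection()
    geometry: GeometrySection = GeometrySection()
    plan: PlanSection = PlanSection()
    camera: CameraSection = CameraSection()
    sample: SampleSection = SampleSection()
    sim: SimSection = SimSection()
    recon: ReconSection = ReconSection()
    sa: SASection = SASection()
    evaluation: EvaluationSection = EvaluationSection()
    seed: int = 0
    out_dir: str = "fpm_run"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Defaults fill any missing section; schema violations raise a
    ``ValueError`` listing every offending key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ValueError(
            "invalid run configuration:\n  " + "\n  ".join(lines)
        ) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (or JSON by extension); round-trip safe."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
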