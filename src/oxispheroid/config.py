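"""Validated run configuration (YAML) for the command-line pipeline.

The schema mirrors the pipeline stages: a geometry block (single or fused
spheroid with optional Gardner noise), a grid block (spacing or cells per
radius), a physics block (diffusion–consumption parameters), and an
experiment block (sweep diameters, hypoxia thresholds, noise design, seed).
Defaults are the culture values used throughout the package: D = 2×10⁻⁹
m²/s, 140 mmHg boundary/initial pressure, OCR = 20 mmHg/s.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import (
    BlendParams,
    FusionSpec,
    GardnerNoiseParams,
    ImplicitModel,
    SpheroidSpec,
    fused_spheroids,
    noisy_spheroid,
)
from .solver import SimulationConfig

__all__ = [
    "NoiseConfig",
    "FusionConfig",
    "GeometryConfig",
    "GridConfig",
    "PhysicsConfig",
    "ExperimentConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseConfig(_Strict):
    a: float = Field(0.0, ge=0.0, description="per-factor amplitude")
    q_per_um: float = Field(0.0, ge=0.0, description="frequency, rad/μm")
    p: float = Field(0.0, description="phase (dimensionless)")

    def to_params(self) -> GardnerNoiseParams:
        return GardnerNoiseParams(a=self.a, q=self.q_per_um, p=self.p)


class FusionConfig(_Strict):
    separation_um: Optional[float] = Field(None, gt=0.0)  # default: 1.5·R
    a0_um: Optional[float] = Field(None, ge=0.0)          # default: 0.2·R
    a1_um: Optional[float] = Field(None, gt=0.0)          # default: R
    a2_um: Optional[float] = Field(None, gt=0.0)          # default: R


class GeometryConfig(_Strict):
    kind: Literal["single", "fused"] = "single"
    radius_um: float = Field(150.0, gt=0.0)
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    fusion: FusionConfig = Field(default_factory=FusionConfig)

    def build_model(self) -> ImplicitModel:
        R = self.radius_um
        if self.kind == "single":
            return noisy_spheroid(SpheroidSpec(
                center=self.center_um, radius=R, noise=self.noise.to_params()))
        fu = self.fusion
        sep = fu.separation_um if fu.separation_um is not None else 1.5 * R
        blend = BlendParams(
            a0=fu.a0_um if fu.a0_um is not None else 0.2 * R,
            a1=fu.a1_um if fu.a1_um is not None else R,
            a2=fu.a2_um if fu.a2_um is not None else R,
        )
        spec = FusionSpec.symmetric(radius=R, separation=sep,
                                    noise=self.noise.to_params(), blend=blend)
        return fused_spheroids(spec)


class GridConfig(_Strict):
    cells_per_radius: int = Field(20, ge=2)
    spacing_um: Optional[float] = Field(None, gt=0.0)  # overrides cells_per_radius
    pad_cells: int = Field(2, ge=1)

    def spacing_for(self, radius_um: float) -> float:
        return self.spacing_um if self.spacing_um is not None \
            else radius_um / self.cells_per_radius


class PhysicsConfig(_Strict):
    D_m2_s: float = Field(2e-9, gt=0.0)
    OCR_mmHg_s: float = Field(20.0, ge=0.0)
    P_boundary_mmHg: float = Field(140.0, ge=0.0, le=160.0)
    P_init_mmHg: float = Field(140.0, ge=0.0, le=160.0)
    dt_s: float = Field(0.05, gt=0.0)
    t_end_s: float = Field(30.0, gt=0.0)
    output_every_s: float = Field(0.25, gt=0.0)
    clamp_nonnegative: bool = True
    steady_tol_mmHg_s: float = Field(1e-4, gt=0.0)
    boundary_offset: Literal["interface", "half"] = "interface"

    def to_simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            D=self.D_m2_s, OCR=self.OCR_mmHg_s,
            P_boundary=self.P_boundary_mmHg, P_init=self.P_init_mmHg,
            dt=self.dt_s, t_end=self.t_end_s, output_every=self.output_every_s,
            clamp_nonnegative=self.clamp_nonnegative,
            steady_tol=self.steady_tol_mmHg_s,
            boundary_offset=self.boundary_offset,
        )


class ExperimentConfig(_Strict):
    sweep_diameters_um: list[float] = Field(
        default_factory=lambda: [float(d) for d in range(200, 401, 20)])
    thresholds_mmHg: tuple[float, float] = (50.0, 100.0)
    noise_design: Literal["factorial", "random"] = "factorial"
    noise_design_size: int = Field(27, ge=4)  # used by the random design
    noise_study_radius_um: float = Field(150.0, gt=0.0)
    noise_study_cells_per_radius: int = Field(10, ge=2)
    fit_points: int = Field(10, ge=2)
    log_transform: bool = False
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check_thresholds(self):
        low, high = self.thresholds_mmHg
        if not low < high:
            raise ValueError("thresholds_mmHg must be (low, high) with low < high")
        return self


class RunConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    physics: PhysicsConfig = Field(default_factory=PhysicsConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)
    outdir: str = "oxispheroid_out"

    def echo(self) -> dict:
        return self.model_dump(mode="json")


def load_config(path_or_none) -> RunConfig:
    """Load and validate a YAML config; with no path, return all defaults.

    Validation failures name the offending field path (pydantic), e.g.
    ``geometry.radius_um``.
    """
    if path_or_none is None:
        return RunConfig()
    with open(path_or_none) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
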