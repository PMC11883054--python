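"""Run configuration: validated, serialisable, hashable.

YAML or JSON documents with blocks ``template``, ``materials`` (per
region: ``{E1, E2, nu}``), ``solver``, ``loads`` and a ``seed``.
Unknown keys are rejected with the offending path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .fem import LoadCase, SolverOptions
from .geometry import (
    DEFAULT_MATERIALS,
    DEFAULT_SC_PRESSURE,
    StomatalTemplate,
    default_dumbbell_template,
    default_kidney_template,
)
from .io import config_digest
from .material import WallMaterial

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TemplateConfig(_Strict):
    morphology: Literal["dumbbell", "kidney"] = "dumbbell"
    rod_length: float | None = None
    rod_radius: float | None = None
    bulb_radius: float | None = None
    contact_radius: float | None = None
    sc_bulge: float | None = None
    sc_arc_frac: float | None = None
    tube_radius: float | None = None
    pore_semi_axis_a: float | None = None
    pore_semi_axis_b: float | None = None
    polar_margin: float | None = None
    wall_thickness_bulb: float | None = None
    wall_thickness_rod: float | None = None
    slit_half_width: float | None = None
    volume_asymmetry: float | None = None
    mesh_resolution: float | None = None
    jitter_amplitude: float | None = None

    def build(self, seed: int = 0) -> StomatalTemplate:
        overrides = {
            k: v for k, v in self.model_dump().items()
            if v is not None and k != "morphology"
        }
        overrides["random_seed"] = seed
        if self.morphology == "dumbbell":
            return default_dumbbell_template(**overrides)
        return default_kidney_template(**overrides)


class MaterialConfig(_Strict):
    E1: float = Field(gt=0, description="transverse Young's modulus, MPa")
    E2: float = Field(gt=0, description="fibre-direction Young's modulus, MPa")
    nu: float = Field(default=0.3, ge=0, lt=0.5)

    def build(self) -> WallMaterial:
        return WallMaterial(fibre_modulus=self.E2, transverse_modulus=self.E1, poisson=self.nu)


class SolverConfig(_Strict):
    damping: float = 0.02
    dt_scale: float = 0.9
    tol_rel: float = 1e-4
    max_iter: int = 200_000
    ramp_steps: int = 400
    kinetic_damping: bool = True

    def build(self) -> SolverOptions:
        return SolverOptions(
            damping=self.damping, dt_scale=self.dt_scale, tol_rel=self.tol_rel,
            max_iter=self.max_iter, ramp_steps=self.ramp_steps,
            kinetic_damping=self.kinetic_damping,
        )


class LoadsConfig(_Strict):
    total: float | None = None
    ratio: float | None = Field(default=None, gt=0, lt=1)
    totals: list[float] | None = None
    ratios: list[float] | None = None
    sc_pressure: float = DEFAULT_SC_PRESSURE


class RunConfig(_Strict):
    template: TemplateConfig = TemplateConfig()
    materials: dict[str, MaterialConfig] = {}
    solver: SolverConfig = SolverConfig()
    loads: LoadsConfig = LoadsConfig()
    seed: int = 0

    def build_template(self) -> StomatalTemplate:
        return self.template.build(seed=self.seed)

    def build_materials(self) -> dict[str, WallMaterial]:
        if self.materials:
            return {region: mc.build() for region, mc in self.materials.items()}
        return {
            region: WallMaterial(**params)
            for region, params in DEFAULT_MATERIALS[self.template.morphology].items()
        }

    def build_solver_options(self) -> SolverOptions:
        return self.solver.build()

    def sc_pressure(self) -> float:
        return self.loads.sc_pressure if self.template.morphology == "dumbbell" else 0.0

    def single_load_case(self) -> LoadCase:
        if self.loads.total is None or self.loads.ratio is None:
            raise ConfigError("loads.total and loads.ratio are required for a single solve")
        return LoadCase(self.loads.total, self.loads.ratio, self.sc_pressure())

    def load_grid(self) -> list[LoadCase]:
        from .sweep import DEFAULT_RATIOS, DEFAULT_TOTALS, make_load_grid

        totals = self.loads.totals or list(DEFAULT_TOTALS)
        ratios = self.loads.ratios or list(DEFAULT_RATIOS)
        return make_load_grid(totals, ratios, self.sc_pressure())

    def digest(self) -> str:
        return config_digest(self.model_dump())


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; errors name the bad field."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
        else:
            raw = yaml.safe_load(path.read_text())
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc
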