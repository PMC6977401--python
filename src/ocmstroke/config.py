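"""Validated pipeline configuration (single YAML document, per-stage blocks).

Unknown keys are rejected, band intervals must partition the quantified depth
range, and a seed is mandatory whenever a stochastic stage is enabled.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class StageToggles(BaseModel):
    model_config = {"extra": "forbid"}
    simulate: bool = True
    reconstruct: bool = True
    angio: bool = True
    project: bool = True
    quantify: bool = True
    infarct: bool = False


class SimulateConfig(BaseModel):
    model_config = {"extra": "forbid"}
    grid: tuple[int, int, int] = (64, 64, 256)  # scene (ny, nx, nz)
    pitch_um: tuple[float, float, float] = (17.2, 17.2, 2.5)
    n_spectral: int = 512
    n_repeats: int = 6
    frames: dict[str, int] = Field(
        default_factory=lambda: {"baseline": 4, "dye": 0, "occlusion": 6, "recovery": 4})
    occlusion_factor: dict[int, float] | float = 0.1
    recovery_factor: dict[int, float] | float = 1.0
    noise_std: float = 0.004
    bulk_std_rad: float = 0.5
    dispersion: list[float] = Field(default_factory=list)
    k_warp: float = 0.0
    shadow_scramble_rad: float = 0.0

    @field_validator("frames")
    @classmethod
    def _stages_known(cls, v):
        allowed = {"baseline", "dye", "occlusion", "recovery"}
        bad = set(v) - allowed
        if bad:
            raise ValueError(f"unknown stage name(s) {sorted(bad)}")
        if v.get("baseline", 0) < 1:
            raise ValueError("need at least one baseline frame")
        return v


class ReconConfig(BaseModel):
    model_config = {"extra": "forbid"}
    window: str | None = "hann"
    interpolation: str = "cubic"
    z_crop: tuple[int, int] = (4, 132)
    tilt_correct: bool = False
    dc_subtract: bool = True
    refractive_index: float = 1.35


class AngioConfig(BaseModel):
    model_config = {"extra": "forbid"}
    pairs: str = "consecutive"
    averaging: str = "complex"
    static_mask: str = "truth"  # 'truth' (scene-derived) or 'auto'

    @field_validator("pairs")
    @classmethod
    def _pairs(cls, v):
        if v not in ("consecutive", "all"):
            raise ValueError("pairs must be 'consecutive' or 'all'")
        return v


class ProjectConfig(BaseModel):
    model_config = {"extra": "forbid"}
    reduction: str = "mean"
    depth_range_um: tuple[float, float] = (0.0, 640.0)
    colormap: str = "turbo"


class QuantifyConfig(BaseModel):
    model_config = {"extra": "forbid"}
    band_edges_um: tuple[float, ...] = (0.0, 160.0, 320.0, 640.0)
    threshold_k_sigma: float = 5.0
    vessel_mask_quantile: float = 0.9
    vessel_mask_min_area_px: int = 40
    c_none: float = 0.2
    c_full: float = 0.8

    @field_validator("band_edges_um")
    @classmethod
    def _partition(cls, v):
        if len(v) < 2:
            raise ValueError("need at least one band")
        if v[0] != 0.0:
            raise ValueError("bands must start at 0 um (the brain surface)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError(
                f"band edges {v} must be strictly increasing (disjoint, contiguous)")
        return v

    @model_validator(mode="after")
    def _cuts(self):
        if not (0 < self.c_none < self.c_full):
            raise ValueError("need 0 < c_none < c_full")
        return self


class InfarctConfig(BaseModel):
    model_config = {"extra": "forbid"}
    n_sections: int = 29
    pixel_size_um: float = 20.0
    slice_thickness_um: float = 40.0
    shape: tuple[int, int] = (160, 160)
    max_shift_px: float = 8.0
    max_rot_deg: float = 5.0
    noise_std: float = 0.02
    hemisphere_mm3: float = 127.3
    threshold: str | float = "otsu"


class PipelineConfig(BaseModel):
    model_config = {"extra": "forbid"}
    seed: int | None = None
    out_dir: str = "ocmstroke_run"
    stages: StageToggles = Field(default_factory=StageToggles)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    recon: ReconConfig = Field(default_factory=ReconConfig)
    angio: AngioConfig = Field(default_factory=AngioConfig)
    project: ProjectConfig = Field(default_factory=ProjectConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)
    infarct: InfarctConfig = Field(default_factory=InfarctConfig)

    @model_validator(mode="after")
    def _seed_required(self):
        if (self.stages.simulate or self.stages.infarct) and self.seed is None:
            raise ValueError("seed is mandatory when a stochastic stage is enabled")
        return self


def validate_config(document: dict | str | Path) -> PipelineConfig:
    """Parse and validate a config document (dict, YAML text, or path)."""
    if isinstance(document, (str, Path)) and Path(str(document)).exists():
        document = yaml.safe_load(Path(str(document)).read_text())
    elif isinstance(document, str):
        document = yaml.safe_load(document)
    if document is None:
        document = {}
    if not isinstance(document, dict):
        raise ValueError("config document must be a mapping")
    return PipelineConfig.model_validate(document)
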