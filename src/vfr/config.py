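"""Validated study configuration with lossless YAML round-tripping.

All protocol constants live here as defaults — 0.60 mm voxels, five rods at
0.00-0.20 g/cm^3 with 15 mm diameter, 3 mm median smoothing, 1 mm maximum
element size, 1.9% apparent strain, 27 probes of 2 mm radius, and the
density-material power laws — so stage code never hard-codes them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .imaging import ROD_BMD_VALUES

__all__ = ["StudyConfig"]


class GeometryCfg(BaseModel):
    a: float = 20.0
    b: float = 15.0
    height: float = 30.0
    waist: float = Field(0.15, ge=0, lt=1)
    base_density: float = Field(0.15, ge=0)
    size_jitter: float = Field(0.10, ge=0, lt=0.5)


class ScannerCfg(BaseModel):
    hu_slope: float = Field(1000.0, gt=0)
    hu_intercept: float = -15.0
    noise_sd: float = Field(10.0, ge=0)
    psf_sd_mm: float = Field(0.4, ge=0)
    voxel_mm: float = Field(0.60, gt=0)
    rod_diameter: float = Field(15.0, gt=0)
    rod_bmd: tuple[float, ...] = ROD_BMD_VALUES


class OperatorCfg(BaseModel):
    offset_sd: float = Field(ge=0, default=0.0)
    jitter_amp: float = Field(ge=0, default=0.0)
    jitter_corr_mm: float = Field(gt=0, default=5.0)
    slice_amp: float = Field(ge=0, default=0.0)
    inclusion_prob: float = Field(ge=0, le=1, default=0.0)


class MaterialCfg(BaseModel):
    e_coeff: float = 4730.0
    e_exp: float = 1.56
    sy_coeff: float = 21.7
    sy_exp: float = 1.52
    post_yield_ratio: float = Field(0.05, gt=0, lt=1)
    ash_per_app: float = 0.6
    floor_app: float = Field(0.01, ge=0)
    poisson: float = Field(0.3, ge=0, lt=0.5)


class SolveCfg(BaseModel):
    elem_size: float = Field(1.0, gt=0)
    apparent_strain: float = Field(0.019, gt=0)
    n_increments: int = Field(10, ge=1)
    caudal_bc: str = "fixed"
    cranial_bc: str = "slide"
    newton_tol: float = Field(1e-6, gt=0)


class ProbeCfg(BaseModel):
    radius_mm: float = Field(2.0, gt=0)
    offset_fraction: float = Field(0.25, gt=0, lt=0.5)


class StudyConfig(BaseModel):
    n_control: int = Field(3, ge=0)
    n_lytic: int = Field(3, ge=0)
    seed: int = 0
    geometry: GeometryCfg = GeometryCfg()
    scanner: ScannerCfg = ScannerCfg()
    intra: OperatorCfg = OperatorCfg(offset_sd=0.10, jitter_amp=0.15,
                                     jitter_corr_mm=6.0, slice_amp=0.10)
    inter: OperatorCfg = OperatorCfg(offset_sd=0.25, jitter_amp=0.35,
                                     jitter_corr_mm=8.0, slice_amp=0.20,
                                     inclusion_prob=0.25)
    materials: MaterialCfg = MaterialCfg()
    solve: SolveCfg = SolveCfg()
    probes: ProbeCfg = ProbeCfg()
    smooth_kernel_mm: float = Field(3.0, ge=0)
    endplate_fraction: float = Field(0.10, ge=0, lt=0.5)
    local_metrics: bool = True

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
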