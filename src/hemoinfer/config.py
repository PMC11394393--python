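"""YAML-backed run configuration.

Every block has defaults matching the documented study conditions, so an empty
config is a valid (full-scale) run.  The population defaults are stand-ins for
an unpublished animal-derived generator and are fully overridable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .ekf import DEFAULT_P0_DIAG, EKFConfig
from .engine import SimSettings
from .errors import ConfigurationError
from .evaluation import DEFAULT_HEM_RATES, DEFAULT_NOISE_LEVELS, DEFAULT_U_FRACS
from .vpg import PopulationModel

__all__ = ["RunConfig", "load_config"]


class PopulationBlock(BaseModel):
    vb0: float = 5.0
    alpha_u: float = 0.5
    alpha_h: float = 2.0
    k: float = 0.1
    cv: float = Field(0.15, ge=0.0, description="per-parameter coefficient of variation")
    sigma0_range: tuple[float, float] = (0.35, 0.45)


class LOBlock(BaseModel):
    poles: tuple[float, float, float] = (-0.06, -0.05, -0.04)

    @field_validator("poles")
    @classmethod
    def _negative(cls, v):
        if any(p >= 0 for p in v):
            raise ValueError("observer poles must be strictly negative")
        return v


class EKFBlock(BaseModel):
    p0_diag: tuple[float, float, float, float] = DEFAULT_P0_DIAG
    q_floor: float = Field(1e-10, ge=0.0)
    qv_floor: float = Field(1e-8, gt=0.0)


class DetectionBlock(BaseModel):
    window: float = Field(10.0, gt=0.0)
    majority: float = Field(0.5, gt=0.0, lt=1.0)
    naive_drop: float = Field(0.10, gt=0.0, lt=1.0)


class GridBlock(BaseModel):
    n_vp_eval: int = Field(100, ge=1)
    n_vp_calib: int = Field(100, ge=1)
    hem_rates: tuple[float, ...] = DEFAULT_HEM_RATES
    u_fracs: tuple[float, ...] = DEFAULT_U_FRACS
    noise_levels_eval: tuple[float, ...] = (0.01,)
    noise_levels_calib: tuple[float, ...] = DEFAULT_NOISE_LEVELS
    primary_noise: float = 0.01
    chunk_size: int = Field(4096, ge=1)


class SimBlock(BaseModel):
    t_settle: float = Field(10.0, ge=0.0)
    t_max: float = Field(480.0, gt=0.0)
    dt_plant: float = Field(0.05, gt=0.0)
    dt_meas: float = Field(1.0, gt=0.0)
    n_substeps: int = Field(4, ge=1)


class RunConfig(BaseModel):
    """Top-level configuration; see the block classes for field meanings."""

    master_seed: int = 1
    population: PopulationBlock = PopulationBlock()
    lo: LOBlock = LOBlock()
    ekf: EKFBlock = EKFBlock()
    detection: DetectionBlock = DetectionBlock()
    grid: GridBlock = GridBlock()
    sim: SimBlock = SimBlock()
    output_dir: str = "results"

    def population_model(self) -> PopulationModel:
        p = self.population
        return PopulationModel.from_cv(
            vb0=p.vb0, alpha_u=p.alpha_u, alpha_h=p.alpha_h, k=p.k,
            cv=p.cv, sigma0_range=tuple(p.sigma0_range),
        )

    def ekf_config(self, pop: PopulationModel, nominal) -> EKFConfig:
        # Qv is set per run from the scenario noise level; 0 here is a placeholder
        return EKFConfig(
            params_nominal=nominal,
            q_theta=pop.q_theta,
            q_v=0.0,
            p0=np.diag(self.ekf.p0_diag),
            q_floor=self.ekf.q_floor,
            qv_floor=self.ekf.qv_floor,
        )

    def sim_settings(self) -> SimSettings:
        s = self.sim
        return SimSettings(
            t_settle=s.t_settle, t_max=s.t_max, dt_plant=s.dt_plant,
            dt_meas=s.dt_meas, n_substeps=s.n_substeps,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; a missing path or empty file yields the defaults.

    Validation errors are re-raised as :class:`ConfigurationError` naming the
    offending field paths.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration ({paths})") from exc
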