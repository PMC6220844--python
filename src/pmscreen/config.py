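"""Typed, range-checked pipeline configuration (YAML file + CLI overrides)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigurationError
from .reference import ParticleBetas
from .simulate import SimulationConfig


class SimSettings(BaseModel):
    """Overridable synthetic-experiment parameters (see SimulationConfig)."""

    model_config = ConfigDict(extra="forbid")

    cell_lines: tuple[str, ...] = ("J774", "A549")
    particles: tuple[str, ...] = ("SiO2", "EHC6802", "TiO2")
    doses_proteomic: tuple[float, ...] = (0.0, 30.0, 100.0)
    doses_cytotox: tuple[float, ...] = (0.0, 30.0, 100.0, 300.0)
    n_bio_replicates: int = 3
    n_spots: int = 5
    n_peptides_total: int = 700
    n_responsive: int = 200
    beta_true: Optional[dict[str, tuple[float, float, float]]] = None
    mz_range: tuple[float, float] = (700.0, 3100.0)
    mz_step: float = 0.1
    intensity_cv: float = 0.15
    baseline_amplitude: float = 50.0
    detector_noise_sd: float = 1.0
    peak_width_sigma: float = 0.8
    basal_height_range: tuple[float, float] = (2.5, 250.0)

    def to_simulation_config(self, seed: int) -> SimulationConfig:
        kwargs = self.model_dump()
        betas = kwargs.pop("beta_true")
        if betas is not None:
            kwargs["beta_true"] = {p: ParticleBetas(*v) for p, v in betas.items()}
        config = SimulationConfig(seed=seed, **kwargs)
        config.validate()
        return config


class ProcessingParams(BaseModel):
    """Spectral-processing stage parameters (windows in Th)."""

    model_config = ConfigDict(extra="forbid")

    baseline_window: float = Field(30.0, gt=0)
    noise_window: float = Field(15.0, gt=0)
    smooth_window: float = Field(1.5, ge=0)  # 0 disables smoothing
    snr_detect: float = Field(2.0, gt=0)
    snr_floor: float = Field(3.0, gt=0)
    top_n: int = Field(200, gt=0)
    tolerance_ppm: float = Field(250.0, gt=0)
    min_spot_fraction: float = Field(0.6, gt=0, le=1)


class PipelineConfig(BaseModel):
    """Everything one reproducible end-to-end run needs."""

    model_config = ConfigDict(extra="forbid")

    input_dir: Optional[Path] = None  # None -> simulate a fixture
    outdir: Path = Path("pmscreen_out")
    seed: int = Field(0, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    sim: SimSettings = Field(default_factory=SimSettings)
    processing: ProcessingParams = Field(default_factory=ProcessingParams)
    log_scale_tests: bool = False
    bh_correction: bool = False
    anova_method: Literal["holm", "dunnett"] = "holm"
    heatmap: bool = True

    @field_validator("sim")
    @classmethod
    def _sim_consistent(cls, sim: SimSettings) -> SimSettings:
        sim.to_simulation_config(seed=0)  # raises ConfigurationError naming the field
        return sim


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse YAML config text into a validated :class:`PipelineConfig`.

    Unknown keys, out-of-range values and malformed fields are each named in
    the raised :class:`ConfigurationError`.  An empty document yields all
    defaults.
    """
    try:
        raw = yaml.safe_load(raw_text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping of option names to values")
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration: {issues}") from exc
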