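"""Pipeline configuration: a validated YAML schema tying the stages together.

Unknown keys are rejected (``extra="forbid"``) so typos fail loudly before
any computation.  One master seed drives every stochastic stage through
:func:`mesbi.io.stage_seed`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .npe import ArchConfig, PriorBox
from .simulator import PARAM_NAMES, FixedConstants, FrequencyGrid

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration failed schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PriorSpec(_Strict):
    low: list[float] = Field(default=[1.0, 0.005, 1.0, 1.0, 1.0, 0.05, 3.0])
    high: list[float] = Field(default=[20.0, 1.0, 10.0, 10.0, 10.0, 0.2, 30.0])
    scale: list[str] = Field(default=["linear"] * 7)

    def build(self) -> PriorBox:
        return PriorBox(low=tuple(self.low), high=tuple(self.high), scale=tuple(self.scale))


class GridSpec(_Strict):
    n_freq: int = 50
    f_lo: float = 250.0
    f_hi: float = 8000.0

    def build(self) -> FrequencyGrid:
        return FrequencyGrid(n_freq=self.n_freq, f_lo=self.f_lo, f_hi=self.f_hi)


class ConstantsSpec(_Strict):
    rho_air: float = 1.205
    c_air: float = 343.0
    canal_radius: float = 3.0e-3
    canal_length_probe_to_drum: float = 10.0e-3
    plane_distance_from_probe: float = 3.0e-3
    footplate_area: float = 3.2e-6
    m_td: float = 4.5e3
    m_os: float = 2.0e3
    g_td: float = 1.8e4
    g_ml: float = 5.0e3
    g_j: float = 2.0e4
    g_s: float = 5.0e3
    g_sal: float = 4.0e5
    transformer: float = 675.0

    def build(self) -> FixedConstants:
        return FixedConstants(**self.model_dump())


class NoiseSpec(_Strict):
    mag_db: float = 0.5
    phase_cycles: float = 0.02
    absorbance: float = 0.02
    scale: float = 1.0
    n_replicates: int = 17
    per_block_median: bool = False  # collapse per-element STD to block medians


class TrainingSpec(_Strict):
    n_train: int = 10_000
    feature_blocks: list[str] = Field(default=["all"])
    embedding_layers: int = 3
    embedding_units: int = 50
    n_components: int = 8
    lr: float = 5e-4
    batch_size: int = 200
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1

    def build_arch(self, seed: int = 0) -> ArchConfig:
        return ArchConfig(
            embedding_layers=self.embedding_layers,
            embedding_units=self.embedding_units,
            n_components=self.n_components,
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=seed,
        )


class ExperimentSpec(_Strict):
    n_heldout: int = 5
    noise_scales: list[float] = Field(default=[0.1, 1.0, 10.0])
    train_sizes: list[int] = Field(default=[100, 1000, 10_000])


class PipelineConfig(_Strict):
    """Top-level validated configuration for every CLI command."""

    prior: PriorSpec = Field(default_factory=PriorSpec)
    grid: GridSpec = Field(default_factory=GridSpec)
    constants: ConstantsSpec = Field(default_factory=ConstantsSpec)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    training: TrainingSpec = Field(default_factory=TrainingSpec)
    experiment: ExperimentSpec = Field(default_factory=ExperimentSpec)
    seed: int = 0
    output_dir: str = "mesbi_out"

    @model_validator(mode="after")
    def _check(self):
        n = len(PARAM_NAMES)
        if not (len(self.prior.low) == len(self.prior.high) == len(self.prior.scale) == n):
            raise ValueError(f"prior lists must all have length {n}")
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file; raise ConfigError on violation."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except FileNotFoundError:
        raise
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: not valid YAML: {e}") from e
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as e:  # pydantic ValidationError carries offending keys
        raise ConfigError(f"{path}: {e}") from e
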