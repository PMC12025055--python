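"""Run configuration: validated, defaulted, hashable.

A single structured config drives the end-to-end pipeline. Unknown keys are
rejected up front (``extra="forbid"``), and the fully resolved config — with
every default filled in — is echoed into the run report together with its
hash so any report can be traced to the exact settings that produced it.

One master ``seed`` fans out deterministically to the balancing, selection,
model and bootstrap sub-seeds.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ParameterError

__all__ = ["RunConfig", "load_config", "config_hash", "fan_out_seeds"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Block):
    source: Literal["synthetic", "bonn_dir", "edf"] = "synthetic"
    # synthetic
    n_per_class: int = Field(100, ge=1)
    fs: float = Field(173.61, gt=0)
    duration_s: float = Field(23.6, gt=0)
    hurst_bg: float = Field(0.7, gt=0, lt=1)
    alpha_amp: float = Field(0.5, ge=0)
    sw_rate: float = Field(3.0, gt=0)
    sw_amp: float = Field(4.0, gt=0)
    burst_fraction: float = Field(0.5, ge=0, le=1)
    noise_sd: float = Field(0.2, ge=0)
    # bonn_dir / edf
    path: str | None = None
    channel: str = "CZ-PZ"
    annotations: str | None = None  # CSV with seizure start/end seconds
    epoch_s: float = Field(23.6, gt=0)


class PreprocessConfig(_Block):
    low_hz: float = Field(0.53, gt=0)
    high_hz: float = Field(40.0, gt=0)
    order: int = Field(4, ge=1)
    scale_mode: Literal["per_segment", "none"] = "per_segment"
    balance_method: Literal["undersample", "none"] = "none"


class FeatureConfig(_Block):
    dwt_wavelet: str = "db4"
    dwt_level: int = Field(4, ge=1)
    dwt_mode: str = "symmetric"
    include_approx: bool = True
    hurst_min_window: int = Field(16, ge=8)


class SelectionConfig(_Block):
    method: Literal["none", "anova", "rf"] = "none"
    k: int = Field(20, ge=1)


class ModelConfig(_Block):
    family: Literal["svm", "rf", "lstm"] = "rf"
    hyperparameters: dict[str, Any] = Field(default_factory=dict)
    input_mode: Literal["features", "raw_timeseries"] = "features"


class EvaluationConfig(_Block):
    folds: int = Field(10, ge=2)
    bootstrap_B: int = Field(1000, ge=100)
    timing: bool = True


class RunConfig(_Block):
    data: DataConfig = Field(default_factory=DataConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    seed: int = 0

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(source: str | dict | None = None) -> RunConfig:
    """Build a validated config from a dict, a JSON/YAML file path, or defaults."""
    if source is None:
        return RunConfig()
    if isinstance(source, dict):
        raw = source
    else:
        text = open(source, "r", encoding="utf-8").read()
        if str(source).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    try:
        return RunConfig.model_validate(raw or {})
    except ValidationError as exc:
        raise ParameterError(f"invalid configuration: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    canon = json.dumps(config.resolved_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def fan_out_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic sub-seeds for each stochastic stage."""
    children = np.random.SeedSequence(master_seed).spawn(5)
    names = ("data", "balance", "selection", "model", "bootstrap")
    return {
        name: int(ss.generate_state(1)[0] % (2**31 - 1))
        for name, ss in zip(names, children)
    }
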