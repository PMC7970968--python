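"""Run configuration: one strict, human-readable YAML file drives a full run.

Unknown keys are rejected; every run echoes its effective configuration and
its hash into the output directory so artifacts are reproducible from config
plus seed alone.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .synthetic import DEFAULT_NOISE_LEVELS

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "stage_seed",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureConfig(_Strict):
    categories: tuple[str, str] = ("face", "house")
    image_size: tuple[int, int] = (300, 450)
    n_per_category: int = 10
    noise_levels: list[float] = list(DEFAULT_NOISE_LEVELS)


class BehaviorConfig(_Strict):
    base_rt_ms: dict[str, float] = {"face": 550.0, "house": 580.0}
    rt_slope_ms: float = 400.0
    rt_noise_sd: float = 80.0
    lapse_rate: float = 0.05
    n_trials: int = 20


class FrontendConfig(_Strict):
    wavelength: float = 5.0
    width: float = 2.0
    kernel_size: int = 5
    orientations_deg: list[float] = [22.5, 67.5, 112.5, 157.5]
    scale_factors: list[float] = [1.00, 0.71, 0.50, 0.35, 0.25]
    epsilon: float = 1e-6


class S2Config(_Strict):
    n_per_category: int = 10
    a_plus: float = 2.0**-5
    a_minus: float = 0.75 * 2.0**-5
    epochs: int = 400
    theta_fraction: float = 2.0 / 3.0
    threshold_factor: float = 0.5
    init_mean: float = 0.8
    init_sd: float = 0.05
    orientation_sensitive: bool = True


class DecisionConfig(_Strict):
    init_threshold: float = 10.0
    init_alpha: float = 10.0
    init_rt_motor: float = 300.0
    u: float = 0.0
    n_restarts: int = 5
    max_evals: int = 2000
    n_bins: int = 512


class SweepConfig(_Strict):
    collapse_fractions: list[float] = list(np.round(np.linspace(0.1, 1.0, 10), 3))
    n_deadlines: int = 8


class RunConfig(_Strict):
    seed: int = 0
    fixtures: FixtureConfig = FixtureConfig()
    behavior: BehaviorConfig = BehaviorConfig()
    frontend: FrontendConfig = FrontendConfig()
    s2: S2Config = S2Config()
    decision: DecisionConfig = DecisionConfig()
    sweep: SweepConfig = SweepConfig()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when path is None)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)
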