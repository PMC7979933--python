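"""Run configuration: one YAML file drives an end-to-end analysis.

Every protocol tunable defaults to the published study value: IQR
multiplier 1.5, Pearson pruning threshold 0.70, significance alpha 0.05,
training fraction 0.75.  Seeds are mandatory for the stochastic stages; all
stage seeds derive deterministically from the single ``seed`` field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError


@dataclass
class ScenarioSpec:
    """Climate drift of one scenario: additive temperature trend (degC per
    decade) and multiplicative precipitation trend (ratio per decade)."""

    temp_delta_per_decade: float
    precip_factor_per_decade: float


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "socgwr_run"

    # synthetic landscape
    nx: int = 40
    ny: int = 40
    cell_size: float = 800.0
    n_regions: int = 5
    smoothness: float = 6.0
    n_obs: int = 300
    layers_per_profile: int = 5
    lambda_true: float = 0.5
    noise_sd: float = 0.4
    continuous_predictors: list = field(
        default_factory=lambda: ["temperature", "precipitation", "npp", "ndvi"]
    )
    categorical_predictors: list = field(
        default_factory=lambda: [["soil_order", 4], ["land_cover", 3]]
    )

    # protocol tunables (published defaults)
    iqr_k: float = 1.5
    corr_threshold: float = 0.70
    alpha: float = 0.05
    train_fraction: float = 0.75

    # GWR
    kernel: str = "bisquare"
    k_min: int | None = None
    k_max: int | None = None
    ridge_jitter: float = 1e-8

    # scenarios
    decades: list = field(default_factory=lambda: list(range(2030, 2101, 10)))
    scenarios: dict = field(
        default_factory=lambda: {
            "ssp_low": {"temp_delta_per_decade": 0.1, "precip_factor_per_decade": 1.0},
            "ssp_high": {"temp_delta_per_decade": 0.5, "precip_factor_per_decade": 0.97},
        }
    )

    priority: list | None = None  # pruning priority; defaults to column order

    def validate(self) -> "RunConfig":
        if not 0 < self.train_fraction < 1:
            raise InvalidArgumentError("train_fraction must be in (0, 1)")
        for name, v in (("iqr_k", self.iqr_k), ("corr_threshold", self.corr_threshold),
                        ("alpha", self.alpha)):
            if v <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.seed is None:
            raise InvalidArgumentError("a seed is mandatory")
        return self

    def stage_seed(self, offset: int) -> int:
        """Deterministic per-stage seed below 2^31."""
        return (int(self.seed) * 1000 + offset) % (2**31 - 1)

    def to_dict(self) -> dict:
        return asdict(self)


def read_config(path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise InvalidArgumentError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw).validate()


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
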