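"""Flat, validated pipeline configuration.

One serializable key-value document collects every tunable the modules
expose; unknown keys are rejected and each run can echo its effective
config into its outputs for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .exceptions import InvalidArgumentError

__all__ = ["PipelineConfig", "read_config", "validate_config"]


@dataclass
class PipelineConfig:
    # denoising
    wavelet_name: str = "bior3.9"
    n_levels: int = 5
    shape_beta: int = 10
    # reference fitting
    fit_tol: float = 1e-8
    fit_max_iter: int = 500
    # time of flight
    sound_speed: float = 1480.0        # m/s (water phantom; 1540 for tissue)
    min_separation_us: float = 2.0     # two carrier periods at 1 MHz
    threshold_frac: float = 0.02
    subsample_refine: bool = True
    # ellipsoid
    ellipsoid_k: float = 4.0
    min_points: int = 9
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        validate_config(self)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def validate_config(cfg: PipelineConfig) -> None:
    checks = [
        (cfg.n_levels >= 1, "n_levels", "must be >= 1"),
        (cfg.shape_beta >= 2, "shape_beta", "must be an integer >= 2"),
        (cfg.fit_tol > 0, "fit_tol", "must be > 0"),
        (cfg.fit_max_iter >= 1, "fit_max_iter", "must be >= 1"),
        (cfg.sound_speed > 0, "sound_speed", "must be > 0"),
        (cfg.min_separation_us > 0, "min_separation_us", "must be > 0"),
        (0.0 < cfg.threshold_frac < 1.0, "threshold_frac", "must be in (0, 1)"),
        (cfg.ellipsoid_k > 0, "ellipsoid_k", "must be > 0"),
        (cfg.min_points >= 9, "min_points", "must be >= 9"),
    ]
    for ok, key, msg in checks:
        if not ok:
            raise InvalidArgumentError(f"config key '{key}' {msg}")


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise InvalidArgumentError(f"{path}: config must be a JSON object")
    return PipelineConfig.from_dict(data)
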