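"""Run configuration: dataclasses, YAML loading, validation, digests.

A run is fully described by four blocks (preprocess, engine, detector, eval)
plus a seed. Unknown keys are rejected so that a typo in a YAML file fails
loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "PreprocessConfig",
    "EngineConfig",
    "DetectorConfig",
    "EvalConfig",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values in a configuration."""


def _from_dict(cls, data: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} key(s): {', '.join(sorted(unknown))}"
        )
    obj = cls(**data)
    obj.validate()
    return obj


@dataclass
class PreprocessConfig:
    """Segmentation and edge-map extraction parameters.

    ``edge_method`` selects which edge map feeds detection: ``"canny"``
    (Canny applied to the binary mask rendered 0/255, the default) or
    ``"morph"`` (erosion-based morphological boundary).
    """

    edge_method: str = "canny"
    median_filter: int = 3                # despeckle window before thresholding; 0 = off
    threshold: int | None = None          # explicit intensity threshold; None = Otsu
    foreground: str = "dark"              # which side of the threshold is the cell class
    canny_sigma: float = 1.0
    canny_low: float | None = None        # None = median-based automatic rule
    canny_high: float | None = None
    on_constant: str = "warn"             # constant image + auto threshold: warn | error

    def validate(self) -> None:
        if self.edge_method not in ("canny", "morph"):
            raise ConfigError(f"edge_method must be 'canny' or 'morph', got {self.edge_method!r}")
        if self.median_filter < 0 or self.median_filter == 2 or (
                self.median_filter > 1 and self.median_filter % 2 == 0):
            raise ConfigError("median_filter must be 0, 1 or an odd window size")
        if self.foreground not in ("dark", "bright"):
            raise ConfigError(f"foreground must be 'dark' or 'bright', got {self.foreground!r}")
        if self.threshold is not None and not (0 <= self.threshold <= 255):
            raise ConfigError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.on_constant not in ("warn", "error"):
            raise ConfigError(f"on_constant must be 'warn' or 'error', got {self.on_constant!r}")
        if (self.canny_low is None) != (self.canny_high is None):
            raise ConfigError("canny_low and canny_high must be given together")


@dataclass
class EngineConfig:
    """Plant-growth optimiser parameters.

    k         initial particles (trunk nodes)
    q         maximum branch nodes proposed when a node grows
    patience  improvement-free growth cycles before stopping
    p_explore probability of a fresh uniform candidate instead of a
              neighbourhood perturbation
    w         index-perturbation half-width; None = max(1, round(0.02 * N_p))
    root_fitness  f(R_0); nodes are eligible only if strictly fitter
    """

    k: int = 30
    q: int = 10
    patience: int = 10
    max_iterations: int = 200
    p_explore: float = 0.1
    w: int | None = None
    root_fitness: float = 1.0
    max_restarts: int = 5

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.q < 1:
            raise ConfigError("q must be >= 1")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if not (0.0 <= self.p_explore <= 1.0):
            raise ConfigError("p_explore must be in [0, 1]")
        if self.w is not None and self.w < 1:
            raise ConfigError("w must be >= 1 when given")
        if self.max_restarts < 1:
            raise ConfigError("max_restarts must be >= 1")


@dataclass
class DetectorConfig:
    """Multi-circle extraction parameters.

    alpha           circumference-coverage acceptance threshold
    delta           erasure band half-width (px) around an accepted circle
    edge_tolerance  Chebyshev radius for edge membership in the coverage term
                    (0 = exact pixel membership)
    """

    alpha: float = 0.5
    delta: float = 2.0
    r_min: float = 5.0
    r_max: float | None = None            # None = min(width, height) / 2
    max_circles: int = 20
    min_edge_points: int = 20
    edge_tolerance: int = 1

    def validate(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError("alpha must be in (0, 1]")
        if self.delta <= 0:
            raise ConfigError("delta must be > 0")
        if self.r_min <= 0:
            raise ConfigError("r_min must be > 0")
        if self.r_max is not None and self.r_max <= self.r_min:
            raise ConfigError("r_max must exceed r_min")
        if self.max_circles < 1:
            raise ConfigError("max_circles must be >= 1")
        if self.min_edge_points < 3:
            raise ConfigError("min_edge_points must be >= 3")
        if self.edge_tolerance < 0:
            raise ConfigError("edge_tolerance must be >= 0")


@dataclass
class EvalConfig:
    """Detection-to-truth matching tolerances and metric conventions."""

    tau_c: float = 5.0                    # centre distance tolerance, px
    tau_r: float = 0.2                    # relative radius tolerance
    fpr_definition: str = "expert"        # 'expert': FP / n_truth; 'standard': undefined

    def validate(self) -> None:
        if self.tau_c <= 0:
            raise ConfigError("tau_c must be > 0")
        if not (0.0 < self.tau_r < 1.0):
            raise ConfigError("tau_r must be in (0, 1)")
        if self.fpr_definition not in ("expert", "standard"):
            raise ConfigError("fpr_definition must be 'expert' or 'standard'")


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    log_level: str = "info"

    def validate(self) -> None:
        for block in (self.preprocess, self.engine, self.detector, self.eval):
            block.validate()
        if self.log_level not in ("debug", "info", "warning", "error"):
            raise ConfigError(f"log_level must be a standard level, got {self.log_level!r}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        known = {"preprocess", "engine", "detector", "eval", "seed", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig key(s): {', '.join(sorted(unknown))}")
        kwargs: dict[str, Any] = {}
        for name, sub in (
            ("preprocess", PreprocessConfig),
            ("engine", EngineConfig),
            ("detector", DetectorConfig),
            ("eval", EvalConfig),
        ):
            if name in data:
                block = data.pop(name)
                if not isinstance(block, Mapping):
                    raise ConfigError(f"{name} block must be a mapping")
                kwargs[name] = _from_dict(sub, block)
        kwargs.update(data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must contain a mapping at top level")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def digest(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
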