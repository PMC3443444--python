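"""Run configuration for the segmentation pipeline.

All tunables the pipeline exposes live here, grouped per stage, with the
defaults used throughout; a TOML or JSON file can override any subset.
Unknown keys are rejected so typos fail loudly instead of silently running
with defaults.
"""
from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .io import Calibration

__all__ = ["CannyParams", "SamplingParams", "CornerParams", "InterfaceParams",
           "SplineParams", "RunConfig"]


@dataclass(frozen=True)
class CannyParams:
    """Edge-detector settings; thresholds are gradient-magnitude quantiles
    so detection survives exposure differences between scans."""

    sigma: float = 2.0      # px, Gaussian derivative scale
    low_q: float = 0.80     # hysteresis low threshold quantile
    high_q: float = 0.95    # hysteresis high threshold quantile

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigError(f"canny.sigma must be > 0, got {self.sigma}")
        if not (0 <= self.low_q <= self.high_q <= 1):
            raise ConfigError(
                f"need 0 <= low_q <= high_q <= 1, got ({self.low_q}, {self.high_q})"
            )


@dataclass(frozen=True)
class SamplingParams:
    step: int = 10  # px between boundary samples; damps interference noise

    def __post_init__(self):
        if self.step < 1:
            raise ConfigError(f"sampling.step must be >= 1, got {self.step}")


@dataclass(frozen=True)
class CornerParams:
    """Dominant-point (k-cosine) corner detector settings."""

    window: int = 10          # support arm length, in boundary samples
    z_threshold: float = 2.5  # significance threshold on the turn-angle z-score
    min_angle_deg: float = 3.0  # reject sub-noise "corners" on smooth arcs

    def __post_init__(self):
        if self.window < 2:
            raise ConfigError(f"corner.window must be >= 2, got {self.window}")
        if self.z_threshold <= 0 or self.min_angle_deg < 0:
            raise ConfigError("corner thresholds must be positive")


@dataclass(frozen=True)
class InterfaceParams:
    """Host-graft interface search settings.

    The search band extends from the posterior boundary anteriorly by at
    most ``band_factor`` x the median prior band-thickness estimate; a
    column yields a gap when no axial gradient in the band clears the
    absolute noise floor.
    """

    band_factor: float = 1.5
    abs_floor: float = 0.005   # intensity units per px
    posterior_margin_px: float = 3.0  # keep the posterior edge's own gradient tail out
    max_gap_fraction: float = 0.5  # beyond this, raise LowContrastError
    outlier_px: float = 4.0    # reject picks this far from the local median path

    def __post_init__(self):
        if self.band_factor <= 0 or self.abs_floor < 0 or self.posterior_margin_px < 0:
            raise ConfigError("invalid interface parameters")


@dataclass(frozen=True)
class SplineParams:
    smoothing: float = 1.0  # px^2 residual budget per control point

    def __post_init__(self):
        if self.smoothing < 0:
            raise ConfigError(f"spline.smoothing must be >= 0, got {self.smoothing}")


@dataclass(frozen=True)
class RunConfig:
    calibration: Calibration = field(default_factory=Calibration)
    preprocess_scale: float = 1.0  # px, pre-smoothing before edge detection
    canny: CannyParams = field(default_factory=CannyParams)
    sampling: SamplingParams = field(default_factory=SamplingParams)
    corner: CornerParams = field(default_factory=CornerParams)
    interface: InterfaceParams = field(default_factory=InterfaceParams)
    spline: SplineParams = field(default_factory=SplineParams)
    mode: str = "automated"
    seed: int = 0

    def __post_init__(self):
        if self.preprocess_scale < 0:
            raise ConfigError("preprocess_scale must be >= 0")
        if self.mode not in ("automated", "semi_automated"):
            raise ConfigError(f"mode must be automated|semi_automated, got {self.mode!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs: dict = {}
        nested = {
            "calibration": Calibration,
            "canny": CannyParams,
            "sampling": SamplingParams,
            "corner": CornerParams,
            "interface": InterfaceParams,
            "spline": SplineParams,
        }
        for key, klass in nested.items():
            if key in data:
                sub = data.pop(key)
                _check_keys(sub, klass, key)
                try:
                    kwargs[key] = klass(**sub)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"bad {key} section: {exc}") from exc
        _check_keys(data, cls, "top level")
        try:
            return cls(**kwargs, **data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            try:
                data = json.loads(path.read_text())
            except json.JSONDecodeError as exc:
                raise ConfigError(f"{path.name}: not valid JSON ({exc.msg})") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path.name}: config root must be a table/object")
        return cls.from_dict(data)


def _check_keys(section: dict, klass, where: str) -> None:
    if not isinstance(section, dict):
        raise ConfigError(f"{where}: expected a table/object")
    valid = {f.name for f in dataclasses.fields(klass)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"{where}: unknown config key(s) {sorted(unknown)}")
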