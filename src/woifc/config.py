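"""Run configuration for the wide-field imaging pipeline.

Defaults reproduce the acquisition/processing parameters of the pigeon
wide-field optical imaging study this package implements: three LED
wavelengths (530/590/625 nm), 16 frames/s reduced to 8 frames/s, spatial
downsampling to 75x100 pixels, a 0.02-0.167 Hz functional passband, 5x5
Gaussian smoothing with sigma = 1.3 px, a censoring threshold of 1 on the
frame-mean squared HbO2 contrast, 30 parcels, and a hierarchical cut at the
first level with at least 8 clusters.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parameters controlling every stage of the pipeline.

    All rates are in Hz, sizes in pixels. ``band_hz`` is the functional
    passband applied after hemoglobin conversion; ``censor_threshold`` is
    compared against the spatial mean of squared HbO2 contrast per frame.
    """

    wavelengths_nm: tuple[float, ...] = (530.0, 590.0, 625.0)
    frame_rate_hz: float = 16.0
    downsample_shape: tuple[int, int] = (75, 100)
    downsample_frame_rate_hz: float = 8.0
    band_hz: tuple[float, float] = (0.02, 0.167)
    smoothing: tuple[int, float] = (5, 1.3)  # (kernel size, sigma in px)
    censor_threshold: float = 1.0
    n_parcels: int = 30
    min_clusters: int = 8
    max_iter: int = 100
    midline_band_halfwidth: int = 3
    filter_order: int = 5
    linkage: str = "average"
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        low, high = self.band_hz
        nyquist = self.downsample_frame_rate_hz / 2.0
        if not (0.0 < low < high):
            raise ConfigError(f"band_hz must satisfy 0 < low < high, got {self.band_hz}")
        if high >= nyquist:
            raise ConfigError(
                f"band high {high} Hz must be below Nyquist {nyquist} Hz "
                f"at {self.downsample_frame_rate_hz} fps"
            )
        if self.frame_rate_hz <= 0 or self.downsample_frame_rate_hz <= 0:
            raise ConfigError("frame rates must be positive")
        if self.downsample_frame_rate_hz > self.frame_rate_hz:
            raise ConfigError("downsampled rate cannot exceed acquisition rate")
        if any(s <= 0 for s in self.downsample_shape):
            raise ConfigError("downsample_shape entries must be positive")
        if len(self.wavelengths_nm) < 2:
            raise ConfigError("at least two wavelengths are required")
        if self.min_clusters < 2:
            raise ConfigError("min_clusters must be >= 2")
        if self.n_parcels < self.min_clusters:
            raise ConfigError(
                f"n_parcels ({self.n_parcels}) must be >= min_clusters ({self.min_clusters})"
            )
        ksize, sigma = self.smoothing
        if ksize < 1 or sigma <= 0:
            raise ConfigError("smoothing kernel size must be >= 1 and sigma > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")

    def replace(self, **kwargs: Any) -> "RunConfig":
        """Return a copy with the given keys overridden (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # tuples -> lists for YAML/JSON friendliness
        for key in ("wavelengths_nm", "downsample_shape", "band_hz", "smoothing"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any], strict: bool = False) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            msg = f"unknown config keys: {sorted(unknown)}"
            if strict:
                raise ConfigError(msg)
            warnings.warn(msg, stacklevel=2)
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if f.name in ("wavelengths_nm", "downsample_shape", "band_hz", "smoothing"):
                value = tuple(value)
            kwargs[f.name] = value
        return cls(**kwargs)


def load_config(path: str | Path, strict: bool = False) -> RunConfig:
    """Load a :class:`RunConfig` from YAML or JSON.

    Omitted keys take the documented study defaults; an empty file yields
    the full default configuration. Unknown keys warn, or raise when
    ``strict`` is true.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    # allow a nested `run:` section so one file can hold run + scenario config
    if "run" in data and isinstance(data["run"], dict):
        data = data["run"]
    data = {k: v for k, v in data.items() if k != "scenario"}
    return RunConfig.from_dict(data, strict=strict)
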