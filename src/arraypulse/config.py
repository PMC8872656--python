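"""Pipeline configuration with YAML loading.

Defaults follow the published processing chain: 100 Hz sampling, a 6th-order
Chebyshev-I band-pass between 1 and 4 Hz, and a 1000 x 1000 interpolation
grid for the array surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import FootprintSpec


@dataclass(frozen=True)
class PipelineConfig:
    # band-pass filter
    filter_low_hz: float = 1.0
    filter_high_hz: float = 4.0
    filter_order: int = 6
    filter_ripple_db: float = 0.5
    filter_zero_phase: bool = True
    # surface interpolation / volume
    n_grid: int = 1000
    footprint: FootprintSpec = field(default_factory=FootprintSpec)
    literal_total_area_s: bool = False
    # beat segmentation heart-rate bounds (bpm)
    min_hr_bpm: float = 40.0
    max_hr_bpm: float = 180.0
    # statistics
    normality_alpha: float = 0.05
    significance_alpha: float = 0.05
    # default sampling rate assumed for files without explicit fs
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.filter_low_hz < self.filter_high_hz):
            raise ConfigError("need 0 < low < high for the band-pass")
        if self.fs > 0 and self.filter_high_hz >= self.fs / 2:
            raise ConfigError("high cutoff must be below Nyquist")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ConfigError("filter order must be even and >= 2")
        if self.filter_ripple_db <= 0:
            raise ConfigError("passband ripple must be positive")
        if self.n_grid < 4:
            raise ConfigError("interpolation grid N must be >= 4")
        if not (0 < self.min_hr_bpm < self.max_hr_bpm):
            raise ConfigError("need 0 < min_hr < max_hr")
        for name in ("normality_alpha", "significance_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ConfigError(f"{name} must lie in (0, 1)")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


_KEYMAP = {
    ("filter", "low_hz"): "filter_low_hz",
    ("filter", "high_hz"): "filter_high_hz",
    ("filter", "order"): "filter_order",
    ("filter", "ripple_db"): "filter_ripple_db",
    ("filter", "zero_phase"): "filter_zero_phase",
    ("apv", "n_grid"): "n_grid",
    ("apv", "literal_total_area_s"): "literal_total_area_s",
    ("segmentation", "min_hr_bpm"): "min_hr_bpm",
    ("segmentation", "max_hr_bpm"): "max_hr_bpm",
    ("stats", "normality_alpha"): "normality_alpha",
    ("stats", "significance_alpha"): "significance_alpha",
    (None, "fs"): "fs",
    (None, "seed"): "seed",
}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; absent keys fall back to the defaults above."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    kwargs: dict = {}
    for (section, key), attr in _KEYMAP.items():
        src = raw.get(section, {}) if section else raw
        if isinstance(src, dict) and key in src:
            kwargs[attr] = src[key]
    apv = raw.get("apv", {})
    if isinstance(apv, dict) and ("footprint_width" in apv or "footprint_length" in apv):
        kwargs["footprint"] = FootprintSpec(
            width=float(apv.get("footprint_width", 1.0)),
            length=float(apv.get("footprint_length", 1.0)),
        )
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:  # wrong value type slipped through YAML
        raise ConfigError(str(exc)) from exc
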