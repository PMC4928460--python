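"""Analysis configuration: every fixed constant of the method in one place.

Defaults are the method's standard values: 0.01–0.15 Hz band, order-3
zero-phase Butterworth, 3 mm FWHM smoothing, maxcc threshold 0.3, ±6 s lag
window, 10 equal-count bins.  The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .exceptions import ParameterError


@dataclass
class AnalysisConfig:
    band_low_hz: float = 0.01
    band_high_hz: float = 0.15
    filter_order: int = 3
    fwhm_mm: float = 3.0
    maxcc_threshold: float = 0.3
    lag_limit_s: float = 6.0
    n_bins: int = 10
    alff_valid_mode: str = "brain"  # "brain" | "maxcc_valid"
    swap_pooling: str = "per_map"  # "per_map" | "per_subject"
    smooth_before_filter: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.band_low_hz < self.band_high_hz):
            raise ParameterError("band_low_hz must be in (0, band_high_hz)")
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")
        if self.fwhm_mm < 0:
            raise ParameterError("fwhm_mm must be >= 0")
        if self.lag_limit_s <= 0:
            raise ParameterError("lag_limit_s must be positive")
        if self.n_bins < 1:
            raise ParameterError("n_bins must be >= 1")
        if self.alff_valid_mode not in ("brain", "maxcc_valid"):
            raise ParameterError(f"unknown alff_valid_mode {self.alff_valid_mode!r}")
        if self.swap_pooling not in ("per_map", "per_subject"):
            raise ParameterError(f"unknown swap_pooling {self.swap_pooling!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg
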