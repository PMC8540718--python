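"""Pipeline configuration: the study's processing settings in one place.

Defaults reproduce the protocol settings: 60-s windows with 10 % overlap,
EMA extrapolation windows of 30/60/120 min, the 2 °C temperature rule, the
10-min daily heart-rate baseline, the 10 % class-prevalence floor, and the
Butterworth chains per channel. Everything is overridable from a YAML file
or CLI flags; a run manifest (config hash + seed) makes stochastic
protocols replayable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dataset_model import SvmConfig
from .ema_labeling import EMA_WINDOW_CHOICES_MIN
from .features import WindowSpec
from .preprocess import ACC_BANDPASS, EDA_LOWPASS, FilterSpec

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    window: WindowSpec = field(default_factory=WindowSpec)
    ema_window_min: float = 60.0
    allow_any_ema_window: bool = False
    temp_threshold_C: float = 2.0
    hr_baseline_min: float = 10.0
    label_min_fraction: float = 0.5
    min_class_fraction: float = 0.10
    acc_filter: FilterSpec = field(default_factory=lambda: ACC_BANDPASS)
    eda_filter: FilterSpec = field(default_factory=lambda: EDA_LOWPASS)
    gap_threshold_s: float = 4 * 3600.0
    svm: SvmConfig = field(default_factory=SvmConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.allow_any_ema_window and self.ema_window_min not in EMA_WINDOW_CHOICES_MIN:
            raise ValueError(
                f"ema_window_min must be one of {EMA_WINDOW_CHOICES_MIN} "
                "(set allow_any_ema_window to override)"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "window" in d and isinstance(d["window"], dict):
            d["window"] = WindowSpec(**d["window"])
        for key in ("acc_filter", "eda_filter"):
            if key in d and isinstance(d[key], dict):
                d[key] = FilterSpec(**d[key])
        if "svm" in d and isinstance(d["svm"], dict):
            sv = dict(d["svm"])
            for g in ("c_grid", "gamma_grid"):
                if g in sv:
                    sv[g] = tuple(sv[g])
            d["svm"] = SvmConfig(**sv)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
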