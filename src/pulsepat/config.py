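"""Pipeline configuration with YAML loading.

Defaults are the operating point used throughout: k = 3, θ1 = 0,
θ2 = 0.0005, envelope median order 5, correction order M = 5, PAT median
order n = 15, 5 Hz uniform resampling, 10-s template-matching windows.
Precedence is CLI flag > config file > defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from pulsepat.quality import QualityParams
from pulsepat.rhythm import RhythmParams


@dataclass
class PipelineConfig:
    quality: QualityParams = field(default_factory=QualityParams)
    rhythm: RhythmParams = field(default_factory=RhythmParams)
    M: int = 5
    n_median: int = 15
    out_rate: float = 5.0
    tm_window_s: float = 10.0
    tm_corr_threshold: float = 0.86
    ecg_label: str = "EKG"
    ppg_label: str = "Pleth"
    spo2_label: str | None = None
    normalize_ppg: bool = False
    elimination_mode: str = "correct"  # or "exclude"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elimination_mode not in {"correct", "exclude"}:
            raise ValueError("elimination_mode must be 'correct' or 'exclude'")
        if self.n_median % 2 == 0:
            raise ValueError("n_median must be odd")
        if self.out_rate <= 0 or self.tm_window_s <= 0:
            raise ValueError("out_rate and tm_window_s must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        if "quality" in raw:
            kwargs["quality"] = QualityParams(**raw.pop("quality"))
        if "rhythm" in raw:
            kwargs["rhythm"] = RhythmParams(**raw.pop("rhythm"))
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
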