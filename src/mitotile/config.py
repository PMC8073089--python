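"""Run/analysis configuration with per-kit presets.

Two named presets mirror the two multiplex chemistries: ``control-region``
(151-cycle pairs, AT/IT 10%, minimum 64 reads) and ``whole-genome``
(201-cycle pairs, AT/IT 6%, minimum 45 reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .call import CONTROL_REGION_THRESHOLDS, WHOLE_GENOME_THRESHOLDS, Thresholds


class ConfigError(ValueError):
    pass


PRESETS: dict[str, dict] = {
    "control-region": {
        "thresholds": CONTROL_REGION_THRESHOLDS,
        "read_length": 151,
    },
    "whole-genome": {
        "thresholds": WHOLE_GENOME_THRESHOLDS,
        "read_length": 201,
    },
}


@dataclass
class PipelineConfig:
    genome_path: Optional[str] = None  # None -> packaged synthetic reference
    panel_path: Optional[str] = None
    sample_sheet_path: Optional[str] = None
    numt_db_path: Optional[str] = None
    output_dir: str = "mitotile-out"
    preset: str = "control-region"
    thresholds: Thresholds = field(default_factory=lambda: CONTROL_REGION_THRESHOLDS)
    read_length: int = 151
    seed: int = 0
    uas_compat: bool = False

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "PipelineConfig":
        if preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        p = PRESETS[preset]
        cfg = cls(preset=preset, thresholds=p["thresholds"], read_length=p["read_length"])
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown config field {k!r}")
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        preset = data.pop("preset", "control-region")
        thr = data.pop("thresholds", None)
        cfg = cls.from_preset(preset)
        if thr:
            cfg.thresholds = Thresholds(
                analytical_threshold=thr.get(
                    "analytical_threshold", cfg.thresholds.analytical_threshold
                ),
                interpretation_threshold=thr.get(
                    "interpretation_threshold", cfg.thresholds.interpretation_threshold
                ),
                min_read_count=thr.get("min_read_count", cfg.thresholds.min_read_count),
                min_q=thr.get("min_q", cfg.thresholds.min_q),
            )
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown config field {k!r} in {path}")
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "preset": self.preset,
            "genome_path": self.genome_path,
            "panel_path": self.panel_path,
            "sample_sheet_path": self.sample_sheet_path,
            "numt_db_path": self.numt_db_path,
            "output_dir": self.output_dir,
            "read_length": self.read_length,
            "seed": self.seed,
            "uas_compat": self.uas_compat,
            "thresholds": {
                "analytical_threshold": self.thresholds.analytical_threshold,
                "interpretation_threshold": self.thresholds.interpretation_threshold,
                "min_read_count": self.thresholds.min_read_count,
                "min_q": self.thresholds.min_q,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
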