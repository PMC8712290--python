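"""Validated run configuration: YAML file + CLI overrides, strict ranges,
unknown keys rejected before any I/O happens."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # class building
    p_threshold: float = 0.9
    erode_binary: int = 1
    erode_probability: int = 0
    early_window_s: float = 180.0
    n_top_blood: int = 50
    aggregation: str = "mean"
    hbgm_mask_name: str = "high_binding"
    blood_search_dilate: int = 2
    min_subjects_warn: int = 10
    # extraction
    lbgm_ratio_threshold: float = 0.9
    averaging: str = "simple"
    candidate_policy: str = "lbgm"  # "lbgm" or "brain"
    candidate_p_threshold: float = 0.9
    genotype_policy: str = "strict"  # "strict" or "ignore"
    min_voxels_warn: int = 50
    force_mask_mismatch: bool = False
    # simulation / misc
    noise_level: float = 0.1
    seed: int = 0

    def validate(self) -> "RunConfig":
        checks = [
            (0.0 < self.p_threshold < 1.0, "p_threshold must be in (0,1)"),
            (0.0 < self.candidate_p_threshold < 1.0, "candidate_p_threshold must be in (0,1)"),
            (0.0 <= self.lbgm_ratio_threshold <= 1.0, "lbgm_ratio_threshold must be in [0,1]"),
            (self.erode_binary >= 0, "erode_binary must be >= 0"),
            (self.erode_probability >= 0, "erode_probability must be >= 0"),
            (self.early_window_s > 0, "early_window_s must be > 0"),
            (self.n_top_blood >= 1, "n_top_blood must be >= 1"),
            (self.aggregation in ("mean", "median"), "aggregation must be mean|median"),
            (self.averaging in ("simple", "weighted"), "averaging must be simple|weighted"),
            (self.candidate_policy in ("lbgm", "brain"), "candidate_policy must be lbgm|brain"),
            (self.genotype_policy in ("strict", "ignore"), "genotype_policy must be strict|ignore"),
            (self.noise_level >= 0, "noise_level must be >= 0"),
            (self.min_voxels_warn >= 0, "min_voxels_warn must be >= 0"),
            (self.blood_search_dilate >= 0, "blood_search_dilate must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        return self

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig with precedence CLI overrides > YAML file > defaults.

    Unknown keys anywhere are a hard error.
    """
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        values.update(loaded)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown override(s): {sorted(unknown)}")
    values.update(overrides)
    try:
        cfg = RunConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg.validate()
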