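"""Layered run configuration: one dataclass block per pipeline stage, all
defaults defined once on the dataclasses themselves.

Unknown keys are rejected rather than ignored, so a typo in a config file
fails loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from csatk.csa_merge import MergeParams
from csatk.mini_assembly import AssemblyParams
from csatk.read_filter import FilterParams
from csatk.simulate import SimConfig

# FilterParams fields that hold sequences/records are wired by the pipeline
# (adapter from the simulation block, contaminants from the vector), not
# from the config file.
_NON_CONFIG_FIELDS = {"contam_refs", "adapter_seqs"}


@dataclass
class HaplotypeConfig:
    same_threshold: float = 0.2  # variants/kb at or below which clones are 'same'


@dataclass
class EvaluateConfig:
    link_min_support: int = 3
    gc_window: int = 500
    anchor_k: int = 32


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        coverage=100.0, seq_error_rate=0.0, duplicate_frac=0.02))
    filter: FilterParams = field(default_factory=FilterParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    merge: MergeParams = field(default_factory=MergeParams)
    haplotype: HaplotypeConfig = field(default_factory=HaplotypeConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    n_sites: int = 3
    large_insert_coverage: float = 30.0  # per large-insert library
    seed: int = 0
    outdir: str = "csa_out"
    log_level: str = "INFO"


_BLOCKS = {
    "sim": SimConfig, "filter": FilterParams, "assembly": AssemblyParams,
    "merge": MergeParams, "haplotype": HaplotypeConfig, "evaluate": EvaluateConfig,
}


def _build_block(cls: type, data: dict[str, Any], context: str) -> Any:
    allowed = {f.name for f in fields(cls)} - _NON_CONFIG_FIELDS
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    if "insert_stats" in data and data["insert_stats"] is not None:
        data = dict(data)
        data["insert_stats"] = {
            int(k): tuple(v) for k, v in data["insert_stats"].items()}
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _BLOCKS:
            kwargs[key] = _build_block(_BLOCKS[key], dict(value or {}), key)
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    # the global seed overrides the simulation block's seed
    cfg.sim.seed = cfg.seed
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in fields(RunConfig):
        value = getattr(cfg, f.name)
        if f.name in _BLOCKS:
            block = {}
            for bf in fields(value):
                if bf.name in _NON_CONFIG_FIELDS:
                    continue
                v = getattr(value, bf.name)
                if isinstance(v, dict):
                    v = {k: list(t) if isinstance(t, tuple) else t for k, t in v.items()}
                block[bf.name] = v
            out[f.name] = block
        else:
            out[f.name] = value
    return out


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
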