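"""Pipeline configuration: one YAML file driving every stage.

The file has a flat ``paths`` section plus one section per policy
(``filter``, ``orthology``, ``quant``, ``simulation``); every key is
optional and falls back to the corresponding dataclass default, so a
minimal config is just an output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .evidence import FilterPolicy
from .orthology import OrthologyPolicy
from .quant import QuantPolicy
from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    out_dir: Path = Path("orthoppi_out")
    evidence_path: Path | None = None
    experiments_path: Path | None = None
    fly_proteome: Path | None = None
    human_proteome: Path | None = None
    curated_pairs_path: Path | None = None
    hits_fly_to_human: Path | None = None  # precomputed 12-column tabular hits
    hits_human_to_fly: Path | None = None
    control_mode: str = "accession"
    log_level: str = "INFO"
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    orthology_policy: OrthologyPolicy = field(default_factory=OrthologyPolicy)
    quant_policy: QuantPolicy = field(default_factory=QuantPolicy)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def resolve(self, name: str, default_name: str) -> Path:
        """Path from config, else the conventional artifact under out_dir."""
        configured = getattr(self, name)
        return Path(configured) if configured else self.out_dir / default_name


def _build(cls, section: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    kwargs = dict(section)
    # YAML lists for set/tuple-typed fields
    if cls is FilterPolicy and "contaminant_accessions" in kwargs:
        kwargs["contaminant_accessions"] = set(kwargs["contaminant_accessions"])
    if cls is SimulationConfig and "human_conditions" in kwargs:
        kwargs["human_conditions"] = tuple(kwargs["human_conditions"])
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline configuration; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    config = PipelineConfig(
        filter_policy=_build(FilterPolicy, raw.get("filter", {})),
        orthology_policy=_build(OrthologyPolicy, raw.get("orthology", {})),
        quant_policy=_build(QuantPolicy, raw.get("quant", {})),
        simulation=_build(SimulationConfig, raw.get("simulation", {})),
    )
    paths = raw.get("paths", {})
    for key in (
        "out_dir",
        "evidence_path",
        "experiments_path",
        "fly_proteome",
        "human_proteome",
        "curated_pairs_path",
        "hits_fly_to_human",
        "hits_human_to_fly",
    ):
        if key in paths and paths[key] is not None:
            setattr(config, key, Path(paths[key]))
    config.control_mode = raw.get("control_mode", config.control_mode)
    config.log_level = raw.get("log_level", config.log_level)
    return config
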